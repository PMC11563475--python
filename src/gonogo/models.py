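"""Task structure and the nested Go/NoGo reinforcement-learning model space.

The task presents 8 cues, each either a *win* cue (outcomes: reward +1 or
neutral 0) or an *avoid* cue (outcomes: neutral 0 or punishment -1), and each
requiring one of three actions: ``go_left``, ``go_right``, or ``nogo``.
Agents learn action values by a Rescorla-Wagner delta rule

    Q_t(a, s) = Q_{t-1}(a, s) + epsilon * (rho * r_t - Q_{t-1}(a, s)),

bias them with a Go bias ``b`` and a Pavlovian term ``pi * V(s)``
(V = +0.5 for win cues, -0.5 for avoid cues) applied to Go actions only, and
choose through a softmax over the three action weights.

The model space M1-M7 grows from the plain delta rule:

=====  ==========================================================
model  parameters
=====  ==========================================================
M1     rho, epsilon
M2     rho, epsilon, gobias
M3     rho, epsilon, gobias, pi
M4     rho, epsilon, gobias, kappa   (instrumental learning bias)
M5     rho, epsilon, gobias, pi, kappa
M6     rho_win, rho_avoid, epsilon, gobias, pi
M7     rho_pos, rho_neg, epsilon, gobias, pi
=====  ==========================================================

``rho`` (feedback sensitivity) scales outcomes before value updating and acts
like an inverse temperature: the higher it is, the more deterministically
choices follow values, i.e. the lower the decision noise.  M6 splits it by cue
valence; M7 splits it by *outcome* valence, which requires recoding outcomes
by their context-relative desirability (see :func:`scale_outcome`).  ``kappa``
biases the learning rate upward for rewarded Go and downward for punished
NoGo, with a symmetric construction on the logit scale
(:func:`effective_learning_rate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from gonogo._kernels import nll_kernel

# Action codes used throughout kernels and data frames.
ACTIONS = ("go_left", "go_right", "nogo")
GO_LEFT, GO_RIGHT, NOGO = 0, 1, 2
ACTION_CODE = {name: i for i, name in enumerate(ACTIONS)}

WIN, AVOID = "win", "avoid"
VALENCE_CODE = {WIN: 1, AVOID: 0}
# Pavlovian stimulus values entering the Go action weights.
V_BY_VALENCE = {WIN: 0.5, AVOID: -0.5}

CONDITIONS = ("go2win", "go2avoid", "nogo2win", "nogo2avoid")

_MODE_SINGLE, _MODE_VALENCE, _MODE_OUTCOME = 0, 1, 2


@dataclass(frozen=True)
class CueSpec:
    """One of the 8 task cues: its required action and motivational valence."""

    cue_id: int
    required_action: str
    valence: str

    def __post_init__(self) -> None:
        if self.required_action not in ACTIONS:
            raise ValueError(f"unknown action {self.required_action!r}")
        if self.valence not in (WIN, AVOID):
            raise ValueError(f"unknown valence {self.valence!r}")

    @property
    def condition(self) -> str:
        go = "go" if self.required_action != "nogo" else "nogo"
        return f"{go}2{self.valence}"

    @property
    def legal_outcomes(self) -> tuple[int, int]:
        return (1, 0) if self.valence == WIN else (0, -1)


def _default_cues() -> tuple[CueSpec, ...]:
    # 4 conditions x 2 cues; Go conditions split by response side, NoGo
    # conditions duplicated so every cue appears 40 times in a 320-trial run.
    return (
        CueSpec(1, "go_left", WIN),
        CueSpec(2, "go_right", WIN),
        CueSpec(3, "go_left", AVOID),
        CueSpec(4, "go_right", AVOID),
        CueSpec(5, "nogo", WIN),
        CueSpec(6, "nogo", WIN),
        CueSpec(7, "nogo", AVOID),
        CueSpec(8, "nogo", AVOID),
    )


DEFAULT_CUES: tuple[CueSpec, ...] = _default_cues()


@dataclass(frozen=True)
class TrialRecord:
    """One task trial as stored in trial-level data files."""

    subject_id: str
    trial_index: int
    cue_id: int
    action: str
    outcome: int
    feedback_valid: bool

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.outcome not in (-1, 0, 1):
            raise ValueError(f"outcome must be in {{-1, 0, 1}}, got {self.outcome}")


# ---------------------------------------------------------------------------
# Model specifications and parameter transforms
# ---------------------------------------------------------------------------

# Transform of each parameter from the unconstrained fitting scale to its
# native scale: sensitivities must be positive, learning rates must live in
# (0, 1), the biases are unbounded.
TRANSFORMS: Mapping[str, str] = {
    "rho": "exp",
    "rho_win": "exp",
    "rho_avoid": "exp",
    "rho_pos": "exp",
    "rho_neg": "exp",
    "epsilon": "invlogit",
    "gobias": "identity",
    "pi": "identity",
    "kappa": "identity",
}


@dataclass(frozen=True)
class ModelSpec:
    """A member of the nested model space: its id and ordered parameter names."""

    model_id: str
    parameter_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    @property
    def outcome_mode(self) -> int:
        if self.model_id == "M6":
            return _MODE_VALENCE
        if self.model_id == "M7":
            return _MODE_OUTCOME
        return _MODE_SINGLE

    @property
    def uses_kappa(self) -> bool:
        return "kappa" in self.parameter_names

    def transform(self, name: str) -> str:
        return TRANSFORMS[name]


MODELS: Mapping[str, ModelSpec] = {
    "M1": ModelSpec("M1", ("rho", "epsilon")),
    "M2": ModelSpec("M2", ("rho", "epsilon", "gobias")),
    "M3": ModelSpec("M3", ("rho", "epsilon", "gobias", "pi")),
    "M4": ModelSpec("M4", ("rho", "epsilon", "gobias", "kappa")),
    "M5": ModelSpec("M5", ("rho", "epsilon", "gobias", "pi", "kappa")),
    "M6": ModelSpec("M6", ("rho_win", "rho_avoid", "epsilon", "gobias", "pi")),
    "M7": ModelSpec("M7", ("rho_pos", "rho_neg", "epsilon", "gobias", "pi")),
}


def to_native(model: ModelSpec, unconstrained: np.ndarray) -> np.ndarray:
    """Map an unconstrained parameter vector to the native scale."""
    out = np.asarray(unconstrained, dtype=float).copy()
    for i, name in enumerate(model.parameter_names):
        t = TRANSFORMS[name]
        if t == "exp":
            out[i] = np.exp(out[i])
        elif t == "invlogit":
            out[i] = expit(out[i])
    return out


def to_unconstrained(model: ModelSpec, native: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_native`."""
    out = np.asarray(native, dtype=float).copy()
    for i, name in enumerate(model.parameter_names):
        t = TRANSFORMS[name]
        if t == "exp":
            out[i] = np.log(out[i])
        elif t == "invlogit":
            out[i] = logit(out[i])
    return out


@dataclass
class ParameterVector:
    """Per-subject parameters of one model, on both scales.

    ``native`` holds interpretable values (rho > 0, epsilon in (0, 1));
    ``unconstrained`` holds the values the optimizer works on.  The two are
    linked bijectively by the per-parameter transforms.
    """

    model_id: str
    native: dict[str, float] = field(default_factory=dict)
    unconstrained: dict[str, float] = field(default_factory=dict)

    @property
    def model(self) -> ModelSpec:
        return MODELS[self.model_id]

    @classmethod
    def from_native(cls, model_id: str, **values: float) -> "ParameterVector":
        model = MODELS[model_id]
        _check_names(model, values)
        nat = np.array([values[n] for n in model.parameter_names], float)
        unc = to_unconstrained(model, nat)
        return cls(
            model_id,
            dict(zip(model.parameter_names, nat)),
            dict(zip(model.parameter_names, unc)),
        )

    @classmethod
    def from_unconstrained(cls, model_id: str, values) -> "ParameterVector":
        model = MODELS[model_id]
        if isinstance(values, Mapping):
            _check_names(model, values)
            unc = np.array([values[n] for n in model.parameter_names], float)
        else:
            unc = np.asarray(values, dtype=float)
            if unc.shape != (model.n_params,):
                raise ValueError(
                    f"{model_id} expects {model.n_params} parameters, got {unc.shape}"
                )
        nat = to_native(model, unc)
        return cls(
            model_id,
            dict(zip(model.parameter_names, nat)),
            dict(zip(model.parameter_names, unc)),
        )

    def native_array(self) -> np.ndarray:
        return np.array([self.native[n] for n in self.model.parameter_names])

    def unconstrained_array(self) -> np.ndarray:
        return np.array([self.unconstrained[n] for n in self.model.parameter_names])


def _check_names(model: ModelSpec, values: Mapping[str, float]) -> None:
    expected = set(model.parameter_names)
    got = set(values)
    if expected != got:
        raise ValueError(
            f"{model.model_id} expects parameters {sorted(expected)}, got {sorted(got)}"
        )


def _kernel_params(params: ParameterVector) -> tuple[float, float, float, float, float, float]:
    """Pack a ParameterVector into the fixed kernel layout.

    Returns (rho_a, rho_b, eps_hat, gobias, pi, kappa) where rho_a/rho_b are
    the (first, second) sensitivities on the native scale, eps_hat is the
    *unconstrained* learning rate (the kernel applies the inverse logit, which
    the kappa construction needs), and absent parameters are 0.
    """
    nat = params.native
    unc = params.unconstrained
    model = params.model
    if model.model_id == "M6":
        rho_a, rho_b = nat["rho_win"], nat["rho_avoid"]
    elif model.model_id == "M7":
        rho_a, rho_b = nat["rho_pos"], nat["rho_neg"]
    else:
        rho_a, rho_b = nat["rho"], 0.0
    return (
        rho_a,
        rho_b,
        unc["epsilon"],
        nat.get("gobias", 0.0),
        nat.get("pi", 0.0),
        unc.get("kappa", 0.0),
    )


# ---------------------------------------------------------------------------
# Elementary model operations
# ---------------------------------------------------------------------------

def scale_outcome(
    model: ModelSpec, params: ParameterVector, outcome: int, cue_valence: str
) -> float:
    """Scaled reinforcement signal rho * r entering the delta rule.

    M1-M5 multiply the raw outcome by a single sensitivity.  M6 picks the
    sensitivity by cue valence.  M7 first recodes the outcome by its
    context-relative valence: the desired outcome (reward on a win cue,
    neutral on an avoid cue) enters as +rho_pos and the undesired outcome
    (neutral on a win cue, punishment on an avoid cue) as -rho_neg, so both
    sensitivities operate in both motivational contexts.
    """
    legal = (1, 0) if cue_valence == WIN else (0, -1)
    if outcome not in legal:
        raise ValueError(
            f"outcome {outcome} illegal for {cue_valence} cue (legal: {legal})"
        )
    mode = model.outcome_mode
    if mode == _MODE_SINGLE:
        return params.native["rho"] * outcome
    if mode == _MODE_VALENCE:
        rho = params.native["rho_win"] if cue_valence == WIN else params.native["rho_avoid"]
        return rho * outcome
    desired = outcome == (1 if cue_valence == WIN else 0)
    return params.native["rho_pos"] if desired else -params.native["rho_neg"]


def effective_learning_rate(
    model: ModelSpec, params: ParameterVector, outcome: int, action: str
) -> float:
    """Learning rate after the instrumental bias kappa, clamped to (0, 1).

    With base rate eps0 = invlogit(eps_hat), kappa raises the rate for
    rewarded Go and lowers it for punished NoGo trials.  To keep the
    modulation symmetric around eps0 on the probability scale, the smaller
    branch is computed as invlogit(eps_hat -/+ kappa) and the larger branch
    is reflected: eps_large = eps0 + (eps0 - eps_small).  The reflected value
    can leave (0, 1), hence the clamp.
    """
    eps_hat = params.unconstrained["epsilon"]
    eps0 = float(expit(eps_hat))
    if not model.uses_kappa:
        return eps0
    kappa = params.unconstrained["kappa"]
    if eps0 <= 0.5:  # boundary tie broken toward this branch
        eps_pnogo = float(expit(eps_hat - kappa))
        eps_rgo = eps0 + (eps0 - eps_pnogo)
    else:
        eps_rgo = float(expit(eps_hat + kappa))
        eps_pnogo = eps0 + (eps0 - eps_rgo)
    tiny = 1e-9
    eps_rgo = min(max(eps_rgo, tiny), 1.0 - tiny)
    eps_pnogo = min(max(eps_pnogo, tiny), 1.0 - tiny)
    if outcome == 1 and action != "nogo":
        return eps_rgo
    if outcome == -1 and action == "nogo":
        return eps_pnogo
    return eps0


def update_q(
    q_table: np.ndarray, cue_id: int, action: str, scaled_outcome: float, lr: float
) -> np.ndarray:
    """One delta-rule step; returns a new 8 x 3 table, input untouched."""
    if not 0.0 < lr < 1.0:
        raise ValueError(f"learning rate must be in (0, 1), got {lr}")
    out = np.array(q_table, dtype=float, copy=True)
    a = ACTION_CODE[action]
    out[cue_id - 1, a] += lr * (scaled_outcome - out[cue_id - 1, a])
    return out


def action_weights(
    q_table: np.ndarray, cue: CueSpec, params: ParameterVector, model: ModelSpec
) -> np.ndarray:
    """Action weights (go_left, go_right, nogo) for one cue.

    Go weights receive the Go bias and the Pavlovian term pi * V(s); the NoGo
    weight is the bare Q-value.  Parameters absent from the model act as 0.
    """
    b = params.native.get("gobias", 0.0)
    pi = params.native.get("pi", 0.0)
    v = V_BY_VALENCE[cue.valence]
    q = np.asarray(q_table, dtype=float)[cue.cue_id - 1]
    return np.array([q[0] + b + pi * v, q[1] + b + pi * v, q[2]])


def action_probabilities(weights: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the three action weights."""
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError(f"non-finite action weight in {w}")
    e = np.exp(w - w.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ("cue", "response", "outcome")


def trials_to_arrays(
    trials: pd.DataFrame, cues: Sequence[CueSpec] = DEFAULT_CUES
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Convert one subject's trial frame into kernel-ready integer arrays.

    Returns (cue_index 0-based, action code, outcome, valence code), ordered
    by the ``trial`` column.
    """
    missing = [c for c in _TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial data missing columns {missing}")
    df = trials.sort_values("trial") if "trial" in trials.columns else trials
    cue_ids = df["cue"].to_numpy(dtype=np.int64)
    valence_by_cue = np.zeros(len(cues) + 1, dtype=np.int64)
    for c in cues:
        valence_by_cue[c.cue_id] = VALENCE_CODE[c.valence]
    actions = df["response"].map(ACTION_CODE)
    if actions.isna().any():
        bad = df["response"][actions.isna()].iloc[0]
        raise ValueError(f"unknown response label {bad!r}")
    return (
        cue_ids - 1,
        actions.to_numpy(dtype=np.int64),
        df["outcome"].to_numpy(dtype=np.int64),
        valence_by_cue[cue_ids],
    )


def negative_log_likelihood(
    params: ParameterVector,
    model: ModelSpec | None = None,
    trials: pd.DataFrame | None = None,
    cues: Sequence[CueSpec] = DEFAULT_CUES,
    *,
    arrays: tuple[np.ndarray, ...] | None = None,
) -> float:
    """Total negative log likelihood of one subject's choice sequence.

    Runs the full generative recursion (weights -> softmax -> choice
    probability, then outcome scaling / learning-rate selection -> Q update)
    over the ordered trials.  Probabilities are floored at 1e-12 inside the
    log.  ``arrays`` may be passed instead of ``trials`` to skip the frame
    conversion in tight loops (as produced by :func:`trials_to_arrays`).
    """
    model = model if model is not None else params.model
    if arrays is None:
        if trials is None or len(trials) == 0:
            return 0.0
        arrays = trials_to_arrays(trials, cues)
    cue_idx, action, outcome, valence = arrays
    if len(cue_idx) == 0:
        return 0.0
    rho_a, rho_b, eps_hat, b, pi, kappa = _kernel_params(params)
    return float(
        nll_kernel(
            cue_idx, action, outcome, valence,
            rho_a, rho_b, eps_hat, b, pi, kappa,
            model.outcome_mode, model.uses_kappa,
        )
    )
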