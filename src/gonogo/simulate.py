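"""Synthetic task schedules, agents, cohorts, and cross-task tables.

Everything here is generative plumbing for testing and validating the
modelling pipeline without any empirical data: a 320-trial schedule with
exactly balanced 80:20 valid/invalid feedback, agents that play the task
under any model in the M1-M7 space, age-graded cohorts with Gaussian
between-subject variation on the unconstrained parameter scale, and a
linear-Gaussian cross-task table with a configurable mediation structure
(age -> decision noise -> task outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gonogo._kernels import simulate_kernel
from gonogo.models import (
    ACTIONS,
    ACTION_CODE,
    DEFAULT_CUES,
    MODELS,
    VALENCE_CODE,
    CueSpec,
    ModelSpec,
    ParameterVector,
    to_unconstrained,
)
from gonogo.models import _kernel_params

N_TRIALS = 320
N_REPEATS = 40
VALID_PER_CUE = 32  # 80% of 40, balanced exactly rather than i.i.d.

# Group-mean parameter estimates (native scale) reported for the fitted model
# space on the empirical cohort; used as default generating values for
# synthetic cohorts so simulations run in a realistic regime.
REPORTED_GROUP_MEANS: Mapping[str, Mapping[str, float]] = {
    "M1": {"rho": 25.73, "epsilon": 0.04},
    "M2": {"rho": 24.17, "epsilon": 0.05, "gobias": -0.02},
    "M3": {"rho": 15.37, "epsilon": 0.08, "gobias": 0.07, "pi": 0.34},
    "M4": {"rho": 21.10, "epsilon": 0.06, "gobias": -0.001, "kappa": 2.61},
    "M5": {"rho": 15.71, "epsilon": 0.06, "gobias": 0.06, "pi": 0.06, "kappa": 1.68},
    "M6": {"rho_win": 21.06, "rho_avoid": 12.60, "epsilon": 0.06, "gobias": 0.02, "pi": 0.72},
    "M7": {"rho_pos": 5.52, "rho_neg": 1.03, "epsilon": 0.18, "gobias": -0.08, "pi": 0.25},
}


@dataclass(frozen=True)
class TaskSchedule:
    """Ordered trial plan: cue id and feedback-validity flag per trial."""

    cue_ids: np.ndarray
    feedback_valid: np.ndarray

    def __len__(self) -> int:
        return len(self.cue_ids)


def generate_schedule(
    seed: int, cues: Sequence[CueSpec] = DEFAULT_CUES, n_repeats: int = N_REPEATS
) -> TaskSchedule:
    """Random schedule: each cue ``n_repeats`` times, validity balanced 80:20.

    Validity flags are balanced exactly within cue (32 valid / 8 invalid at
    the default 40 repeats) so the feedback ratio carries no sampling
    variance into recovery experiments.
    """
    rng = np.random.default_rng(seed)
    n_valid = int(round(0.8 * n_repeats))
    cue_col, valid_col = [], []
    for cue in cues:
        flags = np.zeros(n_repeats, dtype=bool)
        flags[:n_valid] = True
        rng.shuffle(flags)
        cue_col.append(np.full(n_repeats, cue.cue_id, dtype=np.int64))
        valid_col.append(flags)
    cue_ids = np.concatenate(cue_col)
    valid = np.concatenate(valid_col)
    order = rng.permutation(len(cue_ids))
    return TaskSchedule(cue_ids[order], valid[order])


def realize_outcome(cue: CueSpec, action: str, valid: bool) -> int:
    """Outcome of one trial under the probabilistic feedback rule.

    Valid feedback rewards the correct action (win: +1, avoid: 0); invalid
    feedback flips the mapping, so a correct response can still draw the
    unfavorable outcome.
    """
    correct = action == cue.required_action
    favorable = correct == bool(valid)
    if cue.valence == "win":
        return 1 if favorable else 0
    return 0 if favorable else -1


def _cue_lookup(cues: Sequence[CueSpec]) -> tuple[np.ndarray, np.ndarray]:
    req = np.zeros(len(cues), dtype=np.int64)
    val = np.zeros(len(cues), dtype=np.int64)
    for cue in cues:
        req[cue.cue_id - 1] = ACTION_CODE[cue.required_action]
        val[cue.cue_id - 1] = VALENCE_CODE[cue.valence]
    return req, val


def simulate_agent(
    params: ParameterVector,
    model: ModelSpec | None = None,
    schedule: TaskSchedule | None = None,
    seed: int = 0,
    subject_id: str = "sim",
    cues: Sequence[CueSpec] = DEFAULT_CUES,
) -> pd.DataFrame:
    """One agent playing one session; returns a trial-level data frame.

    The generative loop mirrors the likelihood exactly: action weights ->
    softmax -> sampled action -> realized outcome -> Q update.
    """
    model = model if model is not None else params.model
    if schedule is None:
        schedule = generate_schedule(seed)
    req, val_by_cue = _cue_lookup(cues)
    rho_a, rho_b, eps_hat, b, pi, kappa = _kernel_params(params)
    actions, outcomes = simulate_kernel(
        schedule.cue_ids - 1,
        schedule.feedback_valid.astype(np.int64),
        req, val_by_cue,
        rho_a, rho_b, eps_hat, b, pi, kappa,
        model.outcome_mode, model.uses_kappa,
        int(seed) % (2**31 - 1),
    )
    cond = {c.cue_id: c.condition for c in cues}
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial": np.arange(1, len(schedule) + 1),
            "cue": schedule.cue_ids,
            "condition": [cond[c] for c in schedule.cue_ids],
            "response": [ACTIONS[a] for a in actions],
            "outcome": outcomes,
            "valid": schedule.feedback_valid.astype(int),
        }
    )


@dataclass
class CohortSpec:
    """Generative description of a simulated cohort.

    Group means/sds are on the unconstrained scale.  ``age_slopes`` adds a
    linear shift (per standard deviation of age) to a parameter's mean,
    encoding age-graded effects such as rising feedback sensitivity.
    """

    n_subjects: int
    model_id: str
    group_means: Mapping[str, float] | None = None
    group_sds: Mapping[str, float] | float = 0.5
    age_range: tuple[float, float] = (12.0, 42.0)
    age_slopes: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def resolved_means(self) -> dict[str, float]:
        model = MODELS[self.model_id]
        if self.group_means is not None:
            return dict(self.group_means)
        nat = np.array([REPORTED_GROUP_MEANS[self.model_id][n] for n in model.parameter_names])
        unc = to_unconstrained(model, nat)
        return dict(zip(model.parameter_names, unc))

    def resolved_sds(self) -> dict[str, float]:
        model = MODELS[self.model_id]
        if isinstance(self.group_sds, Mapping):
            return dict(self.group_sds)
        return {n: float(self.group_sds) for n in model.parameter_names}


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trials, subjects) frames.

    Each subject gets a fresh schedule.  The subjects frame records age and
    the true generating parameters on both scales (columns ``true_<name>``
    native, ``true_u_<name>`` unconstrained).
    """
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    model = MODELS[spec.model_id]
    rng = np.random.default_rng(spec.seed)
    means = spec.resolved_means()
    sds = spec.resolved_sds()
    for name, sd in sds.items():
        if sd < 0:
            raise ValueError(f"negative group sd for {name}")
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, spec.n_subjects)
    age_z = (ages - ages.mean()) / ages.std() if spec.n_subjects > 1 else np.zeros(1)

    trial_frames, rows = [], []
    for i in range(spec.n_subjects):
        unc = {}
        for name in model.parameter_names:
            mu = means[name] + spec.age_slopes.get(name, 0.0) * age_z[i]
            unc[name] = mu + sds[name] * rng.standard_normal()
        params = ParameterVector.from_unconstrained(spec.model_id, unc)
        sid = f"sub{i + 1:03d}"
        sched_seed = int(rng.integers(2**31 - 1))
        agent_seed = int(rng.integers(2**31 - 1))
        schedule = generate_schedule(sched_seed)
        trial_frames.append(
            simulate_agent(params, model, schedule, seed=agent_seed, subject_id=sid)
        )
        row = {"subject_id": sid, "age": ages[i]}
        row.update({f"true_{n}": params.native[n] for n in model.parameter_names})
        row.update({f"true_u_{n}": params.unconstrained[n] for n in model.parameter_names})
        rows.append(row)
    return pd.concat(trial_frames, ignore_index=True), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-task table with mediation structure
# ---------------------------------------------------------------------------

CROSSTASK_COLUMNS = (
    "age",
    "rho_pos_gonogo", "rho_neg_gonogo", "epsilon_gonogo", "gobias_gonogo", "pi_gonogo",
    "rho_pos_reversal", "rho_neg_reversal", "epsilon_reversal",
    "pre_post_accuracy", "switch_after_negative",
    "beta1_twostep", "beta2_twostep", "omega_twostep", "mb_estimate",
    "overall_accuracy", "pavlovian_score",
)

# Columns generated as outcomes of the mediation paths; the sign multiplies
# the mediator path b (switching after negative feedback falls as noise falls).
_OUTCOME_SIGNS = {
    "overall_accuracy": 1.0,
    "pavlovian_score": 1.0,
    "pre_post_accuracy": 1.0,
    "switch_after_negative": -1.0,
    "mb_estimate": 1.0,
    "omega_twostep": 1.0,
}

# Default rank-correlation structure of the remaining columns with the
# mediator, qualitatively matching the empirical cross-task pattern: noise
# parameters cohere across tasks, learning rates do not.
_DEFAULT_AUX_CORR = {
    "rho_pos_reversal": 0.47,
    "rho_neg_reversal": -0.30,
    "beta1_twostep": 0.43,
    "beta2_twostep": 0.52,
    "rho_neg_gonogo": 0.0,
    "epsilon_gonogo": 0.0,
    "gobias_gonogo": 0.0,
    "pi_gonogo": 0.0,
    "epsilon_reversal": 0.0,
}


@dataclass
class CrossTaskSpec:
    """Linear-Gaussian generative spec for the per-subject cross-task table.

    Path coefficients follow the classic mediation triangle on z-scored age:
    mediator m = a * age_z + e1 and each outcome y = sign * b * m +
    c_prime * age_z + e2, so the true indirect effect is a*b and the true
    proportion mediated is a*b / (a*b + c_prime).  The defaults give a
    proportion mediated of 0.5.  Remaining columns correlate with the
    mediator at the specified levels and are otherwise independent.
    """

    a: float = 0.5
    b: float = 0.5
    c_prime: float = 0.25
    sd_mediator: float = 1.0
    sd_outcome: float = 1.0
    aux_corr: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_AUX_CORR))
    age_range: tuple[float, float] = (12.0, 42.0)

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def proportion_mediated(self) -> float:
        return self.indirect / (self.indirect + self.c_prime)


def generate_crosstask_table(
    n: int, spec: CrossTaskSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic per-subject cross-task table with known mediation structure."""
    spec = spec or CrossTaskSpec()
    for col, r in spec.aux_corr.items():
        if not -1.0 <= r <= 1.0:
            raise ValueError(
                f"aux correlation for {col} is {r}; implied covariance not PSD"
            )
    rng = np.random.default_rng(seed)
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, n)
    age_z = (age - age.mean()) / age.std()
    mediator = spec.a * age_z + spec.sd_mediator * rng.standard_normal(n)
    m_z = (mediator - mediator.mean()) / mediator.std()

    out = {"age": age, "rho_pos_gonogo": mediator}
    for col, sign in _OUTCOME_SIGNS.items():
        out[col] = (
            sign * spec.b * mediator
            + sign * spec.c_prime * age_z
            + spec.sd_outcome * rng.standard_normal(n)
        )
    for col in CROSSTASK_COLUMNS:
        if col in out:
            continue
        r = spec.aux_corr.get(col, 0.0)
        out[col] = r * m_z + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    df = pd.DataFrame(out)
    df.insert(0, "subject_id", [f"sub{i + 1:03d}" for i in range(n)])
    return df[["subject_id", *CROSSTASK_COLUMNS]]
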