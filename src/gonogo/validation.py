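"""Posterior-predictive checks and parameter-recovery studies.

A fitted model is only credible if agents simulated at the fitted parameters
reproduce the qualitative behavioral signatures of the data (learning curves
per condition, win-stay/lose-shift style repeat probabilities) and if the
fitting procedure can recover known generating parameters from simulated
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from gonogo._kernels import pgo_curves_kernel
from gonogo.fitting import SubjectFit, fit_hierarchical
from gonogo.models import (
    ACTION_CODE,
    DEFAULT_CUES,
    MODELS,
    CueSpec,
)
from gonogo.models import _kernel_params
from gonogo.simulate import CohortSpec, _cue_lookup, simulate_cohort


@dataclass
class PosteriorPredictiveReport:
    """Observed vs. simulated behavioral summaries.

    ``learning_curves``: P(Go) by condition and within-cue presentation index
    (observed and mean simulated).  ``condition_pgo``: session-level P(Go)
    per condition with the absolute observed-simulated discrepancy.
    ``repeat_table``: observed-minus-simulated P(repeat) per
    (previous action, outcome valence, outcome salience) cell.
    """

    learning_curves: pd.DataFrame
    condition_pgo: pd.DataFrame
    repeat_table: pd.DataFrame
    n_sims: int


def _observed_pgo_curves(trials: pd.DataFrame, cond_by_cue: dict[int, str]) -> pd.DataFrame:
    df = trials.sort_values("trial").copy()
    df["presentation"] = df.groupby("cue").cumcount() + 1
    df["is_go"] = (df["response"] != "nogo").astype(float)
    df["condition"] = df["cue"].map(cond_by_cue)
    return df


def _repeat_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """P(repeat same action on next presentation of the same cue), classified
    by previous action type, outcome valence, and outcome salience.

    Outcome valence follows the motivational-context convention: positive =
    reward on win cues or neutral on avoid cues; negative otherwise.
    Salience: salient = reward/punishment, neutral = 0 outcome.
    """
    df = trials.sort_values("trial")
    rows = []
    for _, grp in df.groupby("cue"):
        resp = grp["response"].to_numpy()
        out = grp["outcome"].to_numpy()
        win = grp["condition"].iloc[0].endswith("win")
        for i in range(len(grp) - 1):
            positive = out[i] == 1 if win else out[i] == 0
            rows.append(
                {
                    "prev_action": "go" if resp[i] != "nogo" else "nogo",
                    "outcome_valence": "positive" if positive else "negative",
                    "salience": "salient" if out[i] != 0 else "neutral",
                    "repeat": float(resp[i + 1] == resp[i]),
                }
            )
    return pd.DataFrame(rows)


def posterior_predictive(
    fits: Sequence[SubjectFit],
    dataset: pd.DataFrame,
    n_sims: int = 100,
    seed: int = 0,
    cues: Sequence[CueSpec] = DEFAULT_CUES,
) -> PosteriorPredictiveReport:
    """Simulate each subject at the fitted parameters on their own schedule.

    For every subject, ``n_sims`` fresh sessions are generated on the cue
    order and feedback-validity flags of that subject's observed data; new
    choices and outcomes follow the fitted response probabilities.
    """
    cond_by_cue = {c.cue_id: c.condition for c in cues}
    req, val_by_cue = _cue_lookup(cues)
    fit_by_subject = {f.subject_id: f for f in fits}
    rng = np.random.default_rng(seed)

    curve_rows, repeat_obs_frames, repeat_sim_frames = [], [], []
    for sid, grp in dataset.groupby("subject_id", sort=False):
        fit = fit_by_subject[str(sid)]
        model = MODELS[fit.model_id]
        params = fit.parameters
        grp = grp.sort_values("trial")
        cue_idx = grp["cue"].to_numpy(dtype=np.int64) - 1
        valid = grp["valid"].to_numpy(dtype=np.int64)
        rho_a, rho_b, eps_hat, b, pi, kappa = _kernel_params(params)
        sim_seed = int(rng.integers(2**31 - 1 - n_sims))
        pgo, pres_len = pgo_curves_kernel(
            cue_idx, valid, req, val_by_cue,
            rho_a, rho_b, eps_hat, b, pi, kappa,
            model.outcome_mode, model.uses_kappa, n_sims, sim_seed,
        )
        obs = _observed_pgo_curves(grp, cond_by_cue)
        for (cue_id, pres), sub in obs.groupby(["cue", "presentation"]):
            curve_rows.append(
                {
                    "subject_id": sid,
                    "condition": cond_by_cue[cue_id],
                    "presentation": pres,
                    "p_go_observed": sub["is_go"].mean(),
                    "p_go_simulated": pgo[cue_id - 1, pres - 1],
                }
            )
        repeat_obs_frames.append(_repeat_cells(grp).assign(subject_id=sid))
        # one simulated session per subject feeds the repeat comparison
        from gonogo._kernels import simulate_kernel

        actions, outcomes = simulate_kernel(
            cue_idx, valid, req, val_by_cue,
            rho_a, rho_b, eps_hat, b, pi, kappa,
            model.outcome_mode, model.uses_kappa, sim_seed,
        )
        sim = grp.copy()
        sim["response"] = [("go_left", "go_right", "nogo")[a] for a in actions]
        sim["outcome"] = outcomes
        repeat_sim_frames.append(_repeat_cells(sim).assign(subject_id=sid))

    curves = pd.DataFrame(curve_rows)
    learning = (
        curves.groupby(["condition", "presentation"])[["p_go_observed", "p_go_simulated"]]
        .mean()
        .reset_index()
    )
    cond = (
        curves.groupby("condition")[["p_go_observed", "p_go_simulated"]]
        .mean()
        .reset_index()
    )
    cond["abs_diff"] = (cond["p_go_observed"] - cond["p_go_simulated"]).abs()

    cells = ["prev_action", "outcome_valence", "salience"]
    rep_obs = pd.concat(repeat_obs_frames).groupby(cells)["repeat"].mean()
    rep_sim = pd.concat(repeat_sim_frames).groupby(cells)["repeat"].mean()
    repeat = (
        pd.DataFrame({"p_repeat_observed": rep_obs, "p_repeat_simulated": rep_sim})
        .reset_index()
    )
    repeat["obs_minus_sim"] = repeat["p_repeat_observed"] - repeat["p_repeat_simulated"]
    return PosteriorPredictiveReport(learning, cond, repeat, n_sims)


@dataclass
class RecoveryReport:
    """Per-parameter rank correlation between generating and recovered values."""

    model_id: str
    correlations: pd.Series
    subject_table: pd.DataFrame
    degenerate: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> float:
        return float(self.correlations[name])


def parameter_recovery(
    model: str,
    cohort_spec: CohortSpec | None = None,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> RecoveryReport:
    """Simulate a cohort, refit it hierarchically, and correlate true vs.
    recovered parameters (Spearman, on the unconstrained scale).

    Parameters with zero between-subject variance are reported as degenerate
    rather than given a correlation.
    """
    spec = cohort_spec or CohortSpec(n_subjects=93, model_id=model, seed=seed)
    trials, subjects = simulate_cohort(spec)
    _, fits = fit_hierarchical(trials, model, seed=seed + 1, **(fit_kwargs or {}))
    model_spec = MODELS[model]
    rec = pd.DataFrame(
        [
            {"subject_id": f.subject_id, "converged": f.converged}
            | {f"recovered_u_{n}": f.map_unconstrained[i]
               for i, n in enumerate(model_spec.parameter_names)}
            for f in fits
        ]
    )
    table = subjects.merge(rec, on="subject_id")
    corrs, degenerate = {}, []
    for name in model_spec.parameter_names:
        true = table[f"true_u_{name}"]
        got = table[f"recovered_u_{name}"]
        if true.nunique() <= 1 or got.nunique() <= 1:
            degenerate.append(name)
            corrs[name] = np.nan
            continue
        corrs[name] = spearmanr(true, got).statistic
    return RecoveryReport(model, pd.Series(corrs), table, tuple(degenerate))
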