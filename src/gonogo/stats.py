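"""Descriptive scores, cross-task Spearman correlations, and bootstrap
mediation analysis.

The Pavlovian bias score summarizes how much motivational congruency helps
performance: P_corr(Go2Win) - P_corr(Go2Avoid) + P_corr(NoGo2Win) -
P_corr(NoGo2Avoid).  Cross-task correlations use Spearman rank coefficients
with per-family Bonferroni thresholds (0.05/4 for Go/NoGo x reversal,
0.05/2 for Go/NoGo x two-step).  Mediation follows the classic three-model
product-of-coefficients approach with nonparametric case-resampling
percentile bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from gonogo.models import CONDITIONS, DEFAULT_CUES, CueSpec

logger = logging.getLogger(__name__)

REVERSAL_ALPHA = 0.05 / 4
TWOSTEP_ALPHA = 0.05 / 2
ALPHA_BY_FAMILY = {"reversal": REVERSAL_ALPHA, "twostep": TWOSTEP_ALPHA}


def condition_accuracy(
    trials: pd.DataFrame, cues: Sequence[CueSpec] = DEFAULT_CUES
) -> pd.DataFrame:
    """Per-subject P(correct) per condition plus the Pavlovian bias score.

    A response is correct when it equals the cue's required action (including
    the Go side); Go conditions pool left- and right-requiring cues.  Empty
    conditions yield NaN, never 0.
    """
    req = {c.cue_id: c.required_action for c in cues}
    cond = {c.cue_id: c.condition for c in cues}
    df = trials.copy()
    df["correct"] = df["response"] == df["cue"].map(req)
    df["condition"] = df["cue"].map(cond)
    acc = (
        df.groupby(["subject_id", "condition"])["correct"].mean().unstack("condition")
    )
    acc = acc.reindex(columns=CONDITIONS)
    acc["pavlovian_score"] = pavlovian_score(acc)
    acc["overall_accuracy"] = df.groupby("subject_id")["correct"].mean()
    return acc.reset_index()


def pavlovian_score(p_correct: pd.DataFrame | Mapping[str, float]) -> pd.Series | float:
    """Bias score from per-condition accuracies; range [-2, 2]."""
    if isinstance(p_correct, pd.DataFrame):
        return (
            p_correct["go2win"] - p_correct["go2avoid"]
            + p_correct["nogo2win"] - p_correct["nogo2avoid"]
        )
    return (
        p_correct["go2win"] - p_correct["go2avoid"]
        + p_correct["nogo2win"] - p_correct["nogo2avoid"]
    )


def spearman_matrix(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
    alpha_by_family: Mapping[str, float] = ALPHA_BY_FAMILY,
) -> pd.DataFrame:
    """Rank correlations for (x, y, family) pairs with family-wise thresholds.

    Rows with missing values are dropped pairwise and the retained n is
    reported.  Constant columns give a flagged undefined correlation.
    """
    rows = []
    for x, y, family in pairs:
        sub = table[[x, y]].dropna()
        n = len(sub)
        if n < 4:
            raise ValueError(f"fewer than 4 complete pairs for ({x}, {y})")
        alpha = alpha_by_family.get(family, 0.05)
        if sub[x].nunique() <= 1 or sub[y].nunique() <= 1:
            rows.append(
                {"x": x, "y": y, "family": family, "n": n, "rs": np.nan,
                 "p": np.nan, "alpha": alpha, "significant": False, "defined": False}
            )
            continue
        res = spearmanr(sub[x], sub[y])
        rows.append(
            {"x": x, "y": y, "family": family, "n": n,
             "rs": float(res.statistic), "p": float(res.pvalue), "alpha": alpha,
             "significant": bool(res.pvalue < alpha), "defined": True}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Product-of-coefficients mediation estimate with percentile bootstrap CIs.

    ``indirect`` = a*b (path through the mediator), ``direct`` = c' (effect of
    x on y holding m), ``total`` = c (marginal effect of x on y); in the
    linear case total = indirect + direct identically.  ``proportion_mediated``
    is indirect/total and is flagged unstable when the total effect's CI
    covers zero.
    """

    indirect: float
    direct: float
    total: float
    indirect_ci: tuple[float, float]
    direct_ci: tuple[float, float]
    total_ci: tuple[float, float]
    p_indirect: float
    p_direct: float
    p_total: float
    proportion_mediated: float
    proportion_unstable: bool
    n: int
    n_boot: int
    seed: int

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "indirect": self.indirect,
                "indirect_lo": self.indirect_ci[0],
                "indirect_hi": self.indirect_ci[1],
                "p_indirect": self.p_indirect,
                "direct": self.direct,
                "direct_lo": self.direct_ci[0],
                "direct_hi": self.direct_ci[1],
                "p_direct": self.p_direct,
                "total": self.total,
                "total_lo": self.total_ci[0],
                "total_hi": self.total_ci[1],
                "p_total": self.p_total,
                "proportion_mediated": self.proportion_mediated,
                "proportion_unstable": self.proportion_unstable,
                "n": self.n,
            }
        )


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(indirect, direct, total) by three least-squares fits."""
    ones = np.ones_like(x)
    x1 = np.column_stack([ones, x])
    a = np.linalg.lstsq(x1, m, rcond=None)[0][1]
    coef = np.linalg.lstsq(np.column_stack([ones, x, m]), y, rcond=None)[0]
    c_prime, b = coef[1], coef[2]
    c = np.linalg.lstsq(x1, y, rcond=None)[0][1]
    return a * b, c_prime, c


def _boot_p(samples: np.ndarray) -> float:
    """Doubled tail proportion of bootstrap replicates crossing zero."""
    lower = np.mean(samples <= 0.0)
    upper = np.mean(samples >= 0.0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def mediate(
    x, m, y, n_boot: int = 10_000, seed: int = 0, standardize_x: bool = True
) -> MediationResult:
    """Mediation of the x -> y effect through m with percentile bootstrap.

    The predictor is z-standardized by default (as age is in the downstream
    analyses).  Cases are resampled jointly (subject-level resampling);
    two-sided p-values are doubled tail proportions of replicates crossing 0.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[keep], m[keep], y[keep]
    n = len(x)
    if n < 10:
        raise ValueError(f"mediation needs >= 10 complete cases, got {n}")
    if standardize_x:
        x = (x - x.mean()) / x.std()

    indirect, direct, total = _paths(x, m, y)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i] = _paths(x[idx], m[idx], y[idx])
    ci = np.percentile(boots, [2.5, 97.5], axis=0)
    prop = indirect / total if total != 0 else np.nan
    total_unstable = ci[0, 2] <= 0.0 <= ci[1, 2]
    return MediationResult(
        indirect=float(indirect),
        direct=float(direct),
        total=float(total),
        indirect_ci=(float(ci[0, 0]), float(ci[1, 0])),
        direct_ci=(float(ci[0, 1]), float(ci[1, 1])),
        total_ci=(float(ci[0, 2]), float(ci[1, 2])),
        p_indirect=_boot_p(boots[:, 0]),
        p_direct=_boot_p(boots[:, 1]),
        p_total=_boot_p(boots[:, 2]),
        proportion_mediated=float(prop),
        proportion_unstable=bool(total_unstable or total == 0),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


# The analysis set: decision noise for positive feedback as mediator of every
# age -> outcome relation of interest.
MEDIATION_MODELS: tuple[tuple[str, str, str], ...] = (
    ("age", "rho_pos_gonogo", "overall_accuracy"),
    ("age", "rho_pos_gonogo", "pavlovian_score"),
    ("age", "rho_pos_gonogo", "pi_gonogo"),
    ("age", "rho_pos_gonogo", "pre_post_accuracy"),
    ("age", "rho_pos_gonogo", "switch_after_negative"),
    ("age", "rho_pos_gonogo", "mb_estimate"),
    ("age", "rho_pos_gonogo", "omega_twostep"),
)


def run_mediation_suite(
    table: pd.DataFrame,
    models: Sequence[tuple[str, str, str]] = MEDIATION_MODELS,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the configured mediation models on a cross-task table.

    Models whose columns are absent are skipped with a log entry.  Each model
    gets a deterministic seed derived from ``seed`` and its position.
    """
    rows = []
    for i, (x, m, y) in enumerate(models):
        missing = [c for c in (x, m, y) if c not in table.columns]
        if missing:
            logger.warning("skipping mediation %s -> %s -> %s: missing %s", x, m, y, missing)
            continue
        res = mediate(table[x], table[m], table[y], n_boot=n_boot, seed=seed + i)
        row = res.summary()
        row["x"], row["m"], row["y"] = x, m, y
        rows.append(row)
    return pd.DataFrame(rows)
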