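"""Hierarchical empirical-Bayes fitting and random-effects model selection.

Per subject, parameters are estimated by MAP under a Gaussian group prior on
the unconstrained scale, and the model evidence is approximated by Laplace's
method at the mode.  The group prior itself is learned by
expectation-maximization: the E-step computes each subject's MAP and local
posterior curvature, the M-step updates the group mean and variance from the
subject posteriors.  Models are then compared with random-effects Bayesian
model selection, which treats the model identity as a random effect across
subjects: a Dirichlet posterior over model frequencies yields expected
frequencies, exceedance probabilities, and the protected exceedance
probability PXP = (1 - BOR) * EP + BOR / K, where the Bayes omnibus risk BOR
is the posterior probability that all models are equally frequent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betainc, gammaln, logsumexp, psi
from scipy.stats import dirichlet as dirichlet_dist

from gonogo.models import (
    DEFAULT_CUES,
    MODELS,
    CueSpec,
    ModelSpec,
    ParameterVector,
    negative_log_likelihood,
    trials_to_arrays,
)

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-4
DEFAULT_PRIOR_VARIANCE = 6.25


@dataclass
class GroupPrior:
    """Gaussian group-level prior per unconstrained parameter."""

    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        if np.any(self.variances <= 0):
            raise ValueError("prior variances must be positive")
        self.variances = np.maximum(self.variances, VARIANCE_FLOOR)

    @classmethod
    def default(cls, n_params: int) -> "GroupPrior":
        return cls(np.zeros(n_params), np.full(n_params, DEFAULT_PRIOR_VARIANCE))


@dataclass
class SubjectFit:
    """MAP estimate and Laplace evidence for one subject under one model."""

    subject_id: str
    model_id: str
    map_unconstrained: np.ndarray
    hessian_logdet: float
    log_evidence: float
    converged: bool
    posterior_variance: np.ndarray | None = None

    @property
    def parameters(self) -> ParameterVector:
        return ParameterVector.from_unconstrained(self.model_id, self.map_unconstrained)


def _penalized(nll_fn: Callable[[np.ndarray], float], prior: GroupPrior):
    mu, var = prior.means, prior.variances
    const = 0.5 * np.sum(np.log(2.0 * np.pi * var))

    def f(theta: np.ndarray) -> float:
        val = nll_fn(theta) + 0.5 * np.sum((theta - mu) ** 2 / var) + const
        return val if np.isfinite(val) else 1e30

    return f


def _fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = len(x)
    hess = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return hess


def _repair_hessian(hess: np.ndarray) -> np.ndarray:
    eigvals = np.linalg.eigvalsh(hess)
    if eigvals.min() <= 0:
        ridge = abs(eigvals.min()) + 1e-6
        logger.warning("non-positive-definite Hessian; adding ridge %.3g", ridge)
        hess = hess + ridge * np.eye(len(hess))
    return hess


def fit_map_laplace(
    nll_fn: Callable[[np.ndarray], float],
    prior: GroupPrior,
    n_restarts: int = 5,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float, bool, np.ndarray]:
    """MAP + Laplace evidence for an arbitrary negative log likelihood.

    Minimizes ``nll_fn(theta) - log N(theta | prior)`` from the prior mean
    plus jittered restarts (and optionally a warm start ``x0``), keeps the
    best optimum, and evaluates the Laplace approximation of the log marginal
    likelihood: -penalized(theta*) + (d/2) log 2pi - 1/2 log|H|.

    Returns (theta_map, log_evidence, hessian_logdet, converged,
    posterior_variance_diag).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    d = len(prior.means)
    f = _penalized(nll_fn, prior)
    starts = [prior.means.copy()]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    sd = np.sqrt(prior.variances)
    while len(starts) < n_restarts + (x0 is not None):
        starts.append(prior.means + 0.5 * sd * rng.standard_normal(d))

    best = None
    for s in starts:
        res = optimize.minimize(f, s, method="L-BFGS-B", options={"maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) or np.isfinite(best.fun)
    if not np.isfinite(best.fun):
        return best.x, -np.inf, np.nan, False, np.full(d, np.nan)

    hess = _repair_hessian(_fd_hessian(f, best.x))
    sign, logdet = np.linalg.slogdet(hess)
    if sign <= 0:  # pathological even after ridge repair
        return best.x, -np.inf, np.nan, False, np.full(d, np.nan)
    log_evidence = -best.fun + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    post_var = np.diag(np.linalg.inv(hess))
    return best.x, float(log_evidence), float(logdet), converged, post_var


def fit_subject_map(
    trials: pd.DataFrame,
    model: ModelSpec | str,
    prior: GroupPrior | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    cues: Sequence[CueSpec] = DEFAULT_CUES,
    x0: np.ndarray | None = None,
    subject_id: str | None = None,
) -> SubjectFit:
    """MAP fit of one subject's trial sequence under one model."""
    model = MODELS[model] if isinstance(model, str) else model
    prior = prior or GroupPrior.default(model.n_params)
    arrays = trials_to_arrays(trials, cues)
    if subject_id is None:
        subject_id = str(trials["subject_id"].iloc[0]) if "subject_id" in trials else "?"

    def nll_fn(theta: np.ndarray) -> float:
        params = ParameterVector.from_unconstrained(model.model_id, theta)
        return negative_log_likelihood(params, model, arrays=arrays)

    theta, log_ev, logdet, converged, post_var = fit_map_laplace(
        nll_fn, prior, n_restarts=n_restarts, seed=seed, x0=x0
    )
    return SubjectFit(subject_id, model.model_id, theta, logdet, log_ev, converged, post_var)


def fit_hierarchical(
    dataset: pd.DataFrame,
    model: ModelSpec | str,
    tol: float = 1e-3,
    max_iter: int = 25,
    n_restarts: int = 3,
    seed: int = 0,
    cues: Sequence[CueSpec] = DEFAULT_CUES,
) -> tuple[GroupPrior, list[SubjectFit]]:
    """Empirical-Bayes EM fit of one model across all subjects.

    E-step: per-subject MAP + Laplace curvature under the current group
    prior (warm-started from the previous MAP after the first sweep).
    M-step: group mean = mean of MAPs; group variance = mean of squared
    deviations plus local posterior variances, floored at 1e-4.  Iterates
    until the largest change in the prior falls below ``tol``.  The total
    approximate log evidence is tracked and the EM is monotone-accepting: a
    decrease restores the previous prior and stops (this doubles as the
    divergence guard).
    """
    model = MODELS[model] if isinstance(model, str) else model
    subjects = list(dict.fromkeys(dataset["subject_id"]))
    if len(subjects) < 1:
        raise ValueError("hierarchical fitting needs at least 1 subject")
    arrays = {
        sid: trials_to_arrays(dataset[dataset["subject_id"] == sid], cues)
        for sid in subjects
    }
    prior = GroupPrior.default(model.n_params)
    fits: list[SubjectFit] = []
    prev_evidence = -np.inf
    evidence_path: list[float] = []
    rng = np.random.default_rng(seed)

    for it in range(max_iter):
        new_fits = []
        for j, sid in enumerate(subjects):
            arr = arrays[sid]

            def nll_fn(theta: np.ndarray, _arr=arr) -> float:
                params = ParameterVector.from_unconstrained(model.model_id, theta)
                return negative_log_likelihood(params, model, arrays=_arr)

            warm = fits[j].map_unconstrained if fits else None
            restarts = 1 if fits else n_restarts
            theta, log_ev, logdet, converged, post_var = fit_map_laplace(
                nll_fn, prior, n_restarts=restarts,
                seed=int(rng.integers(2**31 - 1)), x0=warm,
            )
            new_fits.append(
                SubjectFit(sid, model.model_id, theta, logdet, log_ev, converged, post_var)
            )
        total_ev = float(sum(f.log_evidence for f in new_fits))
        if evidence_path and total_ev < prev_evidence - 1e-9:
            logger.info(
                "EM evidence decreased (%.6f -> %.6f) at iter %d; keeping previous prior",
                prev_evidence, total_ev, it,
            )
            break
        fits = new_fits
        evidence_path.append(total_ev)
        prev_evidence = total_ev

        thetas = np.array([f.map_unconstrained for f in fits])
        post_vars = np.array(
            [np.nan_to_num(f.posterior_variance, nan=0.0) for f in fits]
        )
        new_means = thetas.mean(axis=0)
        new_vars = np.maximum(
            ((thetas - new_means) ** 2 + post_vars).mean(axis=0), VARIANCE_FLOOR
        )
        delta = max(
            np.abs(new_means - prior.means).max(),
            np.abs(new_vars - prior.variances).max(),
        )
        prior = GroupPrior(new_means, new_vars)
        if delta < tol:
            break
    prior.evidence_path = evidence_path  # type: ignore[attr-defined]
    return prior, fits


# ---------------------------------------------------------------------------
# Random-effects Bayesian model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelComparisonResult:
    """Random-effects comparison across models."""

    model_ids: tuple[str, ...]
    frequencies: np.ndarray
    exceedance: np.ndarray
    pxp: np.ndarray
    responsibilities: np.ndarray  # subjects x models
    bayes_omnibus_risk: float
    alpha: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_ids,
                "frequency": self.frequencies,
                "exceedance": self.exceedance,
                "pxp": self.pxp,
            }
        )


def _vb_dirichlet(log_evidence: np.ndarray, alpha0: float = 1.0, max_iter: int = 200):
    n, k = log_evidence.shape
    alpha = np.full(k, alpha0)
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        log_u = log_evidence + psi(alpha) - psi(alpha.sum())
        resp_new = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + resp_new.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < 1e-8:
            alpha, resp = alpha_new, resp_new
            break
        alpha, resp = alpha_new, resp_new
    return alpha, resp


def _exceedance(alpha: np.ndarray, n_samples: int, seed: int) -> np.ndarray:
    k = len(alpha)
    if k == 2:
        # P(r1 > r2) = P(r1 > 1/2) under r1 ~ Beta(a1, a2), exact.
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    samples = dirichlet_dist.rvs(alpha, size=n_samples, random_state=rng)
    wins = np.bincount(np.argmax(samples, axis=1), minlength=k)
    return wins / n_samples


def _dirichlet_free_energy(
    log_evidence: np.ndarray, alpha: np.ndarray, resp: np.ndarray, alpha0: float
) -> float:
    k = len(alpha)
    dig = psi(alpha) - psi(alpha.sum())
    e_like = float(np.sum(resp * log_evidence))
    e_assign = float(np.sum(resp * dig))
    entropy_z = -float(np.sum(resp * np.log(np.maximum(resp, 1e-300))))
    a0 = np.full(k, alpha0)
    kl = (
        gammaln(alpha.sum()) - gammaln(alpha).sum()
        - gammaln(a0.sum()) + gammaln(a0).sum()
        + float(np.sum((alpha - a0) * dig))
    )
    return e_like + e_assign + entropy_z - kl


def compare_models(
    log_evidence: np.ndarray | pd.DataFrame,
    model_ids: Sequence[str] | None = None,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> ModelComparisonResult:
    """Random-effects Bayesian model selection over a subjects x models
    evidence matrix.

    Fits a Dirichlet posterior over population model frequencies by
    variational Bayes, computes exceedance probabilities (exact two-model
    Beta form, otherwise Dirichlet Monte Carlo), the Bayes omnibus risk
    BOR = 1 / (1 + exp(F1 - F0)) comparing the frequency model against the
    null of equal frequencies, and PXP = (1 - BOR) * EP + BOR / K.
    """
    if isinstance(log_evidence, pd.DataFrame):
        model_ids = tuple(log_evidence.columns)
        log_evidence = log_evidence.to_numpy(dtype=float)
    log_evidence = np.asarray(log_evidence, dtype=float)
    if log_evidence.ndim != 2:
        raise ValueError("log_evidence must be subjects x models")
    if not np.all(np.isfinite(log_evidence)):
        raise ValueError("log_evidence contains non-finite entries")
    n, k = log_evidence.shape
    if model_ids is None:
        model_ids = tuple(f"M{i + 1}" for i in range(k))
    if k < 2:
        return ModelComparisonResult(
            tuple(model_ids), np.ones(1), np.ones(1), np.ones(1),
            np.ones((n, 1)), 0.0, np.array([alpha0 + n]),
        )
    alpha, resp = _vb_dirichlet(log_evidence, alpha0)
    freq = alpha / alpha.sum()
    ep = _exceedance(alpha, n_samples, seed)
    f1 = _dirichlet_free_energy(log_evidence, alpha, resp, alpha0)
    f0 = float(np.sum(logsumexp(log_evidence, axis=1) - np.log(k)))
    bor = float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))
    pxp = (1.0 - bor) * ep + bor / k
    return ModelComparisonResult(tuple(model_ids), freq, ep, pxp, resp, bor, alpha)


def evidence_matrix(fits_by_model: Mapping[str, Sequence[SubjectFit]]) -> pd.DataFrame:
    """Assemble a subjects x models log-evidence frame from per-model fits."""
    frames = {}
    for model_id, fits in fits_by_model.items():
        frames[model_id] = pd.Series(
            {f.subject_id: f.log_evidence for f in fits}, name=model_id
        )
    df = pd.DataFrame(frames)
    if df.isna().any().any():
        missing = df[df.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing evidences for subjects {missing}")
    return df
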