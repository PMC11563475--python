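"""Trial-file I/O, performance filtering, configuration, and the end-to-end
pipeline.

Trial files are plain CSV, one row per trial, columns
``subject_id,trial,cue,condition,response,outcome,valid`` with 1-based trial
indices and fixed lower-case vocabularies.  All randomness flows from
explicit seeds in the configuration; every output directory carries a
manifest with the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binomtest

from gonogo.fitting import compare_models, evidence_matrix, fit_hierarchical
from gonogo.models import ACTIONS, CONDITIONS, DEFAULT_CUES, MODELS, CueSpec
from gonogo.simulate import CohortSpec, CrossTaskSpec, generate_crosstask_table, simulate_cohort
from gonogo.stats import condition_accuracy, run_mediation_suite
from gonogo.validation import posterior_predictive

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ("subject_id", "trial", "cue", "condition", "response", "outcome", "valid")


def read_trials(path: str | Path, cues: Sequence[CueSpec] = DEFAULT_CUES) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Enforces the schema, vocabularies, outcome legality against cue valence,
    and uniqueness of trial indices per subject; violations are rejected with
    the offending row and column named.
    """
    df = pd.read_csv(path)
    return validate_trials(df, cues)


def validate_trials(df: pd.DataFrame, cues: Sequence[CueSpec] = DEFAULT_CUES) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial data missing columns {missing}")
    valence = {c.cue_id: c.valence for c in cues}
    known_cues = set(valence)

    bad = ~df["cue"].isin(known_cues)
    if bad.any():
        i = int(df.index[bad][0])
        raise ValueError(f"row {i}, column 'cue': unknown cue id {df.loc[i, 'cue']}")
    bad = ~df["response"].isin(ACTIONS)
    if bad.any():
        i = int(df.index[bad][0])
        raise ValueError(f"row {i}, column 'response': {df.loc[i, 'response']!r}")
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        i = int(df.index[bad][0])
        raise ValueError(f"row {i}, column 'condition': {df.loc[i, 'condition']!r}")

    val = df["cue"].map(valence)
    legal = np.where(val == "win", df["outcome"].isin([1, 0]), df["outcome"].isin([0, -1]))
    if not legal.all():
        i = int(df.index[~legal][0])
        raise ValueError(
            f"row {i}, column 'outcome': {df.loc[i, 'outcome']} illegal for "
            f"{val.iloc[i]} cue {df.loc[i, 'cue']}"
        )
    for sid, grp in df.groupby("subject_id"):
        if grp["trial"].duplicated().any():
            dup = int(grp["trial"][grp["trial"].duplicated()].iloc[0])
            raise ValueError(f"subject {sid}: duplicate trial index {dup} in column 'trial'")
        if grp["trial"].min() < 1:
            raise ValueError(f"subject {sid}: column 'trial' must be 1-based")
    counts = df.groupby("subject_id")["trial"].count()
    logger.info("read %d subjects; trials per subject: %s", len(counts), counts.to_dict())
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))


def performance_filter(
    dataset: pd.DataFrame,
    threshold: float | None = None,
    alpha: float = 0.05,
    cues: Sequence[CueSpec] = DEFAULT_CUES,
) -> tuple[list[str], list[str], pd.Series]:
    """Split subjects into retained/excluded by overall accuracy.

    With an explicit ``threshold`` in (0, 1), subjects below it are excluded.
    Without one, the rudimentary check is a one-sided binomial test of
    accuracy against chance (1/3 of three actions): subjects not
    significantly above chance at ``alpha`` are excluded.
    """
    if threshold is not None and not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    req = {c.cue_id: c.required_action for c in cues}
    df = dataset.copy()
    df["correct"] = df["response"] == df["cue"].map(req)
    acc = df.groupby("subject_id")["correct"].mean()
    counts = df.groupby("subject_id")["correct"].agg(["sum", "count"])
    retained, excluded = [], []
    for sid, row in counts.iterrows():
        if threshold is not None:
            ok = acc[sid] >= threshold
        else:
            ok = binomtest(int(row["sum"]), int(row["count"]), 1 / 3,
                           alternative="greater").pvalue < alpha
        (retained if ok else excluded).append(str(sid))
    logger.info("performance filter: retained %s, excluded %s", retained, excluded)
    return retained, excluded, acc


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; all seeds explicit."""

    outdir: str = "gonogo_run"
    trials_path: str | None = None  # load instead of simulate when set
    models: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5", "M6", "M7")
    n_subjects: int = 20
    generating_model: str = "M7"
    group_sd: float = 0.5
    seed: int = 1
    performance_threshold: float | None = None
    filter_alpha: float = 0.05
    fit_tol: float = 1e-3
    fit_max_iter: int = 15
    n_restarts: int = 3
    n_sims: int = 100
    n_boot: int = 10_000
    crosstask_n: int | None = None  # run crosstask/mediation stage when set

    def __post_init__(self) -> None:
        self.models = tuple(self.models)
        unknown = [m for m in self.models if m not in MODELS]
        if unknown:
            raise ValueError(f"unknown model ids {unknown}")
        if self.generating_model not in MODELS:
            raise ValueError(f"unknown generating model {self.generating_model}")
        if self.performance_threshold is not None and not 0 < self.performance_threshold < 1:
            raise ValueError("performance_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Simulate-or-load -> filter -> fit -> compare -> validate -> stats.

    Writes every stage's tables to ``config.outdir`` together with a manifest
    carrying the configuration hash; reruns with the same configuration are
    bit-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.trials_path:
        trials = read_trials(config.trials_path)
    else:
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            model_id=config.generating_model,
            group_sds=config.group_sd,
            seed=config.seed,
        )
        trials, truth = simulate_cohort(spec)
        truth.to_csv(out / "cohort_truth.csv", index=False)
    write_trials(trials, out / "trials.csv")

    retained, excluded, acc = performance_filter(
        trials, config.performance_threshold, config.filter_alpha
    )
    acc.rename("accuracy").to_csv(out / "subject_accuracy.csv")
    trials = trials[trials["subject_id"].isin(retained)]
    if trials["subject_id"].nunique() < 2:
        raise RuntimeError("stage 'filter': fewer than 2 subjects retained")

    fits_by_model = {}
    for i, model_id in enumerate(config.models):
        logger.info("stage 'fit': model %s", model_id)
        _, fits = fit_hierarchical(
            trials, model_id, tol=config.fit_tol, max_iter=config.fit_max_iter,
            n_restarts=config.n_restarts, seed=config.seed + 1000 + i,
        )
        fits_by_model[model_id] = fits
        pd.DataFrame(
            [
                {"subject_id": f.subject_id, "log_evidence": f.log_evidence,
                 "converged": f.converged}
                | dict(zip(MODELS[model_id].parameter_names, f.parameters.native_array()))
                for f in fits
            ]
        ).to_csv(out / f"fits_{model_id}.csv", index=False)

    evidence = evidence_matrix(fits_by_model)
    evidence.to_csv(out / "evidence.csv")
    comparison = compare_models(evidence, seed=config.seed + 2000)
    comparison.as_frame().to_csv(out / "model_comparison.csv", index=False)

    best = comparison.model_ids[int(np.argmax(comparison.pxp))]
    ppc = posterior_predictive(
        fits_by_model[best], trials, n_sims=config.n_sims, seed=config.seed + 3000
    )
    ppc.learning_curves.to_csv(out / "ppc_learning_curves.csv", index=False)
    ppc.condition_pgo.to_csv(out / "ppc_condition_pgo.csv", index=False)
    ppc.repeat_table.to_csv(out / "ppc_repeat.csv", index=False)

    scores = condition_accuracy(trials)
    scores.to_csv(out / "bias_scores.csv", index=False)

    results: dict[str, object] = {
        "retained": retained,
        "excluded": excluded,
        "comparison": comparison,
        "winning_model": best,
        "ppc": ppc,
        "scores": scores,
    }
    if config.crosstask_n:
        table = generate_crosstask_table(
            config.crosstask_n, CrossTaskSpec(), seed=config.seed + 4000
        )
        table.to_csv(out / "crosstask_table.csv", index=False)
        mediation = run_mediation_suite(
            table, n_boot=config.n_boot, seed=config.seed + 5000
        )
        mediation.to_csv(out / "mediation.csv", index=False)
        results["mediation"] = mediation

    manifest = {"config": asdict(config), "config_hash": config.digest(),
                "winning_model": best}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
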