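"""Shared fixtures and the independent brute-force likelihood oracle."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import gonogo
from gonogo.models import DEFAULT_CUES, MODELS, ParameterVector


@pytest.fixture(scope="session")
def m7_params() -> ParameterVector:
    """Group-mean parameters of the winning two-sensitivity model."""
    return ParameterVector.from_native(
        "M7", rho_pos=5.52, rho_neg=1.03, epsilon=0.18, gobias=-0.08, pi=0.25
    )


@pytest.fixture(scope="session")
def m3_params() -> ParameterVector:
    return ParameterVector.from_native(
        "M3", rho=15.37, epsilon=0.08, gobias=0.07, pi=0.34
    )


@pytest.fixture(scope="session")
def m7_session(m7_params) -> pd.DataFrame:
    """One simulated 320-trial session under the winning model."""
    return gonogo.simulate_agent(m7_params, seed=7)


def random_trials(rng: np.random.Generator, n: int, subject_id: str = "s1") -> pd.DataFrame:
    """Random legal trial sequence: random cues, actions, and legal outcomes."""
    cues = rng.choice([c.cue_id for c in DEFAULT_CUES], size=n)
    valence = {c.cue_id: c.valence for c in DEFAULT_CUES}
    cond = {c.cue_id: c.condition for c in DEFAULT_CUES}
    actions = rng.choice(["go_left", "go_right", "nogo"], size=n)
    outcomes = [
        rng.choice([1, 0]) if valence[c] == "win" else rng.choice([0, -1]) for c in cues
    ]
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial": np.arange(1, n + 1),
            "cue": cues,
            "condition": [cond[c] for c in cues],
            "response": actions,
            "outcome": outcomes,
            "valid": 1,
        }
    )


def random_params(rng: np.random.Generator, model_id: str) -> ParameterVector:
    model = MODELS[model_id]
    return ParameterVector.from_unconstrained(
        model_id, rng.normal(0.0, 1.0, model.n_params)
    )


def brute_force_nll(params: ParameterVector, trials: pd.DataFrame) -> float:
    """Naive likelihood recomputation with no incremental state reuse.

    For every trial the Q table is rebuilt from scratch by replaying all
    earlier trials through the bare update equations; choice probabilities
    use a plain (unshifted) softmax.  Independent of the package's sequential
    likelihood path.
    """
    model = params.model
    cue_by_id = {c.cue_id: c for c in DEFAULT_CUES}
    rows = trials.sort_values("trial").to_dict("records")
    total = 0.0
    for t, row in enumerate(rows):
        q = _replay_q(params, rows[:t], cue_by_id)
        cue = cue_by_id[row["cue"]]
        v = 0.5 if cue.valence == "win" else -0.5
        b = params.native.get("gobias", 0.0)
        pi = params.native.get("pi", 0.0)
        w = [
            q[(cue.cue_id, "go_left")] + b + pi * v,
            q[(cue.cue_id, "go_right")] + b + pi * v,
            q[(cue.cue_id, "nogo")],
        ]
        denom = sum(math.exp(wi) for wi in w)
        p = math.exp(w[("go_left", "go_right", "nogo").index(row["response"])]) / denom
        total -= math.log(max(p, 1e-12))
    return total


def _replay_q(params, rows, cue_by_id) -> dict:
    q = {(c, a): 0.0 for c in cue_by_id for a in ("go_left", "go_right", "nogo")}
    model = params.model
    for row in rows:
        cue = cue_by_id[row["cue"]]
        s = gonogo.scale_outcome(model, params, row["outcome"], cue.valence)
        lr = gonogo.effective_learning_rate(model, params, row["outcome"], row["response"])
        key = (cue.cue_id, row["response"])
        q[key] = q[key] + lr * (s - q[key])
    return q
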