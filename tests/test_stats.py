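"""Tests for bias scores, cross-task correlations, and bootstrap mediation."""

import numpy as np
import pandas as pd
import pytest

import gonogo
from gonogo.models import DEFAULT_CUES, ParameterVector
from gonogo.simulate import CrossTaskSpec
from gonogo.stats import MEDIATION_MODELS, mediate, run_mediation_suite, spearman_matrix

from conftest import random_trials


def _session_with_policy(policy, seed=0, n=80):
    """Deterministic session where the response is a function of the cue."""
    rng = np.random.default_rng(seed)
    df = random_trials(rng, n)
    cue_map = {c.cue_id: c for c in DEFAULT_CUES}
    df["response"] = [policy(cue_map[c]) for c in df["cue"]]
    return df


class TestConditionAccuracy:
    def test_perfect_responder_scores_zero_bias(self):
        df = _session_with_policy(lambda cue: cue.required_action)
        scores = gonogo.condition_accuracy(df)
        row = scores.iloc[0]
        assert all(row[c] == 1.0 for c in ("go2win", "go2avoid", "nogo2win", "nogo2avoid"))
        assert row["pavlovian_score"] == 0.0
        assert row["overall_accuracy"] == 1.0

    def test_score_formula_direct_arithmetic(self):
        p = {"go2win": 0.9, "go2avoid": 0.5, "nogo2win": 0.4, "nogo2avoid": 0.8}
        assert gonogo.pavlovian_score(p) == pytest.approx(0.0)
        p = {"go2win": 1.0, "go2avoid": 0.2, "nogo2win": 0.6, "nogo2avoid": 0.9}
        assert gonogo.pavlovian_score(p) == pytest.approx(1.0 - 0.2 + 0.6 - 0.9)

    def test_always_go_responder(self):
        df = _session_with_policy(lambda cue: "go_left")
        scores = gonogo.condition_accuracy(df).iloc[0]
        assert scores["nogo2win"] == 0.0 and scores["nogo2avoid"] == 0.0
        # go conditions: only the left-requiring half of cues is correct
        assert 0.0 < scores["go2win"] < 1.0
        expected = scores["go2win"] - scores["go2avoid"] + 0.0 - 0.0
        assert scores["pavlovian_score"] == pytest.approx(expected)

    def test_empty_condition_is_missing_not_zero(self):
        df = _session_with_policy(lambda cue: cue.required_action)
        df = df[~df["condition"].eq("nogo2win")]
        scores = gonogo.condition_accuracy(df).iloc[0]
        assert np.isnan(scores["nogo2win"])
        assert np.isnan(scores["pavlovian_score"])


class TestSpearmanMatrix:
    def test_identity_and_monotone_reversal(self):
        x = np.arange(20, dtype=float)
        table = pd.DataFrame({"x": x, "same": x.copy(), "rev": -(x**3)})
        res = spearman_matrix(
            table, [("x", "same", "reversal"), ("x", "rev", "twostep")]
        )
        assert res.loc[0, "rs"] == pytest.approx(1.0)
        assert res.loc[1, "rs"] == pytest.approx(-1.0)
        assert res.loc[0, "alpha"] == pytest.approx(0.0125)
        assert res.loc[1, "alpha"] == pytest.approx(0.025)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        t1 = pd.DataFrame({"x": x, "y": y})
        t2 = pd.DataFrame({"x": np.exp(x), "y": y**3 + 5 * y})
        r1 = spearman_matrix(t1, [("x", "y", "reversal")])
        r2 = spearman_matrix(t2, [("x", "y", "reversal")])
        assert r1.loc[0, "rs"] == pytest.approx(r2.loc[0, "rs"], abs=1e-12)

    def test_missing_rows_dropped_pairwise(self):
        x = np.arange(10, dtype=float)
        y = x.copy()
        y[3] = np.nan
        res = spearman_matrix(pd.DataFrame({"x": x, "y": y}), [("x", "y", "twostep")])
        assert res.loc[0, "n"] == 9

    def test_constant_column_flagged_undefined(self):
        table = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        res = spearman_matrix(table, [("x", "y", "reversal")])
        assert not res.loc[0, "defined"]
        assert np.isnan(res.loc[0, "rs"])

    def test_too_few_pairs_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="fewer than 4"):
            spearman_matrix(table, [("x", "y", "reversal")])


class TestMediate:
    def test_full_mediation_by_construction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        m = 0.8 * x + rng.normal(size=60)
        y = 1.5 * m  # y depends on x only through m, no outcome noise
        res = mediate(x, m, y, n_boot=500, seed=0)
        assert res.direct == pytest.approx(0.0, abs=1e-10)
        assert res.proportion_mediated == pytest.approx(1.0, abs=1e-10)

    def test_effect_decomposition_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=93)
        m = 0.5 * x + rng.normal(size=93)
        y = 0.4 * m + 0.3 * x + rng.normal(size=93)
        res = mediate(x, m, y, n_boot=200, seed=0)
        assert res.indirect + res.direct == pytest.approx(res.total, abs=1e-8)

    def test_null_independence_gives_nonsignificant_indirect(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x, m, y = rng.normal(size=(3, 93))
            res = mediate(x, m, y, n_boot=400, seed=seed)
            covered = res.indirect_ci[0] <= 0.0 <= res.indirect_ci[1]
            hits += covered and res.p_indirect > 0.05
        assert hits / reps >= 0.9

    def test_percentile_ci_affine_equivariant_in_y(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        m = 0.5 * x + rng.normal(size=50)
        y = 0.5 * m + rng.normal(size=50)
        r1 = mediate(x, m, y, n_boot=300, seed=4)
        r2 = mediate(x, m, 2.0 * y + 7.0, n_boot=300, seed=4)
        assert r2.indirect_ci[0] == pytest.approx(2 * r1.indirect_ci[0], abs=1e-9)
        assert r2.indirect_ci[1] == pytest.approx(2 * r1.indirect_ci[1], abs=1e-9)
        assert r2.total == pytest.approx(2 * r1.total, abs=1e-9)

    def test_unstable_total_flagged(self):
        rng = np.random.default_rng(5)
        x, m, y = rng.normal(size=(3, 40))
        res = mediate(x, m, y, n_boot=300, seed=0)
        assert res.proportion_unstable

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            mediate(np.ones(5), np.ones(5), np.ones(5))


class TestMediationSuite:
    def test_null_table_all_nonsignificant(self):
        spec = CrossTaskSpec(a=0.0, b=0.0, c_prime=0.0)
        table = gonogo.generate_crosstask_table(93, spec, seed=6)
        res = run_mediation_suite(table, n_boot=400, seed=0)
        assert (res["p_indirect"] > 0.05).mean() >= 0.8

    def test_signs_match_configured_paths(self):
        table = gonogo.generate_crosstask_table(1000, CrossTaskSpec(), seed=7)
        res = run_mediation_suite(table, n_boot=300, seed=0).set_index("y")
        assert res.loc["overall_accuracy", "indirect"] > 0
        assert res.loc["mb_estimate", "indirect"] > 0
        assert res.loc["switch_after_negative", "indirect"] < 0

    def test_deterministic_given_seed(self):
        table = gonogo.generate_crosstask_table(60, seed=8)
        r1 = run_mediation_suite(table, n_boot=200, seed=3)
        r2 = run_mediation_suite(table, n_boot=200, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_column_skipped(self, caplog):
        table = gonogo.generate_crosstask_table(30, seed=9).drop(columns=["mb_estimate"])
        res = run_mediation_suite(table, n_boot=100, seed=0)
        assert "mb_estimate" not in set(res["y"])
        assert len(res) == len(MEDIATION_MODELS) - 1
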