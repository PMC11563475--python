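"""Unit and property tests for the task structure and model likelihoods."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import gonogo
from gonogo.models import DEFAULT_CUES, MODELS, ParameterVector, trials_to_arrays

from conftest import brute_force_nll, random_params, random_trials


class TestCues:
    def test_inventory_covers_all_conditions(self):
        assert len(DEFAULT_CUES) == 8
        conds = {c.condition for c in DEFAULT_CUES}
        assert conds == {"go2win", "go2avoid", "nogo2win", "nogo2avoid"}

    def test_legal_outcomes_by_valence(self):
        for cue in DEFAULT_CUES:
            expected = (1, 0) if cue.valence == "win" else (0, -1)
            assert cue.legal_outcomes == expected


class TestTransforms:
    @pytest.mark.parametrize("model_id", list(MODELS))
    def test_native_unconstrained_round_trip(self, model_id):
        rng = np.random.default_rng(42)
        p = random_params(rng, model_id)
        back = ParameterVector.from_native(model_id, **p.native)
        assert np.allclose(
            back.unconstrained_array(), p.unconstrained_array(), atol=1e-12
        )

    def test_native_constraints(self):
        p = random_params(np.random.default_rng(0), "M7")
        assert p.native["rho_pos"] > 0 and p.native["rho_neg"] > 0
        assert 0 < p.native["epsilon"] < 1

    def test_wrong_parameter_names_rejected(self):
        with pytest.raises(ValueError, match="expects parameters"):
            ParameterVector.from_native("M1", rho=1.0, pi=0.2)


class TestScaleOutcome:
    def test_single_rho_is_direct_product(self):
        p = ParameterVector.from_native("M1", rho=2.0, epsilon=0.1)
        assert gonogo.scale_outcome(MODELS["M1"], p, 1, "win") == 2.0

    def test_m7_desired_and_undesired_recoding(self, m7_params):
        m7 = MODELS["M7"]
        assert gonogo.scale_outcome(m7, m7_params, 1, "win") == pytest.approx(5.52)
        assert gonogo.scale_outcome(m7, m7_params, -1, "avoid") == pytest.approx(-1.03)
        # neutral feedback carries sensitivity in both contexts
        assert gonogo.scale_outcome(m7, m7_params, 0, "win") == pytest.approx(-1.03)
        assert gonogo.scale_outcome(m7, m7_params, 0, "avoid") == pytest.approx(5.52)

    def test_m6_splits_by_cue_valence(self):
        p = ParameterVector.from_native(
            "M6", rho_win=21.06, rho_avoid=12.60, epsilon=0.06, gobias=0.02, pi=0.72
        )
        assert gonogo.scale_outcome(MODELS["M6"], p, 1, "win") == pytest.approx(21.06)
        assert gonogo.scale_outcome(MODELS["M6"], p, -1, "avoid") == pytest.approx(-12.60)

    def test_illegal_outcome_rejected(self, m7_params):
        with pytest.raises(ValueError, match="illegal"):
            gonogo.scale_outcome(MODELS["M7"], m7_params, -1, "win")


class TestEffectiveLearningRate:
    def _m5(self, eps_hat, kappa):
        return ParameterVector.from_unconstrained(
            "M5", {"rho": 0.0, "epsilon": eps_hat, "gobias": 0.0, "pi": 0.0, "kappa": kappa}
        )

    def test_zero_kappa_gives_base_rate(self):
        for eps_hat in (-2.0, 0.0, 1.5):
            p = self._m5(eps_hat, 0.0)
            lr = gonogo.effective_learning_rate(MODELS["M5"], p, 1, "go_left")
            assert lr == pytest.approx(expit(eps_hat), abs=1e-12)

    def test_hand_computed_branch_values(self):
        # eps_hat = -1, kappa = 0.5: eps0 = 0.26894, punished-NoGo rate is
        # invlogit(-1.5), rewarded-Go rate its reflection around eps0
        p = self._m5(-1.0, 0.5)
        m5 = MODELS["M5"]
        assert gonogo.effective_learning_rate(m5, p, -1, "nogo") == pytest.approx(
            0.18242552, abs=1e-7
        )
        assert gonogo.effective_learning_rate(m5, p, 1, "go_right") == pytest.approx(
            0.35545732, abs=1e-7
        )
        assert gonogo.effective_learning_rate(m5, p, 0, "go_left") == pytest.approx(
            0.26894142, abs=1e-7
        )

    @given(
        eps_hat=st.floats(-3, 3), kappa=st.floats(-4, 4)
    )
    @settings(max_examples=50, derandomize=True)
    def test_modulation_symmetric_around_base(self, eps_hat, kappa):
        p = self._m5(eps_hat, kappa)
        m5 = MODELS["M5"]
        eps0 = expit(eps_hat)
        up = gonogo.effective_learning_rate(m5, p, 1, "go_left") - eps0
        down = eps0 - gonogo.effective_learning_rate(m5, p, -1, "nogo")
        # symmetry holds whenever the reflected branch is not clamped
        if 1e-8 < eps0 + up < 1 - 1e-8 and 1e-8 < eps0 - down < 1 - 1e-8:
            assert up == pytest.approx(down, abs=1e-9)

    def test_kappa_free_model_ignores_bias(self, m3_params):
        lr = gonogo.effective_learning_rate(MODELS["M3"], m3_params, 1, "go_left")
        assert lr == pytest.approx(0.08, abs=1e-12)


class TestQUpdate:
    def test_one_step_toward_scaled_outcome(self):
        q = gonogo.update_q(np.zeros((8, 3)), 1, "go_left", 5.52, 0.18)
        assert q[0, 0] == pytest.approx(0.9936)
        assert np.count_nonzero(q) == 1

    def test_zero_scaled_outcome_decays_geometrically(self):
        q0 = np.full((8, 3), 2.0)
        q = gonogo.update_q(q0, 3, "nogo", 0.0, 0.25)
        assert q[2, 2] == pytest.approx(1.5)
        assert q0[2, 2] == 2.0  # input untouched

    def test_degenerate_learning_rate_rejected(self):
        with pytest.raises(ValueError, match="learning rate"):
            gonogo.update_q(np.zeros((8, 3)), 1, "nogo", 1.0, 0.0)


class TestActionWeights:
    def test_win_cue_biases_go_actions(self, m7_params):
        w = gonogo.action_weights(np.zeros((8, 3)), DEFAULT_CUES[0], m7_params, MODELS["M7"])
        assert w == pytest.approx([0.045, 0.045, 0.0])

    def test_avoid_cue_flips_pavlovian_sign(self, m7_params):
        w = gonogo.action_weights(np.zeros((8, 3)), DEFAULT_CUES[2], m7_params, MODELS["M7"])
        assert w == pytest.approx([-0.205, -0.205, 0.0])

    def test_no_bias_reduces_to_q_values(self):
        p = ParameterVector.from_native("M1", rho=3.0, epsilon=0.2)
        q = np.arange(24, dtype=float).reshape(8, 3)
        w = gonogo.action_weights(q, DEFAULT_CUES[4], p, MODELS["M1"])
        assert w == pytest.approx(q[4])


class TestSoftmax:
    def test_symmetric_weights_give_uniform(self):
        assert gonogo.action_probabilities(np.zeros(3)) == pytest.approx([1 / 3] * 3)

    def test_closed_form_value(self):
        p = gonogo.action_probabilities(np.array([1.0, 0.0, 0.0]))
        assert p == pytest.approx([0.57612, 0.21194, 0.21194], abs=1e-5)

    @given(
        w=st.lists(st.floats(-200, 200), min_size=3, max_size=3),
        c=st.floats(-500, 500),
    )
    @settings(max_examples=100, derandomize=True)
    def test_shift_invariance_normalization_positivity(self, w, c):
        w = np.array(w)
        p = gonogo.action_probabilities(w)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0)
        assert np.allclose(p, gonogo.action_probabilities(w + c), atol=1e-12)

    def test_non_finite_weight_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            gonogo.action_probabilities(np.array([np.inf, 0.0, 0.0]))


class TestLikelihood:
    def test_uniform_choice_limit(self, m7_session):
        p = ParameterVector.from_native("M1", rho=1e-300, epsilon=0.1)
        nll = gonogo.negative_log_likelihood(p, trials=m7_session)
        assert nll == pytest.approx(320 * np.log(3), abs=1e-9)

    def test_empty_sequence_is_zero(self, m7_params):
        empty = pd.DataFrame(columns=["trial", "cue", "response", "outcome"])
        assert gonogo.negative_log_likelihood(m7_params, trials=empty) == 0.0

    def test_generating_model_beats_uniform_on_own_data(self, m7_params, m7_session):
        nll = gonogo.negative_log_likelihood(m7_params, trials=m7_session)
        assert nll < 320 * np.log(3)

    @pytest.mark.parametrize("model_id", list(MODELS))
    def test_matches_brute_force_oracle(self, model_id):
        rng = np.random.default_rng(hash(model_id) % 2**31)
        for _ in range(5):
            trials = random_trials(rng, 20)
            params = random_params(rng, model_id)
            fast = gonogo.negative_log_likelihood(params, trials=trials)
            slow = brute_force_nll(params, trials)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_nesting_chain_m5_to_m1(self):
        """Each model reduces to its parent under the nested restriction."""
        rng = np.random.default_rng(123)
        trials = random_trials(rng, 60)
        rho, eps, b, pi = 4.0, 0.2, 0.3, 0.6
        nll = lambda p: gonogo.negative_log_likelihood(p, trials=trials)
        m5 = ParameterVector.from_native("M5", rho=rho, epsilon=eps, gobias=b, pi=pi, kappa=0.0)
        m3 = ParameterVector.from_native("M3", rho=rho, epsilon=eps, gobias=b, pi=pi)
        assert nll(m5) == pytest.approx(nll(m3), abs=1e-12)
        m3z = ParameterVector.from_native("M3", rho=rho, epsilon=eps, gobias=b, pi=0.0)
        m2 = ParameterVector.from_native("M2", rho=rho, epsilon=eps, gobias=b)
        assert nll(m3z) == pytest.approx(nll(m2), abs=1e-12)
        m2z = ParameterVector.from_native("M2", rho=rho, epsilon=eps, gobias=0.0)
        m1 = ParameterVector.from_native("M1", rho=rho, epsilon=eps)
        assert nll(m2z) == pytest.approx(nll(m1), abs=1e-12)

    def test_m7_equal_sensitivities_single_rho_on_recoded_outcomes(self):
        """With rho_pos = rho_neg, the two-sensitivity model is a single-rho
        model applied to the desired/undesired recoding of outcomes."""
        rng = np.random.default_rng(7)
        trials = random_trials(rng, 50)
        rho = 2.5
        m7 = ParameterVector.from_native(
            "M7", rho_pos=rho, rho_neg=rho, epsilon=0.15, gobias=0.1, pi=0.2
        )
        recoded = trials.copy()
        win = recoded["condition"].str.endswith("2win")
        desired = np.where(win, recoded["outcome"] == 1, recoded["outcome"] == 0)
        recoded["outcome"] = np.where(desired, 1, -1)
        # the recoded outcomes are no longer valence-legal, so drive the
        # single-rho likelihood through the kernel arrays directly
        m3 = ParameterVector.from_native("M3", rho=rho, epsilon=0.15, gobias=0.1, pi=0.2)
        arr = list(trials_to_arrays(trials))
        arr[2] = np.where(desired[np.argsort(trials["trial"])], 1, -1).astype(np.int64)
        nll_m7 = gonogo.negative_log_likelihood(m7, trials=trials)
        nll_single = gonogo.negative_log_likelihood(m3, arrays=tuple(arr))
        assert nll_m7 == pytest.approx(nll_single, abs=1e-10)

    def test_q_values_bounded_by_scaled_outcomes(self, m7_params):
        """The delta rule is a contraction: |Q| can never exceed the largest
        scaled outcome magnitude."""
        df = gonogo.simulate_agent(m7_params, seed=21)
        bound = max(5.52, 1.03) + 1e-12
        # replay and track Q explicitly
        q = np.zeros((8, 3))
        model = MODELS["M7"]
        cue_by_id = {c.cue_id: c for c in DEFAULT_CUES}
        for row in df.itertuples():
            s = gonogo.scale_outcome(model, m7_params, row.outcome, cue_by_id[row.cue].valence)
            lr = gonogo.effective_learning_rate(model, m7_params, row.outcome, row.response)
            q = gonogo.update_q(q, row.cue, row.response, s, lr)
            assert np.abs(q).max() <= bound
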