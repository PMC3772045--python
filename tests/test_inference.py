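"""Online inversion: filtering, precision semantics, feedback learning."""

import itertools
import warnings

import numpy as np
import pytest

from shcspeech.cochlea import ReducedStimulus, rescale_time, time_compress
from shcspeech.dynamics import (
    SimulationConfig,
    default_model,
    simulate_hierarchy,
)
from shcspeech.inference import (
    InferenceSettings,
    PosteriorTrajectory,
    PrecisionConfig,
    error_summary,
    generalized_precision,
    infer_states,
    learn_feedback,
    precision_to_sd,
    recognition_accuracy,
)
from shcspeech.synth import make_word

from conftest import FAST, model_from_profiles


class TestPrecisionToSd:
    @pytest.mark.parametrize(
        "logpi,expected",
        [(0.0, 1.0), (2.0, np.exp(-1)), (-2.0, np.exp(1))],
    )
    def test_closed_form(self, logpi, expected):
        assert precision_to_sd(logpi) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            precision_to_sd(np.inf)


class TestGeneralizedPrecision:
    def test_inverse_of_derivative_covariance(self):
        R = generalized_precision(2, 0.5)
        # covariance of (value, first, second derivative) for Gaussian
        # autocorrelation with s = 0.5: diag-ish with C01 = 0, C11 = 4 ...
        C = np.array([[1.0, 0.0, -4.0], [0.0, 4.0, 0.0], [-4.0, 0.0, 48.0]])
        assert np.allclose(R @ C, np.eye(3), atol=1e-12)


class TestRecognitionAccuracy:
    @pytest.mark.parametrize(
        "base,test,expected", [(5.0, 5.0, 0.0), (3.0, 0.0, 100.0), (200.0, 50.0, 75.0)]
    )
    def test_formula(self, base, test, expected):
        assert recognition_accuracy(base, test) == pytest.approx(expected)

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            recognition_accuracy(0.0, 1.0)


class TestInferStates:
    def test_self_recognition_reconstructs_visit_order(self, self_generated):
        m, z, latents = self_generated
        traj = infer_states(m, PrecisionConfig.clean_recognition(), z, settings=FAST)
        order = [int(k) for k, _ in itertools.groupby(np.argmax(traj.mu_v2, axis=0))]
        true_order = [
            int(k) for k, _ in itertools.groupby(np.argmax(latents["v2"], axis=0))
        ]
        assert order[: len(true_order)] == true_order

    def test_self_consistency_low_sensory_error(self, self_generated):
        m, z, _ = self_generated
        matched = infer_states(m, PrecisionConfig.clean_recognition(), z, settings=FAST)
        other = model_from_profiles(5)
        mismatched = infer_states(
            other, PrecisionConfig.clean_recognition(), z, settings=FAST
        )
        assert np.sum(matched.err_v1) < 0.25 * np.sum(mismatched.err_v1)

    def test_filter_causality_exact_prefix(self, trained_module):
        mod, z = trained_module
        pc = PrecisionConfig.clean_recognition()
        full = infer_states(mod.model, pc, z, settings=FAST)
        part = infer_states(
            mod.model, pc, ReducedStimulus(z.values[:, :60]), settings=FAST
        )
        assert np.array_equal(full.mu_x1[:, :60], part.mu_x1)
        assert np.array_equal(full.mu_v2[:, :60], part.mu_v2)
        assert np.array_equal(full.err_v1[:60], part.err_v1)

    def test_step_size_refinement_stability(self, trained_module):
        """Halving the gradient-flow step preserves totals to a few
        percent and never flips the matched/mismatched comparison."""
        mod, z = trained_module
        other = model_from_profiles(6)
        pc = PrecisionConfig.clean_recognition()
        totals = {}
        for ni in (4, 8):
            st = InferenceSettings(n_inner=ni)
            em = error_summary(infer_states(mod.model, pc, z, settings=st))
            eo = error_summary(infer_states(other, pc, z, settings=st))
            totals[ni] = (em["v1"], eo["v1"])
        for a, b in zip(totals[4], totals[8]):
            assert abs(a - b) / b < 0.05
        assert totals[4][0] < totals[4][1] and totals[8][0] < totals[8][1]

    def test_time_compressed_stimulus_same_winner_faster_sequence(
        self, trained_module
    ):
        mod, z = trained_module
        other = model_from_profiles(7)
        pc = PrecisionConfig.clean_recognition()
        zc = time_compress(z, 0.75)
        em = error_summary(infer_states(mod.model, pc, zc, settings=FAST))
        eo = error_summary(infer_states(other, pc, zc, settings=FAST))
        assert em["v1"] < eo["v1"]
        # dominance handovers arrive earlier than on the uncompressed token
        tr_c = infer_states(mod.model, pc, zc, settings=FAST)
        tr_n = infer_states(mod.model, pc, z, settings=FAST)

        def kth_handover(traj, k):
            dom = np.argmax(traj.mu_v2, axis=0)
            t, seen = 0, 0
            for _, grp in itertools.groupby(dom):
                t += len(list(grp))
                seen += 1
                if seen == k:
                    return t
            return t

        assert kth_handover(tr_c, 6) <= kth_handover(tr_n, 6)

    def test_dimension_mismatch_rejected(self, self_generated):
        m, z, _ = self_generated
        with pytest.raises(ValueError):
            infer_states(
                m,
                PrecisionConfig.clean_recognition(),
                np.zeros((5, 100)),
                settings=FAST,
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_self_recognition_order_across_models(self, seed):
        m = model_from_profiles(100 + seed)
        z, latents = simulate_hierarchy(m, SimulationConfig(T=100, seed=0))
        traj = infer_states(m, PrecisionConfig.clean_recognition(), z, settings=FAST)
        order = [int(k) for k, _ in itertools.groupby(np.argmax(traj.mu_v2, axis=0))]
        true_order = [
            int(k) for k, _ in itertools.groupby(np.argmax(latents["v2"], axis=0))
        ]
        assert order[: len(true_order)] == true_order


class TestErrorSummary:
    def test_totals_equal_bruteforce_sums(self, trained_module):
        mod, z = trained_module
        traj = infer_states(
            mod.model, PrecisionConfig.clean_recognition(), z, settings=FAST
        )
        es = error_summary(traj)
        assert es["v1"] == pytest.approx(float(np.sum(traj.err_v1)))
        assert es["x1"] == pytest.approx(float(np.sum(traj.err_x1)))
        assert es["v2"] == pytest.approx(float(np.sum(traj.err_v2)))
        assert es["x2"] == pytest.approx(float(np.sum(traj.err_x2)))
        assert es["all"] == pytest.approx(es["v1"] + es["x1"] + es["v2"] + es["x2"])

    def test_zero_series_zero_totals(self):
        T = 10
        traj = PosteriorTrajectory(
            mu_x1=np.zeros((6, T)),
            mu_v1=np.zeros((6, T)),
            mu_x2=np.zeros((8, T)),
            mu_y2=np.zeros((8, T)),
            mu_v2=np.zeros((8, T)),
            err_v1=np.zeros(T),
            err_x1=np.zeros(T),
            err_v2=np.zeros(T),
            err_x2=np.zeros(T),
            free_action=0.0,
        )
        es = error_summary(traj)
        assert all(es[k] == 0.0 for k in ("v1", "x1", "v2", "x2", "all", "score"))

    def test_unknown_score_rejected(self, trained_module):
        mod, z = trained_module
        traj = infer_states(
            mod.model, PrecisionConfig.clean_recognition(), z, settings=FAST
        )
        with pytest.raises(ValueError):
            error_summary(traj, score="nope")


class TestLearnFeedback:
    def test_zero_reps_is_noop(self, self_generated):
        m, z, _ = self_generated
        m2 = default_model()
        I_before = m2.fb.I.copy()
        rec = learn_feedback(m2, PrecisionConfig.learning(), z, max_reps=0)
        assert rec.error_curve == [] and rec.converged_at is None
        assert np.array_equal(m2.fb.I, I_before)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_generating_weights(self, seed):
        m_true = model_from_profiles(200 + seed)
        z, _ = simulate_hierarchy(m_true, SimulationConfig(T=100, seed=0))
        m = default_model()
        rec = learn_feedback(m, PrecisionConfig.learning(), z)
        rel = np.linalg.norm(m.fb.I - m_true.fb.I) / np.linalg.norm(m_true.fb.I)
        assert rel < 0.1
        assert rec.converged_at is not None and rec.converged_at <= 8

    def test_error_curve_nonincreasing_within_tolerance(self, word_specs):
        z = make_word(word_specs[4], token_seed=11)
        m = default_model()
        rec = learn_feedback(m, PrecisionConfig.learning(), z)
        c = np.array(rec.error_curve)
        assert np.all(c[1:] <= c[:-1] * 1.01)

    def test_recognition_preset_does_not_adapt(self, word_specs):
        """Low sensory/internal ratio: accumulated error stays within 10%
        of its initial value (no adaptation)."""
        z = make_word(word_specs[5], token_seed=12)
        m = default_model()
        with pytest.warns(UserWarning, match="ratio"):
            rec = learn_feedback(
                m, PrecisionConfig.noisy_recognition(), z, max_reps=6
            )
        c = rec.error_curve
        assert abs(c[-1] - c[0]) / c[0] < 0.10

    def test_precision_ratio_monotonicity(self, word_specs):
        """Achieved error reduction during adaptation increases with the
        first-level sensory/internal precision ratio (rank order)."""
        from scipy.stats import spearmanr

        z = make_word(word_specs[6], token_seed=13)
        base = default_model()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            learn_feedback(base, PrecisionConfig.learning(), z, settings=FAST)
        from shcspeech.synth import accent_perturb
        from shcspeech.dynamics import GenerativeModel

        acc = accent_perturb(word_specs[6], 0.25, seed=3)
        z_acc = make_word(acc, token_seed=14)

        def regen_mse(model):
            out, _ = simulate_hierarchy(model, SimulationConfig(T=100, seed=0))
            return float(np.mean((out - z_acc.values) ** 2))

        mse_pre = regen_mse(base)
        ratios = [-6.0, -2.0, 2.0, 6.0]
        reductions = []
        for r in ratios:
            pca = PrecisionConfig(5 + r / 2, 5 - r / 2, 7.0, 7.0)
            m = GenerativeModel.from_dict(base.to_dict())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                learn_feedback(m, pca, z_acc, max_reps=5, settings=FAST)
            reductions.append((mse_pre - regen_mse(m)) / mse_pre)
        rho, _ = spearmanr(ratios, reductions)
        assert rho >= 0.75
        assert reductions[-1] > 5 * max(reductions[0], 0.01)
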