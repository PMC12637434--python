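"""Encoding model: F statistic, penalized fits, recovery, nulls."""

import numpy as np
import pytest

from revalue.neural.design import zscore_binned_spikes
from revalue.neural.encoding import (
    BilinearEncodingModel,
    EncodingConfig,
    LinearEncodingModel,
    _ridge_path_cv,
    corrected_delta_r2,
    encoding_trial_folds,
    f_compare,
)
from revalue.neural.synth import GroundTruthNeuron, generate_neuron_spikes, random_kernel
from revalue.neural.timeline import TimelineConfig, build_event_timeline
from revalue.values import detrend_trial_variable


@pytest.fixture(scope="module")
def small_timeline(small_session):
    return build_event_timeline(small_session, TimelineConfig(t_post=3.2))


@pytest.fixture(scope="module")
def small_U(small_trajectories):
    return np.column_stack(
        [
            detrend_trial_variable(small_trajectories["delta_q"].to_numpy()),
            detrend_trial_variable(small_trajectories["v"].to_numpy()),
        ]
    )


@pytest.fixture(scope="module")
def folds(small_session):
    return encoding_trial_folds(small_session, 5, np.random.default_rng(0))


@pytest.fixture(scope="module")
def desk_config():
    return EncodingConfig(
        alphas_l1=np.logspace(-5, 5, 21),
        alphas_l2=np.logspace(-5, 5, 101),
        lasso_max_iter=200,
    )


class TestFStatistic:
    def test_hand_computed_fixture(self):
        """SSE_red = 12, SSE_full = 8, dDOF = 2, n = 10 -> F = 2.5."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=10)
        # construct predictions with exact SSEs
        e = rng.normal(size=10)
        e /= np.linalg.norm(e)
        pred_full = y - np.sqrt(8.0) * e
        pred_red = y - np.sqrt(12.0) * e
        st = f_compare(y, pred_full, pred_red, delta_dof=2)
        assert st.f == pytest.approx(2.5, abs=1e-12)
        assert st.sse_full == pytest.approx(8.0)
        assert st.sse_reduced == pytest.approx(12.0)

    def test_identical_predictions_give_zero(self):
        y = np.arange(6.0)
        pred = y + 0.5
        assert f_compare(y, pred, pred, 3).f == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        pf = y + 0.3 * rng.normal(size=50)
        pr = y + 0.5 * rng.normal(size=50)
        f1 = f_compare(y, pf, pr, 2).f
        c = 3.7
        f2 = f_compare(c * y, c * pf, c * pr, 2).f
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_invalid_ddof(self):
        y = np.zeros(3)
        with pytest.raises(ValueError):
            f_compare(y, y, y, 0)

    def test_corrected_delta_r2(self):
        assert corrected_delta_r2(0.05, [0.05]) == 0.0
        assert corrected_delta_r2(0.05, [0.01, 0.03]) == pytest.approx(0.03)
        with pytest.raises(ValueError):
            corrected_delta_r2(0.1, [])


class TestRidgePath:
    def test_matches_sklearn_ridge(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 8))
        beta = rng.normal(size=8)
        y = X @ beta + 0.5 * rng.normal(size=200)
        fold = np.repeat(np.arange(5), 40)
        fit = _ridge_path_cv(X, y, fold, np.logspace(-3, 3, 25))
        sk = Ridge(alpha=fit.alpha, fit_intercept=False).fit(X, y)
        np.testing.assert_allclose(fit.coef, sk.coef_, atol=1e-8)


class TestLinearRecovery:
    def test_noiseless_neuron_recovered(self, small_session, small_timeline, folds, desk_config):
        """A noiseless neuron whose kernels lie in the basis span is
        recovered with held-out R2 > 0.99."""
        rng = np.random.default_rng(7)
        kernels = {e: random_kernel(e, rng) for e in ("go", "cs_plus", "cs_minus")}
        neuron = GroundTruthNeuron(
            kernels=kernels,
            gain_offsets={e: 1.0 for e in kernels},
            gain_coefs={e: np.zeros(0) for e in kernels},
            noise_sd=0.0,
        )
        counts = generate_neuron_spikes(neuron, small_timeline, None, seed=1)
        sp = zscore_binned_spikes(counts, small_timeline.coverage)
        fit = LinearEncodingModel(
            sp, small_timeline, folds, config=desk_config, include_history=False
        ).fit()
        assert fit.r2_cv > 0.99
        # kernel shape recovered up to the z-scoring scale factor
        k_true = kernels["go"]
        k_fit = fit.kernels["go"]
        corr = np.corrcoef(k_true, k_fit)[0, 1]
        assert corr > 0.99

    def test_pure_noise_neuron_r2_near_zero(self, small_timeline, folds, desk_config):
        rng = np.random.default_rng(8)
        counts = rng.normal(size=(small_timeline.n_trials, small_timeline.n_bins))
        sp = zscore_binned_spikes(counts, small_timeline.coverage)
        fit = LinearEncodingModel(
            sp, small_timeline, folds, config=desk_config, include_history=False
        ).fit()
        assert abs(fit.r2_cv) < 0.02

    def test_huge_penalty_zeroes_coefficients(self, small_timeline, folds):
        rng = np.random.default_rng(9)
        counts = rng.normal(size=(small_timeline.n_trials, small_timeline.n_bins))
        sp = zscore_binned_spikes(counts, small_timeline.coverage)
        cfg = EncodingConfig(alphas_l1=np.array([1e5]), alphas_l2=np.logspace(-5, 5, 11))
        fit = LinearEncodingModel(
            sp, small_timeline, folds, config=cfg, include_history=False
        ).fit()
        assert np.abs(fit.coef).max() == 0.0


class TestBilinear:
    def test_gain_sign_recovered(self, small_timeline, small_U, folds, desk_config):
        """A neuron with a positive relative-value gain on the go-cue kernel
        yields a positive fitted go-cue gain coefficient."""
        rng = np.random.default_rng(11)
        events = ("go", "move_L", "move_R", "cs_plus", "cs_minus")
        kernels = {e: random_kernel(e, rng) for e in events}
        coefs = {e: np.zeros(2) for e in events}
        coefs["go"][0] = 0.6
        neuron = GroundTruthNeuron(
            kernels=kernels,
            gain_offsets={e: 1.0 for e in events},
            gain_coefs=coefs,
            noise_sd=0.3,
        )
        counts = generate_neuron_spikes(neuron, small_timeline, small_U, seed=2)
        sp = zscore_binned_spikes(counts, small_timeline.coverage)
        fit = BilinearEncodingModel(
            sp, small_timeline, small_U, folds, var_names=["dq", "v"],
            config=desk_config, include_history=False,
        ).fit()
        # sign convention: fitted kernel may be flipped relative to ground
        # truth (unit-norm leaves a sign ambiguity); compare the product
        k_sign = np.sign(np.dot(fit.kernels["go"], kernels["go"]))
        assert k_sign * fit.gain_coefs["go"][0] > 0
        assert abs(fit.gain_coefs["go"][0]) > abs(fit.gain_coefs["go"][1])

    def test_refit_gains_reproduces_full_model(self, small_timeline, small_U, folds, desk_config):
        rng = np.random.default_rng(12)
        counts = rng.normal(size=(small_timeline.n_trials, small_timeline.n_bins))
        sp = zscore_binned_spikes(counts, small_timeline.coverage)
        fit = BilinearEncodingModel(
            sp, small_timeline, small_U, folds, config=desk_config,
            include_history=False,
        ).fit()
        full = fit.refit_gains(small_U, drop=None, reselect_alpha=False)
        red = fit.refit_gains(small_U, drop=[0, 1], reselect_alpha=False)
        assert full.n_predictors - red.n_predictors == 12  # 6 kernels x 2 vars
        assert np.isfinite(full.r2_cv) and np.isfinite(red.r2_cv)

    def test_p_value_definition_real_below_all_nulls(self):
        """If the real F is below every null F the empirical p is 1."""
        null_f = np.array([1.0, 2.0, 3.0])
        p = float(np.mean(null_f > 0.5))
        assert p == 1.0
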