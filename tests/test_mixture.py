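import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm
from sklearn.base import clone
from sklearn.mixture import GaussianMixture

from gmmdenoise.errors import DegenerateDataError, NoErrorComponentError
from gmmdenoise.io import ASVTable
from gmmdenoise.mixture import (
    GMMDenoiser,
    GMMFit,
    _em_run,
    component_cl,
    em_fit,
    filtering_threshold,
    log_abundance,
    mixture_loglik,
    responsibilities,
    sample_mixture,
)


def make_fit(means, sds, weights):
    return GMMFit(k=len(means), means=np.asarray(means, float),
                  sds=np.asarray(sds, float), weights=np.asarray(weights, float),
                  loglik=-1.0, n_iter=1, converged=True, data_n=100)


def two_mode_sample(rng, n=2000, w=0.7, mu=(0.3, 4.0), sd=(0.25, 0.4)):
    low = rng.random(n) < w
    return np.where(low, rng.normal(mu[0], sd[0], n), rng.normal(mu[1], sd[1], n))


class TestLogAbundance:
    def test_log10_values(self):
        table = ASVTable(["a", "b", "c", "d"], np.array([[1], [1000], [5], [50]]),
                         ["s"])
        np.testing.assert_allclose(log_abundance(table),
                                   [0.0, 3.0, 0.69897, 1.69897], atol=1e-5)

    def test_total_below_one_rejected(self):
        table = ASVTable(["a"], np.array([[0]]), ["s"])
        with pytest.raises(ValueError, match="'a'"):
            log_abundance(table)


class TestEMFit:
    def test_k1_equals_closed_form_gaussian_mle(self, rng):
        x = rng.normal(2.0, 0.8, 137)
        fit = em_fit(x, 1)
        assert abs(fit.means[0] - x.mean()) < 1e-10
        assert abs(fit.sds[0] - x.std()) < 1e-10  # ML (divide-by-n) SD
        assert fit.weights[0] == 1.0

    def test_two_component_parameter_recovery(self, rng):
        x = two_mode_sample(rng)
        fit = em_fit(x, 2, seed=0)
        np.testing.assert_allclose(fit.means, [0.3, 4.0], atol=0.05)
        np.testing.assert_allclose(fit.weights, [0.7, 0.3], atol=0.03)

    def test_reported_loglik_matches_direct_density_sum(self, rng):
        """Brute-force check: loglik == sum_i log sum_j w_j phi((x-mu_j)/s_j)/s_j."""
        x = two_mode_sample(rng, n=400)
        fit = em_fit(x, 2, seed=0)
        direct = np.log(sum(
            w * norm.pdf(x, m, s)
            for m, s, w in zip(fit.means, fit.sds, fit.weights)
        )).sum()
        assert abs(fit.loglik - direct) < 1e-9

    def test_loglik_never_decreases_across_iterations(self, rng):
        x = two_mode_sample(rng, n=600, mu=(0.0, 1.5), sd=(0.6, 0.6))
        history = []
        _em_run(x, np.array([0.2, 1.0]), np.array([0.7, 0.7]),
                np.array([0.5, 0.5]), 1e-10, 500, 0.01, history=history)
        diffs = np.diff(history)
        assert (diffs >= -1e-8).all()

    def test_permuted_initialisation_labels_give_same_canonical_fit(self, rng):
        x = two_mode_sample(rng, n=800)
        kw = dict(tol=1e-10, max_iter=2000, sd_floor=0.01)
        a = _em_run(x, np.array([0.0, 4.0]), np.array([0.5, 0.5]),
                    np.array([0.4, 0.6]), **kw)
        b = _em_run(x, np.array([4.0, 0.0]), np.array([0.5, 0.5]),
                    np.array([0.6, 0.4]), **kw)
        np.testing.assert_allclose(np.sort(a[0]), np.sort(b[0]), atol=1e-6)
        np.testing.assert_allclose(np.sort(a[2]), np.sort(b[2]), atol=1e-6)

    def test_agrees_with_sklearn_reference_implementation(self, rng):
        """Independent cross-check against sklearn's GaussianMixture."""
        x = two_mode_sample(rng, n=1500)
        fit = em_fit(x, 2, seed=0, sd_floor=1e-6)
        ref = GaussianMixture(2, covariance_type="spherical", tol=1e-8,
                              max_iter=1000, n_init=3, random_state=0)
        ref.fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(fit.means, ref.means_.ravel()[order], atol=0.02)
        np.testing.assert_allclose(fit.weights, ref.weights_[order], atol=0.02)
        ref_ll = ref.score(x[:, None]) * x.size
        assert fit.loglik >= ref_ll - 1.0

    def test_sd_floor_applies_to_tied_data(self):
        x = np.concatenate([np.zeros(300), np.full(40, 4.0) +
                            np.linspace(-0.3, 0.3, 40)])
        fit = em_fit(x, 2, seed=0, sd_floor=0.1)
        assert (fit.sds >= 0.1).all()

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least 10"):
            em_fit(np.arange(8.0), 2)

    def test_all_equal_data_degenerate(self):
        with pytest.raises(DegenerateDataError):
            em_fit(np.ones(50), 2)


class TestResponsibilities:
    def test_k1_all_ones(self, rng):
        fit = em_fit(rng.normal(0, 1, 50), 1)
        np.testing.assert_array_equal(responsibilities(fit, rng.normal(0, 1, 7)), 1.0)

    def test_rows_sum_to_one_and_limit_case(self):
        fit = make_fit([0.0, 5.0], [1.0, 1.0], [0.5, 0.5])
        r = responsibilities(fit, np.array([-50.0, 0.0, 5.0]))
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-12)
        assert r[0, 0] > 1 - 1e-12  # far below both means: lower component wins

    def test_matches_hand_computed_bayes_rule(self):
        fit = make_fit([0.0, 2.0], [0.5, 1.0], [0.3, 0.7])
        x = np.array([-0.2, 1.0, 3.5])
        num0 = 0.3 * norm.pdf(x, 0.0, 0.5)
        num1 = 0.7 * norm.pdf(x, 2.0, 1.0)
        expected = np.stack([num0, num1], axis=1)
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(responsibilities(fit, x), expected, atol=1e-12)


class TestConfidenceLimits:
    def test_standard_normal_95(self):
        fit = make_fit([0.0], [1.0], [1.0])
        assert component_cl(fit, 0.95).cls[0] == pytest.approx(1.6449, abs=1e-4)

    def test_level_half_returns_mean(self):
        fit = make_fit([2.7], [0.4], [1.0])
        assert component_cl(fit, 0.5).cls[0] == pytest.approx(2.7, abs=1e-12)

    def test_scaled_component(self):
        fit = make_fit([2.0], [0.5], [1.0])
        assert component_cl(fit, 0.95).cls[0] == pytest.approx(2.8224, abs=1e-4)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.1, 1.7])
    def test_invalid_level(self, level):
        with pytest.raises(ValueError):
            component_cl(make_fit([0.0], [1.0], [1.0]), level)


class TestFilteringThreshold:
    def test_k2_closed_form(self):
        fit = make_fit([1.0, 4.0], [0.3, 0.5], [0.5, 0.5])
        assert filtering_threshold(fit) == pytest.approx(1.0 + 1.6449 * 0.3, abs=1e-4)

    def test_k3_uses_middle_component(self):
        fit = make_fit([0.5, 2.0, 4.5], [0.2, 0.4, 0.3], [1 / 3] * 3)
        assert filtering_threshold(fit) == pytest.approx(2.0 + 1.6449 * 0.4, abs=1e-4)

    def test_level_half_is_second_uppermost_mean(self):
        fit = make_fit([1.0, 4.0], [0.3, 0.5], [0.5, 0.5])
        assert filtering_threshold(fit, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_k1_has_no_error_component(self):
        with pytest.raises(NoErrorComponentError):
            filtering_threshold(make_fit([1.0], [0.3], [1.0]))

    @given(st.lists(st.floats(0.55, 0.99), min_size=2, max_size=6))
    def test_increasing_in_level(self, levels):
        fit = make_fit([1.0, 4.0], [0.3, 0.5], [0.5, 0.5])
        thresholds = [filtering_threshold(fit, lv) for lv in sorted(levels)]
        assert all(b >= a for a, b in zip(thresholds, thresholds[1:]))


class TestGMMFitInvariants:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to one"):
            make_fit([0.0, 1.0], [1.0, 1.0], [0.6, 0.6])

    def test_components_must_be_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            make_fit([2.0, 1.0], [1.0, 1.0], [0.5, 0.5])

    def test_json_round_trip(self, rng):
        fit = em_fit(rng.normal(0, 1, 60), 1)
        back = GMMFit.from_dict(fit.to_dict())
        np.testing.assert_allclose(back.means, fit.means)
        assert back.loglik == fit.loglik


class TestGMMDenoiserEstimator:
    def test_sklearn_protocol(self, rng):
        est = GMMDenoiser(n_components=2, random_state=0)
        cloned = clone(est)
        assert cloned.get_params()["n_components"] == 2
        x = two_mode_sample(rng, n=500)
        est.fit(x[:, None])  # column vectors accepted
        assert est.threshold_ is not None
        assert est.predict(np.array([0.0, 4.0])).tolist() == [0, 1]
        assert est.score(x) == pytest.approx(est.loglik_ / x.size)

    def test_k1_has_no_threshold(self, rng):
        est = GMMDenoiser(n_components=1).fit(rng.normal(0, 1, 100))
        assert est.threshold_ is None
        with pytest.raises(NoErrorComponentError):
            est.retain_mask(np.zeros(3))

    def test_retain_mask_equality_retains(self, rng):
        est = GMMDenoiser(n_components=2, random_state=0).fit(two_mode_sample(rng))
        mask = est.retain_mask(np.array([est.threshold_]))
        assert mask.tolist() == [True]

    def test_separates_simulated_true_and_error_variants(self, sim_result):
        """On simulated metabarcoding data a 2-component fit should put nearly
        all true variants above the threshold and the bulk of errors below."""
        x = log_abundance(sim_result.table)
        est = GMMDenoiser(n_components=2, random_state=0).fit(x)
        tru = x[sim_result.is_true]
        err = x[~sim_result.is_true]
        assert (tru >= est.threshold_).mean() > 0.95
        assert (err < est.threshold_).mean() > 0.5


class TestSampleMixture:
    def test_moments_match_fit(self, rng):
        fit = make_fit([0.0, 10.0], [0.5, 0.5], [0.5, 0.5])
        draws = sample_mixture(fit, 20_000, rng)
        assert abs(draws.mean() - 5.0) < 0.15
        assert abs(mixture_loglik(fit, draws) / draws.size -
                   np.mean(np.log(0.5 * norm.pdf(draws, 0, 0.5)
                                  + 0.5 * norm.pdf(draws, 10, 0.5)))) < 1e-9
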