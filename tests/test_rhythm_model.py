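"""Discretization, empirical frequencies, mixture EM, and KS goodness
of fit, each checked against an independent route (closed forms, grid
search, quadrature, scipy)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.special import ndtr

from chronocall import (
    ChronotypeProfile,
    MixtureFit,
    discretize,
    empirical_frequency,
    fit_gmm,
    ks_goodness_of_fit,
    mixture_cdf,
    mixture_pdf,
    model_profile,
    observed_call_hours,
    sample_call_times,
    select_k_bic,
)
from chronocall.rhythm_model import RhythmError, ks_statistic

from conftest import make_records

TRUE = ChronotypeProfile(peaks=(10.0, 18.0), spreads=(1.5, 1.5), weight=0.7, daily_rate=2.0)


def circdist(a, b):
    d = np.abs(a - b) % 24.0
    return np.minimum(d, 24.0 - d)


def make_fit(means, sigmas, weights, wrapped=True):
    means = np.asarray(means, float)
    return MixtureFit(
        K=len(means),
        means=means,
        variances=np.asarray(sigmas, float) ** 2,
        weights=np.asarray(weights, float),
        loglik_trace=np.array([0.0]),
        converged=True,
        n_obs=1,
        wrapped=wrapped,
    )


class TestDiscretize:
    def test_half_open_bins(self):
        rs = make_records([
            ("a", "2020-01-01T09:05:00", "out"),
            ("a", "2020-01-01T09:59:59", "out"),
            ("a", "2020-01-01T10:00:00", "out"),
            ("a", "2020-01-01T11:00:00", "in"),  # incoming ignored
        ])
        counts = discretize(rs, "a")
        assert counts.shape == (24,)
        assert counts[9] == 2 and counts[10] == 1 and counts.sum() == 3

    def test_conservation_on_synthetic_person(self, default_cohort):
        records, _ = default_cohort
        pid = records.persons[0]
        n_out = int(
            (
                (records.frame["person_id"] == pid)
                & (records.frame["direction"] == "out")
            ).sum()
        )
        assert discretize(records, pid).sum() == n_out

    def test_unknown_person(self, default_cohort):
        records, _ = default_cohort
        with pytest.raises(Exception, match="unknown person"):
            discretize(records, "nobody")


class TestEmpiricalFrequency:
    def test_point_mass(self):
        counts = np.zeros(24, int)
        counts[10] = 5
        prof = empirical_frequency(counts)
        assert prof.freqs[10] == 1.0 and prof.freqs.sum() == 1.0

    def test_uniform(self):
        prof = empirical_frequency(np.ones(24, int))
        assert np.allclose(prof.freqs, 1 / 24)

    def test_hand_division(self):
        counts = np.zeros(24, int)
        counts[0], counts[1], counts[23] = 3, 1, 4
        prof = empirical_frequency(counts)
        assert prof.freqs[0] == 0.375
        assert prof.freqs[1] == 0.125
        assert prof.freqs[23] == 0.5
        assert prof.freqs[2:23].sum() == 0.0

    def test_zero_total_flagged(self):
        prof = empirical_frequency(np.zeros(24, int))
        assert prof.empty and prof.freqs.sum() == 0.0

    def test_invalid_input(self):
        with pytest.raises(RhythmError):
            empirical_frequency(np.array([1, 2, 3]))
        bad = np.zeros(24, int)
        bad[3] = -1
        with pytest.raises(RhythmError):
            empirical_frequency(bad)

    @given(st.lists(st.integers(0, 1000), min_size=24, max_size=24))
    def test_normalization_property(self, counts):
        prof = empirical_frequency(np.array(counts))
        if prof.total > 0:
            assert abs(prof.freqs.sum() - 1.0) < 1e-12
            assert np.allclose(prof.freqs * prof.total, prof.counts)


class TestMidpointPlacement:
    def test_hour_resolution_goes_to_midpoints(self):
        rs = make_records([("a", "2020-01-01T09:00:00", "out"),
                           ("a", "2020-01-01T14:00:00", "out")])
        assert np.allclose(observed_call_hours(rs, "a"), [9.5, 14.5])

    def test_subhour_resolution_kept(self):
        rs = make_records([("a", "2020-01-01T09:30:00", "out")])
        assert np.allclose(observed_call_hours(rs, "a"), [9.5])
        rs2 = make_records([("a", "2020-01-01T09:15:00", "out"),
                            ("a", "2020-01-01T10:00:00", "out")])
        assert np.allclose(observed_call_hours(rs2, "a"), [9.25, 10.0])


class TestFitGmm:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(13.0, 2.0, 400) % 24
        fit = fit_gmm(x, K=1, wrapped=False, n_init=1, seed=1)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-8)
        assert fit.variances[0] == pytest.approx(x.var(), abs=1e-8)  # /n MLE
        assert fit.weights[0] == 1.0

    def test_recovers_true_mixture(self):
        x = sample_call_times(TRUE, 2000, seed=6)
        fit = fit_gmm(x, K=2, wrapped=True, seed=7)
        order = np.argsort(circdist(fit.means, 10.0))
        mu_m, mu_e = fit.means[order[0]], fit.means[order[1]]
        assert circdist(mu_m, 10.0) < 0.5
        assert circdist(mu_e, 18.0) < 0.5
        assert abs(fit.weights[order[0]] - 0.7) < 0.05

    def test_loglik_trace_non_decreasing(self):
        x = sample_call_times(TRUE, 500, seed=8)
        for wrapped in (True, False):
            fit = fit_gmm(x, K=2, wrapped=wrapped, seed=9)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_beats_grid_search_oracle(self):
        """On a small sample, EM must reach at least the likelihood of a
        brute-force grid over (mu1, mu2, sigma shared, pi)."""
        x = sample_call_times(TRUE, 40, seed=10)
        fit = fit_gmm(x, K=2, wrapped=True, seed=11)

        def wrapped_loglik(mu1, mu2, sigma, pi):
            dens = np.zeros_like(x)
            for mu, w in [(mu1, pi), (mu2, 1 - pi)]:
                for j in (-2, -1, 0, 1, 2):
                    dens += w * stats.norm.pdf(x + 24 * j, mu, sigma)
            return np.log(dens).sum()

        best = -np.inf
        for mu1 in np.arange(8.0, 12.01, 0.5):
            for mu2 in np.arange(16.0, 20.01, 0.5):
                for sigma in (1.0, 1.25, 1.5, 1.75, 2.0):
                    for pi in np.arange(0.3, 0.901, 0.1):
                        best = max(best, wrapped_loglik(mu1, mu2, sigma, pi))
        assert fit.loglik >= best - 1e-3

    def test_errors(self):
        with pytest.raises(RhythmError):
            fit_gmm(np.array([]), K=1)
        with pytest.raises(RhythmError):
            fit_gmm(np.array([5.0, 5.0, 5.0]), K=2)

    def test_agrees_with_sklearn_on_linear_mode(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = sample_call_times(TRUE, 1000, seed=12)
        ours = fit_gmm(x, K=2, wrapped=False, seed=13)
        gm = sklearn.GaussianMixture(2, n_init=5, random_state=0, tol=1e-8)
        gm.fit(x[:, None])
        ref_ll = gm.score(x[:, None]) * len(x)
        assert ours.loglik == pytest.approx(ref_ll, rel=1e-4, abs=0.5)
        assert np.allclose(np.sort(ours.means), np.sort(gm.means_.ravel()), atol=0.1)

    def test_bic_selects_two_components_on_bimodal_data(self):
        x = sample_call_times(TRUE, 800, seed=14)
        fit = select_k_bic(x, k_range=(1, 2, 3), seed=15)
        assert fit.K == 2


class TestMixtureDensity:
    def test_standard_normal_peak(self):
        fit = make_fit([12.0], [1.0], [1.0], wrapped=False)
        assert mixture_pdf(fit, 12.0) == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-9)

    def test_wrapped_density_normalizes(self):
        fit = make_fit([2.0, 18.0], [1.5, 3.0], [0.6, 0.4], wrapped=True)
        val, _ = integrate.quad(lambda t: mixture_pdf(fit, t), 0, 24, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_wrap_exceeds_linear_near_boundary(self):
        wrapped = make_fit([2.0], [1.5], [1.0], wrapped=True)
        linear = make_fit([2.0], [1.5], [1.0], wrapped=False)
        assert mixture_pdf(wrapped, 23.0) > mixture_pdf(linear, 23.0)
        # image-sum oracle at the same point
        expected = sum(
            stats.norm.pdf(23.0 + 24 * j, 2.0, 1.5) for j in range(-3, 4)
        )
        assert mixture_pdf(wrapped, 23.0) == pytest.approx(expected, abs=1e-12)

    def test_component_permutation_invariance(self):
        a = make_fit([9.0, 20.0], [1.0, 2.0], [0.3, 0.7])
        b = make_fit([20.0, 9.0], [2.0, 1.0], [0.7, 0.3])
        t = np.linspace(0, 24, 97)
        assert np.allclose(mixture_pdf(a, t), mixture_pdf(b, t), atol=1e-12)


class TestModelProfile:
    def test_degenerate_component_in_one_bin(self):
        fit = make_fit([10.5], [0.05], [1.0])
        masses = model_profile(fit)
        assert masses[10] > 0.999

    def test_flat_limit(self):
        fit = make_fit([12.0], [200.0], [1.0], wrapped=True)
        assert np.allclose(model_profile(fit), 1 / 24, atol=1e-6)

    def test_sums_to_one_wrapped(self):
        fit = make_fit([2.0, 18.0], [1.5, 2.5], [0.55, 0.45])
        assert model_profile(fit).sum() == pytest.approx(1.0, abs=1e-8)

    def test_matches_simpson_quadrature(self):
        fit = make_fit([3.3, 17.8], [1.1, 2.7], [0.35, 0.65])
        masses = model_profile(fit)
        for t in range(24):
            grid = np.linspace(t, t + 1, 201)
            ref = integrate.simpson(mixture_pdf(fit, grid), x=grid)
            assert masses[t] == pytest.approx(ref, abs=1e-6)


class TestKs:
    def test_hand_example_uniform(self):
        x = np.array([6.0, 12.0, 18.0])
        assert ks_statistic(x, x / 24.0) == pytest.approx(0.25, abs=1e-15)

    def test_quantile_construction_small_d(self):
        fit = make_fit([10.0, 18.0], [1.5, 1.5], [0.7, 0.3])
        n = 200
        probs = (np.arange(1, n + 1) - 0.5) / n
        grid = np.linspace(0, 24, 20001)
        cdf = np.asarray(mixture_cdf(fit, grid))
        x = np.interp(probs, cdf, grid)
        assert ks_statistic(x, np.asarray(mixture_cdf(fit, x))) <= 0.5 / n + 1e-6

    def test_duplication_invariance(self):
        fit = make_fit([10.0], [2.0], [1.0])
        x = np.array([4.0, 9.0, 15.0, 21.0])
        d1 = ks_statistic(x, np.asarray(mixture_cdf(fit, x)))
        xx = np.repeat(x, 2)
        d2 = ks_statistic(xx, np.asarray(mixture_cdf(fit, xx)))
        assert 0.0 <= d1 <= 1.0
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_matches_scipy_kstest(self):
        x = sample_call_times(TRUE, 300, seed=16)
        fit = fit_gmm(x, K=2, seed=17)
        g = ks_goodness_of_fit(x, fit)
        ref = stats.kstest(x, lambda t: np.asarray(mixture_cdf(fit, t)), method="asymp")
        assert g.ks_statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert g.p_value == pytest.approx(ref.pvalue, abs=1e-6)
        assert g.reject == (g.p_value <= 0.05)

    def test_squared_errors_shape_and_sign(self):
        x = sample_call_times(TRUE, 300, seed=18)
        fit = fit_gmm(x, K=2, seed=19)
        g = ks_goodness_of_fit(x, fit)
        assert g.squared_errors.shape == (24,)
        assert (g.squared_errors >= 0).all()

    def test_binned_variant_runs(self):
        x = sample_call_times(TRUE, 300, seed=20)
        fit = fit_gmm(x, K=2, seed=21)
        g = ks_goodness_of_fit(x, fit, binned=True)
        assert 0 <= g.ks_statistic <= 1

    def test_empty_observations(self):
        fit = make_fit([10.0], [1.0], [1.0])
        with pytest.raises(RhythmError):
            ks_goodness_of_fit(np.array([]), fit)
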