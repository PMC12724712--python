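"""Periodic kernel, SoftPlus link, generalized-Poisson likelihood and the
latent-GP fit."""

import dataclasses

import numpy as np
import pytest

from mtspike.latent_gp import (
    GPFitConfig, PeriodicKernelParams, contaminated_loglik, fit_latent_gp,
    genpois_log_norm, genpois_logpmf, genpois_mean_var, periodic_kernel,
    phase_fold, pseudo_r2, softplus_link,
)
from mtspike.synthdata import gen_ongoing_counts


class TestKernelAndLink:
    def test_kernel_variance_at_zero_and_full_period(self):
        p = PeriodicKernelParams(5.0, 300.0, 1.0)
        assert periodic_kernel(12.0, 12.0, p) == pytest.approx(5.0)
        assert periodic_kernel(312.0, 12.0, p) == pytest.approx(5.0)

    def test_kernel_closed_form_quarter_period(self):
        p = PeriodicKernelParams(5.0, 300.0, 1.0)
        assert periodic_kernel(75.0, 0.0, p) == pytest.approx(5 * np.exp(-1.0))

    def test_kernel_symmetric_and_bounded(self):
        p = PeriodicKernelParams(2.0, 100.0, 0.5)
        rng = np.random.default_rng(0)
        t1, t2 = rng.uniform(0, 1000, 50), rng.uniform(0, 1000, 50)
        k12 = periodic_kernel(t1, t2, p)
        k21 = periodic_kernel(t2, t1, p)
        assert np.allclose(k12, k21)
        assert np.all(k12 <= 2.0 + 1e-12)

    def test_invalid_kernel_params(self):
        with pytest.raises(ValueError):
            PeriodicKernelParams(-1.0, 300.0, 1.0)

    def test_softplus_values_and_stability(self):
        assert softplus_link(0.0) == pytest.approx(10 * np.log(2))
        assert softplus_link(50.0) == pytest.approx(500.0, rel=1e-10)
        assert softplus_link(-50.0) == pytest.approx(10 * np.exp(-50), rel=1e-6)
        assert softplus_link(-50.0) > 0.0

    def test_softplus_monotone_nonnegative(self):
        x = np.linspace(-100, 100, 10_001)
        y = softplus_link(x)
        assert np.all(np.diff(y) > 0) and np.all(y >= 0)


class TestGeneralizedPoisson:
    def test_poisson_reduction_at_alpha_zero(self):
        assert genpois_logpmf(0, 2.0, 0.0) == pytest.approx(-2.0)
        from scipy.stats import poisson

        ys = np.arange(30)
        assert np.allclose(genpois_logpmf(ys, 3.5, 0.0), poisson.logpmf(ys, 3.5))

    def test_pmf_sums_to_one_positive_alpha(self):
        ys = np.arange(400)
        total = np.exp(genpois_logpmf(ys, 1.5, 0.3)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_renormalized_pmf_sums_to_one_negative_alpha(self):
        theta, alpha = 3.0, -0.7
        top = int(np.floor(theta / 0.7))
        ys = np.arange(top + 1)
        total = np.exp(genpois_logpmf(ys, theta, alpha)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_mean_identity_by_direct_summation(self):
        """E[Y] = theta / (1 - alpha), verified by summing the pmf."""
        m, _ = genpois_mean_var(1.0, 0.5)
        assert m == pytest.approx(2.0, abs=1e-8)

    def test_variance_identity_grid(self):
        for theta in (0.5, 2.0, 8.0):
            for alpha in (-0.4, 0.0, 0.3, 0.6):
                m, v = genpois_mean_var(theta, alpha)
                if alpha >= 0:
                    assert m == pytest.approx(theta / (1 - alpha), rel=1e-8)
                    assert v == pytest.approx(theta / (1 - alpha) ** 3, rel=1e-6)
                else:
                    # negative dispersion: variance below Poisson level
                    assert v < m
                    assert m == pytest.approx(theta / (1 - alpha), rel=0.25)

    def test_mild_truncation_approaches_closed_form(self):
        # truncation point many SDs beyond the bulk: closed form applies
        m, v = genpois_mean_var(8.0, -0.4)
        assert m == pytest.approx(8.0 / 1.4, rel=0.01)
        assert v == pytest.approx(8.0 / 1.4**3, rel=0.05)

    def test_invalid_alpha_and_theta(self):
        with pytest.raises(ValueError):
            genpois_logpmf(1, 2.0, 1.0)
        with pytest.raises(ValueError):
            genpois_logpmf(1, -2.0, 0.0)


class TestContaminatedLikelihood:
    def test_zero_noise_equals_genpois(self):
        ys = np.arange(20)
        a = contaminated_loglik(ys, 4.0, 0.2, p_noise=0.0, y_max=40)
        b = genpois_logpmf(ys, 4.0 * 0.8, 0.2)
        assert np.allclose(a, b)

    def test_outlier_hits_mixture_floor(self):
        y_max = 200
        ll = contaminated_loglik(np.array([y_max]), 0.5, 0.0, 0.001, y_max)
        assert ll[0] == pytest.approx(np.log(0.001 / (y_max + 1)), abs=1e-3)

    def test_floor_bound_everywhere(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 100, 200)
        mu = rng.uniform(0.1, 30, 200)
        ll = contaminated_loglik(y, mu, 0.4, 0.001, 100)
        assert np.all(ll >= np.log(0.001 / 101) - 1e-12)

    def test_mixture_dominates_weighted_components(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 30, 100)
        mu = rng.uniform(0.5, 20, 100)
        alpha = 0.3
        mix = contaminated_loglik(y, mu, alpha, 0.001, 30)
        comp = genpois_logpmf(y, mu * (1 - alpha), alpha) + np.log(0.999)
        assert np.all(mix >= comp - 1e-12)


class TestPseudoR2:
    def test_perfect_and_baseline_predictions(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert pseudo_r2(obs, obs, obs.mean()) == pytest.approx(1.0)
        assert pseudo_r2(obs, np.full(4, obs.mean()), obs.mean()) == pytest.approx(0.0)

    def test_antiphase_prediction_is_negative(self):
        t = np.linspace(0, 4 * np.pi, 200)
        obs = np.sin(t)
        assert pseudo_r2(obs, -obs, 0.0) < 0

    def test_undefined_when_observed_constant(self):
        with pytest.raises(ValueError):
            pseudo_r2(np.ones(5), np.ones(5), 1.0)


@pytest.fixture(scope="module")
def periodic_fit():
    counts, gt = gen_ongoing_counts(period=300, latent_amp=2.0, alpha=0.5,
                                    duration=1500, seed=5, mode="sinusoid")
    return fit_latent_gp(counts, GPFitConfig(seed=1)), gt


class TestLatentGPFit:
    def test_period_and_dispersion_recovered(self, periodic_fit):
        fit, gt = periodic_fit
        assert abs(fit.kernel.period - 300) / 300 < 0.05
        assert abs(fit.alpha - 0.5) < 0.15
        assert fit.pseudo_r2_test > 0

    def test_heldout_purity(self):
        """Altering held-out counts never changes fitted hyperparameters."""
        counts, _ = gen_ongoing_counts(period=300, latent_amp=2.0, alpha=0.3,
                                       duration=900, seed=6, mode="sinusoid")
        cfg = GPFitConfig(seed=2, maxiter_outer=120)
        fit_a = fit_latent_gp(counts, cfg)
        tampered = counts.counts.copy()
        test_mask = counts.bin_centers > (counts.n_bins * counts.bin_width - 300)
        tampered[test_mask] += 7
        fit_b = fit_latent_gp(dataclasses.replace(counts, counts=tampered), cfg)
        assert fit_a.kernel == fit_b.kernel
        assert fit_a.alpha == fit_b.alpha
        assert fit_a.pseudo_r2_train == fit_b.pseudo_r2_train
        assert fit_a.pseudo_r2_test != fit_b.pseudo_r2_test

    def test_phase_fold_shapes(self, periodic_fit):
        fit, gt = periodic_fit
        profile = phase_fold(fit, n_phase_bins=40)
        assert profile.mean_rate.size == 40
        finite = profile.mean_rate[np.isfinite(profile.mean_rate)]
        # one clean cycle: a single maximum region and modulation present
        assert finite.max() > 2 * finite.min()

    def test_phase_fold_double_period_shows_two_cycles(self, periodic_fit):
        fit, _ = periodic_fit
        doubled = dataclasses.replace(
            fit, kernel=PeriodicKernelParams(fit.kernel.variance,
                                             2 * fit.kernel.period,
                                             fit.kernel.lengthscale))
        doubled._w = fit._w
        # folding the same prediction at twice the period shows two cycles:
        # the first and second half of the profile look alike
        prof = phase_fold(doubled, n_phase_bins=40)
        a, b = prof.mean_rate[:20], prof.mean_rate[20:]
        mask = np.isfinite(a) & np.isfinite(b)
        assert np.corrcoef(a[mask], b[mask])[0, 1] > 0.8

    def test_phase_fold_rejects_long_period(self, periodic_fit):
        fit, _ = periodic_fit
        stretched = dataclasses.replace(
            fit, kernel=PeriodicKernelParams(1.0, 1e5, 1.0))
        stretched._w = fit._w
        with pytest.raises(ValueError):
            phase_fold(stretched)
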