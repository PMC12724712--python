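"""Latent Gaussian-process model of ongoing spike counts.

A latent function x(t) ~ GP(c, k) with an exactly periodic covariance

    k(t, t') = sigma^2 * exp(-2 sin^2(pi (t - t')/p) / ell^2)

is mapped to a positive firing rate through a scaled SoftPlus link
mu(t) = A log(1 + e^{x(t)}) (A = 10 spikes/s) and observed through a
generalized Poisson count likelihood with shared dispersion alpha in (-1, 1)
(theta_t = mu_t (1 - alpha)), mixed with a small uniform contamination term
(p_noise = 0.001) to absorb rare outlier bins.

Fitting is type-II: the latent function is represented through 200 fixed,
equally spaced inducing points; for each hyperparameter setting the whitened
inducing values are driven to their posterior mode and a Laplace approximation
of the marginal likelihood (plus Gaussian log-prior penalties on the periodic
lengthscale and on alpha) forms the outer objective. The model is trained on
all but the final 300 s of data; the held-out window is predicted from the
trained model only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .spikeio import BinnedCounts

DEFAULT_LINK_SCALE = 10.0  # A, spikes/s
DEFAULT_P_NOISE = 0.001


# ---------------------------------------------------------------------------
# Kernel and link


@dataclass(frozen=True)
class PeriodicKernelParams:
    variance: float      # sigma^2
    period: float        # p, seconds
    lengthscale: float   # ell_per, dimensionless

    def __post_init__(self):
        if min(self.variance, self.period, self.lengthscale) <= 0:
            raise ValueError("kernel parameters must be positive")


def periodic_kernel(t, t_prime, params: PeriodicKernelParams):
    """Exactly periodic (exp-sine-squared) covariance between two times."""
    d = np.asarray(t, float) - np.asarray(t_prime, float)
    s = np.sin(np.pi * d / params.period)
    return params.variance * np.exp(-2.0 * s * s / params.lengthscale**2)


def periodic_kernel_matrix(t1: np.ndarray, t2: np.ndarray, params: PeriodicKernelParams):
    return periodic_kernel(t1[:, None], t2[None, :], params)


def softplus_link(x, A: float = DEFAULT_LINK_SCALE):
    """Scaled SoftPlus rate link mu = A log(1 + e^x), stable for large |x|."""
    return A * np.logaddexp(0.0, np.asarray(x, float))


def softplus_inverse(mu, A: float = DEFAULT_LINK_SCALE):
    r = np.asarray(mu, float) / A
    # log(e^r - 1), stable both for small and large r
    with np.errstate(over="ignore"):
        return np.where(r > 30, r, np.log(np.expm1(np.clip(r, 1e-12, None))))


# ---------------------------------------------------------------------------
# Generalized Poisson likelihood


def _genpois_raw_logpmf(y, theta, alpha):
    """Unnormalised log pmf log[ theta (theta+alpha y)^{y-1} e^{-theta-alpha y} / y! ].

    Entries with theta + alpha*y <= 0 (possible for alpha < 0) have
    probability zero.
    """
    y = np.asarray(y, float)
    theta = np.asarray(theta, float)
    lam = theta + alpha * y
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = (np.log(theta) + (y - 1.0) * np.log(lam) - lam - gammaln(y + 1.0))
    return np.where(lam > 0, lp, -np.inf)


def genpois_trunc_support(theta, alpha) -> int:
    """Largest count with positive raw pmf (finite only for alpha < 0)."""
    if alpha >= 0:
        raise ValueError("support is unbounded for alpha >= 0")
    return int(np.floor(np.max(theta) / (-alpha) - 1e-12))


def genpois_log_norm(theta, alpha, max_support: int = 4000):
    """log of the normalising constant of the truncated pmf (alpha < 0).

    For alpha >= 0 the pmf sums to one and the result is 0. For alpha < 0 the
    raw pmf is summed over its (finite) support and the deficiency returned.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    if alpha >= 0:
        return np.zeros(theta.shape)
    y_top = min(genpois_trunc_support(theta, alpha), max_support)
    ys = np.arange(y_top + 1)
    lp = _genpois_raw_logpmf(ys[None, :], theta[:, None], alpha)
    return logsumexp(lp, axis=1)


def genpois_logpmf(y, theta, alpha, renormalize: bool = True):
    """Generalized Poisson log pmf; reduces exactly to Poisson at alpha = 0.

    For alpha < 0 the raw pmf is deficient on its truncated support; by
    default it is renormalised so probabilities sum to one.
    """
    if abs(alpha) >= 1:
        raise ValueError("|alpha| must be < 1")
    theta = np.asarray(theta, float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    lp = _genpois_raw_logpmf(y, theta, alpha)
    if renormalize and alpha < 0:
        theta_b = np.broadcast_to(theta, np.shape(lp)).ravel()
        # the raw pmf is deficient only when the truncation point theta/|alpha|
        # cuts into the bulk of the distribution; elsewhere Z = 1 to machine
        # precision and the summation is skipped
        mu = theta_b / (1 - alpha)
        sd = np.sqrt(theta_b / (1 - alpha) ** 3)
        trunc = theta_b / (-alpha)
        need = trunc < mu + 12 * sd + 10
        logz = np.zeros(theta_b.size)
        if np.any(need):
            logz[need] = genpois_log_norm(theta_b[need], alpha)
        lp = lp - logz.reshape(np.shape(lp))
    return lp


def genpois_mean_var(theta: float, alpha: float, max_support: int = 4000):
    """Mean and variance by direct pmf summation (oracle-style, exact)."""
    if alpha < 0:
        y_top = min(genpois_trunc_support(np.asarray([theta]), alpha), max_support)
    else:
        mu = theta / (1 - alpha)
        sd = np.sqrt(theta / (1 - alpha) ** 3)
        # the tail decays only at rate alpha - 1 - ln(alpha); keep a generous
        # cutoff so summed moments are exact to ~1e-9 even for alpha near 1
        y_top = int(mu + 30 * sd + 400)
    ys = np.arange(y_top + 1)
    lp = _genpois_raw_logpmf(ys, theta, alpha)
    p = np.exp(lp - logsumexp(lp))
    m = float(np.sum(ys * p))
    v = float(np.sum((ys - m) ** 2 * p))
    return m, v


def contaminated_loglik(y, mu, alpha, p_noise: float = DEFAULT_P_NOISE,
                        y_max: int | None = None):
    """Log-likelihood of the contaminated generalized Poisson observation model.

    ``p(y|mu) = (1 - p_noise) GPois(y; mu(1-alpha), alpha) + p_noise U{0..y_max}``.
    The uniform floor keeps every observation's likelihood above
    ``log(p_noise / (y_max + 1))``.
    """
    y = np.asarray(y, float)
    if y_max is None:
        y_max = int(np.max(y)) if y.size else 0
    theta = np.asarray(mu, float) * (1.0 - alpha)
    lp_g = genpois_logpmf(y, theta, alpha)
    if p_noise == 0:
        return lp_g
    lp_u = np.log(p_noise / (y_max + 1.0))
    lp_g = lp_g + np.log1p(-p_noise)
    return np.logaddexp(lp_g, np.full_like(np.asarray(lp_g, float), lp_u))


# ---------------------------------------------------------------------------
# Fit configuration / result


@dataclass(frozen=True)
class GPFitConfig:
    bin_width: float = 5.0           # s
    holdout: float = 300.0           # s held out at the end of the recording
    link_scale: float = DEFAULT_LINK_SCALE
    p_noise: float = DEFAULT_P_NOISE
    n_inducing: int = 200
    period_init: float = 300.0
    lengthscale_init: float = 0.5
    variance_init: float = 1.0
    # Gaussian priors applied as additive log-prior penalties
    lengthscale_prior: tuple[float, float] = (0.1, 0.1)
    alpha_prior: tuple[float, float] = (0.0, 0.5)
    maxiter_outer: int = 400
    maxiter_inner: int = 200
    seed: int = 0


@dataclass
class GPFitResult:
    """Fitted latent-GP hyperparameters, dispersion and predictions."""

    kernel: PeriodicKernelParams
    alpha: float
    mean_const: float                # constant latent mean c
    inducing_points: np.ndarray
    z_map: np.ndarray                # whitened inducing values at the mode
    train_times: np.ndarray
    test_times: np.ndarray
    train_counts: np.ndarray
    test_counts: np.ndarray
    predicted_rate_train: np.ndarray     # spikes/s
    predicted_rate_test: np.ndarray
    latent_sd_train: np.ndarray
    latent_sd_test: np.ndarray
    pseudo_r2_train: float
    pseudo_r2_test: float
    objective: float                 # final outer objective (lower = better)
    converged: bool
    config: GPFitConfig

    def predict_rate(self, times: np.ndarray) -> np.ndarray:
        B = self._basis(np.asarray(times, float))
        x = self.mean_const + B @ self.z_map
        return softplus_link(x, self.config.link_scale)

    def _basis(self, times: np.ndarray) -> np.ndarray:
        Kxm = periodic_kernel_matrix(times, self.inducing_points, self.kernel)
        return Kxm @ self._w

    # filled in by the fitter: whitening matrix mapping K_xm -> basis
    _w: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def pseudo_r2(observed: np.ndarray, predicted: np.ndarray, train_mean: float) -> float:
    """1 - SSE(predicted) / SSE(train mean); negative when worse than the mean."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    denom = float(np.sum((observed - train_mean) ** 2))
    if denom == 0:
        raise ValueError("pseudo-R2 undefined: observations equal the training mean")
    return 1.0 - float(np.sum((observed - predicted) ** 2)) / denom


# ---------------------------------------------------------------------------
# Fitting machinery


def _whiten_basis(Kmm: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    """Whitening map V with basis(t) = K_tm V, so x = c + K_tm V z, z ~ N(0, I).

    V = U_r S_r^{-1/2} from the eigendecomposition of Kmm. The periodic kernel
    makes inducing points separated by whole periods perfectly correlated, so
    Kmm is rank-deficient by construction; null directions are dropped.
    """
    w, U = np.linalg.eigh((Kmm + Kmm.T) / 2)
    keep = w > rel_tol * max(w[-1], 1e-300)
    return U[:, keep] / np.sqrt(w[keep])[None, :]  # M x r


def _loglik_terms(x, y, alpha, A, p_noise, y_max, bin_width):
    mu_rate = softplus_link(x, A)
    mu_bin = np.clip(mu_rate * bin_width, 1e-12, None)
    return contaminated_loglik(y, mu_bin, alpha, p_noise, y_max)


def fit_latent_gp(counts: BinnedCounts, config: GPFitConfig = GPFitConfig()) -> GPFitResult:
    """Fit the periodic latent-GP count model and predict the held-out window.

    Outer optimisation (Nelder-Mead over log variance, log period, log
    lengthscale, mean constant and atanh-dispersion) wraps an inner L-BFGS
    mode search over whitened inducing values; the outer objective is the
    negative Laplace-approximate log marginal likelihood plus log-prior
    penalties. Restarts with jittered initialisation are attempted when the
    objective is non-finite; persistent failure is flagged on the result.
    """
    t_all = counts.bin_centers
    y_all = counts.counts.astype(float)
    t_end = counts.t0 + counts.n_bins * counts.bin_width
    is_test = t_all > (t_end - config.holdout)
    t_tr, y_tr = t_all[~is_test], y_all[~is_test]
    t_te, y_te = t_all[is_test], y_all[is_test]
    if t_tr.size < 10:
        raise ValueError("training window too short")
    y_max = int(y_tr.max()) if y_tr.size else 0  # training data only
    A, p_noise, dt = config.link_scale, config.p_noise, counts.bin_width

    Z = np.linspace(t_tr[0], t_tr[-1], config.n_inducing)
    mean_rate = max(float(np.mean(y_tr)) / dt, 1e-3)
    c0 = float(softplus_inverse(mean_rate, A))

    state = {"z": None, "shape": None}

    def inner_fit(hyper):
        log_s2, log_p, log_ell, c, a_raw = hyper
        params = PeriodicKernelParams(np.exp(log_s2), np.exp(log_p), np.exp(log_ell))
        alpha = np.tanh(a_raw)
        V = _whiten_basis(periodic_kernel_matrix(Z, Z, params))
        B = periodic_kernel_matrix(t_tr, Z, params) @ V  # x = c + B z, z ~ N(0, I)
        r = B.shape[1]
        z = (state["z"] if (state["z"] is not None and state["z"].size == r)
             else np.zeros(r))

        h = 1e-4

        def ll_terms(x):
            return _loglik_terms(x, y_tr, alpha, A, p_noise, y_max, dt)

        def objective(z):
            return float(np.sum(ll_terms(c + B @ z)) - 0.5 * z @ z)

        # damped Newton mode search (elementwise numeric likelihood derivatives)
        obj = objective(z)
        H = np.eye(r)
        for _ in range(config.maxiter_inner):
            x = c + B @ z
            ll0 = ll_terms(x)
            llp = ll_terms(x + h)
            llm = ll_terms(x - h)
            g = (llp - llm) / (2 * h)
            w_curv = np.clip(-(llp - 2 * ll0 + llm) / h**2, 1e-10, None)
            grad_z = B.T @ g - z
            H = np.eye(r) + (B.T * w_curv) @ B
            try:
                step = np.linalg.solve(H, grad_z)
            except np.linalg.LinAlgError:  # pragma: no cover
                step = grad_z
            t_step = 1.0
            improved = False
            for _bt in range(12):
                cand = z + t_step * step
                cand_obj = objective(cand)
                if cand_obj > obj:
                    z, obj, improved = cand, cand_obj, True
                    break
                t_step *= 0.5
            if not improved or np.max(np.abs(grad_z)) < 1e-7 * max(1.0, abs(obj)):
                break
        z_hat = z
        state["z"] = z_hat
        x = c + B @ z_hat
        ll0 = ll_terms(x)
        llp = ll_terms(x + h)
        llm = ll_terms(x - h)
        w_curv = np.clip(-(llp - 2 * ll0 + llm) / h**2, 0.0, None)
        H = np.eye(r) + (B.T * w_curv) @ B
        sign, logdet = np.linalg.slogdet(H)
        log_marginal = float(np.sum(ll0) - 0.5 * z_hat @ z_hat - 0.5 * logdet)
        return log_marginal, z_hat, B, V, params, alpha, H

    mu_lp, sd_lp = config.lengthscale_prior
    mu_a, sd_a = config.alpha_prior

    def outer(hyper):
        try:
            log_marginal, *_rest = inner_fit(hyper)
        except np.linalg.LinAlgError:
            return 1e12
        ell = np.exp(hyper[2])
        alpha = np.tanh(hyper[4])
        logprior = (-0.5 * ((ell - mu_lp) / sd_lp) ** 2
                    - 0.5 * ((alpha - mu_a) / sd_a) ** 2)
        val = -(log_marginal + logprior)
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(config.seed)
    hyper0 = np.array([np.log(config.variance_init), np.log(config.period_init),
                       np.log(config.lengthscale_init), c0, 0.0])
    # deterministic multi-start: default init plus a near-flat-latent start, so
    # cells without rhythmic modulation can shrink the outputscale
    flat0 = hyper0.copy()
    flat0[0] = np.log(1e-2)
    best = None
    for h0 in (hyper0, flat0):
        state["z"] = None
        res = minimize(outer, h0, method="Nelder-Mead",
                       options={"maxiter": config.maxiter_outer, "xatol": 1e-4,
                                "fatol": 1e-4})
        if best is None or res.fun < best.fun:
            best = res
    if not (np.isfinite(best.fun) and best.fun < 1e11):
        res = minimize(outer, hyper0 + 0.1 * rng.standard_normal(5),
                       method="Nelder-Mead",
                       options={"maxiter": config.maxiter_outer, "xatol": 1e-4,
                                "fatol": 1e-4})
        if res.fun < best.fun:
            best = res
    converged = bool(np.isfinite(best.fun) and best.fun < 1e11)
    state["z"] = None

    log_marginal, z_hat, B, w_map, params, alpha, H = inner_fit(best.x)
    c = float(best.x[3])
    cov_z = np.linalg.inv(H)

    def _predict(times):
        Bq = periodic_kernel_matrix(times, Z, params) @ w_map
        x = c + Bq @ z_hat
        sd = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", Bq, cov_z, Bq), 0, None))
        return softplus_link(x, A), sd

    rate_tr, sd_tr = _predict(t_tr)
    rate_te, sd_te = _predict(t_te)
    train_mean_count = float(np.mean(y_tr))
    r2_tr = pseudo_r2(y_tr, rate_tr * dt, train_mean_count)
    r2_te = (pseudo_r2(y_te, rate_te * dt, train_mean_count) if y_te.size else np.nan)

    out = GPFitResult(
        kernel=params, alpha=float(alpha), mean_const=c,
        inducing_points=Z, z_map=z_hat,
        train_times=t_tr, test_times=t_te,
        train_counts=y_tr.astype(int), test_counts=y_te.astype(int),
        predicted_rate_train=rate_tr, predicted_rate_test=rate_te,
        latent_sd_train=sd_tr, latent_sd_test=sd_te,
        pseudo_r2_train=float(r2_tr), pseudo_r2_test=float(r2_te),
        objective=float(best.fun), converged=converged, config=config,
    )
    out._w = w_map
    return out


# ---------------------------------------------------------------------------
# Phase-folded reconstruction


@dataclass(frozen=True)
class PhaseProfile:
    phase: np.ndarray       # bin centers in [0, 1)
    mean_rate: np.ndarray   # spikes/s


def phase_fold(fit: GPFitResult, n_phase_bins: int = 50) -> PhaseProfile:
    """Fold the predicted training-span rate modulo the fitted period.

    Phase 0 anchors at the training-window start; profiles are meaningful up
    to a cyclic shift.
    """
    period = fit.kernel.period
    span = fit.train_times[-1] - fit.train_times[0]
    if not np.isfinite(period) or period <= 0:
        raise ValueError("fitted period must be finite and positive")
    if period > span:
        raise ValueError("fitted period exceeds the training span")
    phases = ((fit.train_times - fit.train_times[0]) / period) % 1.0
    edges = np.linspace(0, 1, n_phase_bins + 1)
    idx = np.clip(np.digitize(phases, edges) - 1, 0, n_phase_bins - 1)
    mean_rate = np.full(n_phase_bins, np.nan)
    for b in range(n_phase_bins):
        sel = idx == b
        if np.any(sel):
            mean_rate[b] = float(np.mean(fit.predicted_rate_train[sel]))
    centers = (edges[:-1] + edges[1:]) / 2
    return PhaseProfile(phase=centers, mean_rate=mean_rate)
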