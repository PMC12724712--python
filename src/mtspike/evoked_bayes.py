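"""Piecewise Bayesian models of pooled evoked spike counts.

Population spike counts in 50 ms bins around the withdrawal (or heat-onset)
event are modelled as Poisson with a piecewise rate: a response branch for
``t < t_s`` and a recovery branch for ``t >= t_s``, continuous at the switch
time ``t_s``.

ON cells: exponential rise toward the switch,

    response(t) = r_pre + k_pre * exp((t - t_s)/tau1),        t <= t_s
    recovery(t) = r_post + k_fast * exp(-(t - t_s)/tau2)
                        + k_slow * exp(-(t - t_s)/tau3),      t >  t_s

with continuity enforced through ``k_slow = k_pre + r_pre - r_post - k_fast``
(the single-exponential variant drops the ``k_fast`` term).

OFF cells: sigmoidal pause,

    response(t) = b + (a - b) / (1 + exp(-k (t - t*)))

with the midpoint ``t*`` chosen so the sigmoid passes through ``(t_s, u0)``,
followed by either a linear + exponential recovery

    recovery(t) = u0 + (c - u0)(1 - exp(-(t - t_s)/tau)) + k3 (t - t_s)

or a double-exponential recovery. A constant-rate null model completes the
candidate set. Note the decreasing OFF response requires a negative signed
slope ``k``; reported slopes are magnitudes.

Posteriors are sampled with an affine-invariant ensemble sampler (emcee),
initialised at a posterior mode found by direct optimisation. Model
comparison uses PSIS-LOO expected log predictive density via arviz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, gammaln
from scipy.optimize import minimize

from .spikeio import BinnedCounts

logger = logging.getLogger(__name__)

VARIANTS = ("on_single_exp", "on_double_exp", "off_double_exp", "off_linear_exp", "null_constant")

_SQRT2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Parameter containers and derived quantities


@dataclass(frozen=True)
class OnParams:
    """ON-cell piecewise model parameters (counts/bin and seconds)."""

    r_pre: float
    r_post: float
    k_pre: float
    k_fast: float  # 0 for the single-exponential variant
    tau1: float    # pre-switch rise time constant
    tau2: float    # fast recovery time constant (unused when k_fast == 0)
    tau3: float    # slow recovery time constant
    t_s: float

    @property
    def k_slow(self) -> float:
        return derive_kslow(self.r_pre, self.r_post, self.k_pre, self.k_fast)


@dataclass(frozen=True)
class OffParams:
    """OFF-cell piecewise model parameters.

    ``k`` is the signed sigmoid slope (negative for the canonical decreasing
    pause); ``tau`` / ``k3`` parameterise the linear+exponential recovery and
    ``tau_fast`` / ``d`` the double-exponential one.
    """

    a: float
    b: float
    k: float
    u0: float
    c: float
    tau: float
    k3: float = 0.0
    d: float = 0.0
    tau_fast: float = 1.0
    t_s: float = 0.0

    @property
    def t_star(self) -> float:
        return derive_tstar(self.a, self.b, self.k, self.u0, self.t_s)


def derive_kslow(r_pre: float, r_post: float, k_pre: float, k_fast: float) -> float:
    """Slow-recovery amplitude that makes the ON rate continuous at ``t_s``."""
    return k_pre + r_pre - r_post - k_fast


def derive_tstar(a, b, k, u0, t_s):
    """Sigmoid midpoint placing the OFF response through ``(t_s, u0)``.

    ``t* = t_s + (1/k) ln((a - b)/(u0 - b) - 1)``; requires ``b < u0 < a``.
    """
    a, b, u0 = np.asarray(a, float), np.asarray(b, float), np.asarray(u0, float)
    if np.any(u0 <= b) or np.any(u0 >= a):
        raise ValueError("u0 must lie strictly between b and a")
    return t_s + np.log((a - b) / (u0 - b) - 1.0) / k


# ---------------------------------------------------------------------------
# Rate functions (vectorised over leading parameter axes)


def _on_rate(t, r_pre, r_post, k_pre, k_fast, tau1, tau2, tau3, t_s):
    dt = t - t_s
    resp = r_pre + k_pre * np.exp(np.minimum(dt / tau1, 0.0))
    k_slow = k_pre + r_pre - r_post - k_fast
    dtp = np.maximum(dt, 0.0)
    rec = r_post + k_fast * np.exp(-dtp / tau2) + k_slow * np.exp(-dtp / tau3)
    return np.where(dt < 0, resp, rec)


def _off_sigmoid(t, a, b, k, u0, t_s):
    t_star = t_s + np.log((a - b) / (u0 - b) - 1.0) / k
    return b + (a - b) * expit(k * (t - t_star))


def _off_linear_exp_rate(t, a, b, k, u0, c, tau, k3, t_s):
    dt = t - t_s
    resp = _off_sigmoid(t, a, b, k, u0, t_s)
    dtp = np.maximum(dt, 0.0)
    rec = u0 + (c - u0) * (1.0 - np.exp(-dtp / tau)) + k3 * dtp
    return np.where(dt < 0, resp, rec)


def _off_double_exp_rate(t, a, b, k, u0, c, tau, d, tau_fast, t_s):
    dt = t - t_s
    resp = _off_sigmoid(t, a, b, k, u0, t_s)
    dtp = np.maximum(dt, 0.0)
    rec = (
        u0
        + (c - u0) * (1.0 - np.exp(-dtp / tau))
        + (d - u0) * (1.0 - np.exp(-dtp / tau_fast))
    )
    return np.where(dt < 0, resp, rec)


def evaluate_rate(variant: str, params, t):
    """Evaluate the piecewise Poisson rate ``lambda_t`` (counts/bin) at ``t``.

    ``params`` is an :class:`OnParams`, :class:`OffParams`, a scalar (null
    model), or a mapping with the same field names.
    """
    t = np.asarray(t, dtype=float)
    if variant == "null_constant":
        r = params if np.isscalar(params) else dict(params)["r"]
        return np.full_like(t, float(r))
    if isinstance(params, dict):
        params = (OnParams(**params) if variant.startswith("on_") else OffParams(**params))
    if variant == "on_double_exp":
        p: OnParams = params
        return _on_rate(t, p.r_pre, p.r_post, p.k_pre, p.k_fast, p.tau1, p.tau2, p.tau3, p.t_s)
    if variant == "on_single_exp":
        p = params
        return _on_rate(t, p.r_pre, p.r_post, p.k_pre, 0.0, p.tau1, 1.0, p.tau3, p.t_s)
    if variant == "off_linear_exp":
        q: OffParams = params
        return _off_linear_exp_rate(t, q.a, q.b, q.k, q.u0, q.c, q.tau, q.k3, q.t_s)
    if variant == "off_double_exp":
        q = params
        return _off_double_exp_rate(t, q.a, q.b, q.k, q.u0, q.c, q.tau, q.d, q.tau_fast, q.t_s)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Model specification: free-parameter layout and priors


@dataclass(frozen=True)
class PiecewiseModelSpec:
    """An evoked model variant plus its sampler configuration.

    Priors (fixed, as used throughout): ON — ``log r_pre, log r_post ~
    N(3, 1)``, ``log k_pre, log k_fast ~ N(1, 1)``, ``beta_i ~ HalfNormal(5)``
    with ``tau_i = 1/beta_i``, ``t_s ~ U[-4, 4]``. OFF — ``b ~ HalfNormal(4)``,
    ``a, c (, d) ~ b + HalfNormal(4)``, signed slope ``k ~ N(0, 1)``,
    recovery rate ``1/tau ~ HalfNormal(1)``, ``k3 ~ HalfNormal(1)``,
    ``u0 ~ U(b, a)``, ``t_s ~ U[-4, 4]``.
    """

    variant: str
    alignment: str = "withdrawal"
    bin_width: float = 0.05
    n_walkers: int = 64
    n_steps: int = 2500
    n_burn: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def cell_class(self) -> str:
        return {"on": "ON", "of": "OFF", "nu": "UNKNOWN"}[self.variant[:2]]

    @property
    def free_names(self) -> tuple[str, ...]:
        return _FREE_NAMES[self.variant]


_FREE_NAMES = {
    "on_double_exp": ("log_r_pre", "log_r_post", "log_k_pre", "log_k_fast",
                      "beta1", "beta2", "beta3", "t_s"),
    "on_single_exp": ("log_r_pre", "log_r_post", "log_k_pre", "beta1", "beta3", "t_s"),
    "off_linear_exp": ("b", "da", "dc", "k", "rate", "k3", "w_u0", "t_s"),
    "off_double_exp": ("b", "da", "dc", "dd", "k", "rate_slow", "rate_fast", "w_u0", "t_s"),
    "null_constant": ("log_r",),
}


def _halfnormal_logpdf(x, sigma):
    return np.where(x > 0, -0.5 * (x / sigma) ** 2 - np.log(sigma * _SQRT2PI / 2.0), -np.inf)


def _normal_logpdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma * _SQRT2PI)


def _log_prior(variant: str, theta: np.ndarray) -> np.ndarray:
    """Vectorised log prior density; ``theta`` has shape (..., ndim)."""
    th = np.moveaxis(theta, -1, 0)
    if variant == "on_double_exp":
        lrp, lrq, lkp, lkf, b1, b2, b3, ts = th
        lp = (_normal_logpdf(lrp, 3, 1) + _normal_logpdf(lrq, 3, 1)
              + _normal_logpdf(lkp, 1, 1) + _normal_logpdf(lkf, 1, 1)
              + _halfnormal_logpdf(b1, 5) + _halfnormal_logpdf(b2, 5)
              + _halfnormal_logpdf(b3, 5))
        # identifiability: the "fast" component is the faster one (tau2 < tau3)
        lp = np.where((ts >= -4) & (ts <= 4) & (b2 > b3), lp - np.log(8.0), -np.inf)
        return lp
    if variant == "on_single_exp":
        lrp, lrq, lkp, b1, b3, ts = th
        lp = (_normal_logpdf(lrp, 3, 1) + _normal_logpdf(lrq, 3, 1)
              + _normal_logpdf(lkp, 1, 1)
              + _halfnormal_logpdf(b1, 5) + _halfnormal_logpdf(b3, 5))
        return np.where((ts >= -4) & (ts <= 4), lp - np.log(8.0), -np.inf)
    if variant == "off_linear_exp":
        b, da, dc, k, rate, k3, w, ts = th
        lp = (_halfnormal_logpdf(b, 4) + _halfnormal_logpdf(da, 4)
              + _halfnormal_logpdf(dc, 4) + _normal_logpdf(k, 0, 1)
              + _halfnormal_logpdf(rate, 1) + _halfnormal_logpdf(k3, 1))
        ok = (w > 0) & (w < 1) & (ts >= -4) & (ts <= 4)
        return np.where(ok, lp - np.log(8.0), -np.inf)
    if variant == "off_double_exp":
        b, da, dc, dd, k, r_s, r_f, w, ts = th
        lp = (_halfnormal_logpdf(b, 4) + _halfnormal_logpdf(da, 4)
              + _halfnormal_logpdf(dc, 4) + _halfnormal_logpdf(dd, 4)
              + _normal_logpdf(k, 0, 1)
              + _halfnormal_logpdf(r_s, 1) + _halfnormal_logpdf(r_f, 1))
        # identifiability: tau_fast < tau_slow
        ok = (w > 0) & (w < 1) & (ts >= -4) & (ts <= 4) & (r_f > r_s)
        return np.where(ok, lp - np.log(8.0), -np.inf)
    if variant == "null_constant":
        (lr,) = th
        return _normal_logpdf(lr, 3, 1)
    raise ValueError(variant)


def _rate_matrix(variant: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Rate lambda for every parameter row; theta (W, ndim) -> (W, T)."""
    th = [c[:, None] for c in np.moveaxis(theta, -1, 0)]
    if variant == "on_double_exp":
        lrp, lrq, lkp, lkf, b1, b2, b3, ts = th
        return _on_rate(t[None, :], np.exp(lrp), np.exp(lrq), np.exp(lkp), np.exp(lkf),
                        1.0 / b1, 1.0 / b2, 1.0 / b3, ts)
    if variant == "on_single_exp":
        lrp, lrq, lkp, b1, b3, ts = th
        return _on_rate(t[None, :], np.exp(lrp), np.exp(lrq), np.exp(lkp), 0.0,
                        1.0 / b1, 1.0, 1.0 / b3, ts)
    if variant == "off_linear_exp":
        b, da, dc, k, rate, k3, w, ts = th
        a = b + da
        u0 = b + w * da
        return _off_linear_exp_rate(t[None, :], a, b, k, u0, b + dc, 1.0 / rate, k3, ts)
    if variant == "off_double_exp":
        b, da, dc, dd, k, r_s, r_f, w, ts = th
        a = b + da
        u0 = b + w * da
        return _off_double_exp_rate(t[None, :], a, b, k, u0, b + dc, 1.0 / r_s,
                                    b + dd, 1.0 / r_f, ts)
    if variant == "null_constant":
        (lr,) = th
        return np.broadcast_to(np.exp(lr), (theta.shape[0], t.size)).copy()
    raise ValueError(variant)


def theta_to_params(variant: str, theta: np.ndarray):
    """Map a free-parameter vector to the natural parameter container."""
    theta = np.asarray(theta, float)
    v = dict(zip(_FREE_NAMES[variant], theta))
    if variant == "on_double_exp":
        return OnParams(np.exp(v["log_r_pre"]), np.exp(v["log_r_post"]),
                        np.exp(v["log_k_pre"]), np.exp(v["log_k_fast"]),
                        1 / v["beta1"], 1 / v["beta2"], 1 / v["beta3"], v["t_s"])
    if variant == "on_single_exp":
        return OnParams(np.exp(v["log_r_pre"]), np.exp(v["log_r_post"]),
                        np.exp(v["log_k_pre"]), 0.0,
                        1 / v["beta1"], 1.0, 1 / v["beta3"], v["t_s"])
    if variant == "off_linear_exp":
        a = v["b"] + v["da"]
        return OffParams(a=a, b=v["b"], k=v["k"], u0=v["b"] + v["w_u0"] * v["da"],
                         c=v["b"] + v["dc"], tau=1 / v["rate"], k3=v["k3"], t_s=v["t_s"])
    if variant == "off_double_exp":
        a = v["b"] + v["da"]
        return OffParams(a=a, b=v["b"], k=v["k"], u0=v["b"] + v["w_u0"] * v["da"],
                         c=v["b"] + v["dc"], tau=1 / v["rate_slow"],
                         d=v["b"] + v["dd"], tau_fast=1 / v["rate_fast"], t_s=v["t_s"])
    if variant == "null_constant":
        return float(np.exp(v["log_r"]))
    raise ValueError(variant)


# ---------------------------------------------------------------------------
# Posterior summaries


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries of one fitted piecewise model."""

    spec: PiecewiseModelSpec
    draws: dict[str, np.ndarray]          # natural-scale parameter draws
    free_draws: np.ndarray                # (n_draws, ndim) sampler-space draws
    log_likelihood: np.ndarray            # (n_ll_draws, n_bins) pointwise
    bin_centers: np.ndarray
    counts: np.ndarray
    diagnostics: dict[str, float]
    converged: bool

    def mean(self, name: str) -> float:
        return float(np.mean(self.draws[name]))

    def hdi(self, name: str, mass: float = 0.97) -> tuple[float, float]:
        return compute_hdi(self.draws[name], mass)

    def summary_table(self, mass: float = 0.97):
        import pandas as pd

        rows = []
        for name, d in self.draws.items():
            lo, hi = compute_hdi(d, mass)
            rows.append((name, float(np.mean(d)), lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "mean", "hdi_lo", "hdi_hi"])


def compute_hdi(draws: Sequence[float], mass: float = 0.97) -> tuple[float, float]:
    """Minimum-width interval containing ``mass`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


_NATURAL = {
    "on_double_exp": ("r_pre", "r_post", "k_pre", "k_fast", "k_slow",
                      "tau_pre", "tau_fast", "tau_slow", "t_s"),
    "on_single_exp": ("r_pre", "r_post", "k_pre", "k_slow", "tau_pre", "tau_slow", "t_s"),
    "off_linear_exp": ("a", "b", "k", "k_mag", "u0", "c", "tau", "k3", "t_star", "t_s"),
    "off_double_exp": ("a", "b", "k", "k_mag", "u0", "c", "tau_slow_off", "d",
                       "tau_fast_off", "t_star", "t_s"),
    "null_constant": ("r",),
}


def _natural_draws(variant: str, free: np.ndarray) -> dict[str, np.ndarray]:
    cols = dict(zip(_FREE_NAMES[variant], free.T))
    out: dict[str, np.ndarray] = {}
    if variant.startswith("on_"):
        out["r_pre"] = np.exp(cols["log_r_pre"])
        out["r_post"] = np.exp(cols["log_r_post"])
        out["k_pre"] = np.exp(cols["log_k_pre"])
        if variant == "on_double_exp":
            out["k_fast"] = np.exp(cols["log_k_fast"])
            out["tau_fast"] = 1.0 / cols["beta2"]
        else:
            out["k_fast"] = np.zeros_like(out["k_pre"])
        out["k_slow"] = out["k_pre"] + out["r_pre"] - out["r_post"] - out["k_fast"]
        out["tau_pre"] = 1.0 / cols["beta1"]
        out["tau_slow"] = 1.0 / cols["beta3"]
        out["t_s"] = cols["t_s"]
        if variant == "on_single_exp":
            out.pop("k_fast")
    elif variant.startswith("off_"):
        out["b"] = cols["b"]
        out["a"] = cols["b"] + cols["da"]
        out["c"] = cols["b"] + cols["dc"]
        out["k"] = cols["k"]
        out["k_mag"] = np.abs(cols["k"])
        out["u0"] = cols["b"] + cols["w_u0"] * cols["da"]
        out["t_s"] = cols["t_s"]
        with np.errstate(divide="ignore", invalid="ignore"):
            out["t_star"] = cols["t_s"] + np.log(
                (out["a"] - out["b"]) / (out["u0"] - out["b"]) - 1.0
            ) / cols["k"]
        if variant == "off_linear_exp":
            out["tau"] = 1.0 / cols["rate"]
            out["k3"] = cols["k3"]
        else:
            out["tau_slow_off"] = 1.0 / cols["rate_slow"]
            out["tau_fast_off"] = 1.0 / cols["rate_fast"]
            out["d"] = cols["b"] + cols["dd"]
    else:
        out["r"] = np.exp(cols["log_r"])
    return out


# ---------------------------------------------------------------------------
# Fitting


def _make_log_prob(variant: str, t: np.ndarray, y: np.ndarray) -> Callable:
    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = _log_prior(variant, theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            lam = _rate_matrix(variant, theta[ok], t)
            good = np.all(lam > 0, axis=1) & np.all(np.isfinite(lam), axis=1)
            ll = np.full(lam.shape[0], -np.inf)
            if np.any(good):
                lg = lam[good]
                ll[good] = np.sum(y[None, :] * np.log(lg) - lg, axis=1)
            out[ok] = lp[ok] + ll
        return out

    return log_prob


def _heuristic_start(variant: str, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Data-informed starting point for mode finding."""
    w = max(1, int(round(1.0 / (t[1] - t[0]) )))  # ~1 s of bins
    smooth = np.convolve(y, np.ones(w) / w, mode="same")
    pre_mean = max(np.mean(y[t < -5.0]), 0.5)
    post_mean = max(np.mean(y[t > 60.0]), 0.5)
    if variant.startswith("on_"):
        peak = max(smooth.max(), pre_mean + 1.0)
        t_peak = float(np.clip(t[np.argmax(smooth)], -3.5, 3.5))
        k_pre = max(peak - pre_mean, 0.5)
        if variant == "on_double_exp":
            return np.array([np.log(pre_mean), np.log(post_mean), np.log(k_pre),
                             np.log(max(0.4 * k_pre, 0.2)), 2.0, 0.4, 0.02, t_peak])
        return np.array([np.log(pre_mean), np.log(post_mean), np.log(k_pre),
                         2.0, 0.05, t_peak])
    if variant.startswith("off_"):
        trough = max(smooth[(t > -4) & (t < 8)].min(), 0.1)
        b0 = max(0.5 * trough, 0.05)
        da = max(pre_mean - b0, 0.5)
        dc = max(post_mean - b0, 0.5)
        t_sw = float(np.clip(t[np.argmin(np.abs(smooth - trough))], -3.5, 3.5))
        w0 = float(np.clip((trough - b0) / da, 0.05, 0.9))
        if variant == "off_linear_exp":
            return np.array([b0, da, dc, -2.0, 0.25, 0.05, w0, t_sw])
        return np.array([b0, da, 0.7 * dc, 0.3 * dc, -2.0, 0.05, 0.3, w0, t_sw])
    return np.array([np.log(max(np.mean(y), 0.5))])


def fit_piecewise_model(counts: BinnedCounts, spec: PiecewiseModelSpec,
                        n_loglik_draws: int = 1000) -> PosteriorSummary:
    """Fit one piecewise variant to pooled binned counts by ensemble MCMC.

    Walkers are initialised in a small ball around a posterior mode located by
    Nelder-Mead restarts; after burn-in, thinned draws, natural-scale derived
    quantities (``tau_i``, ``k_slow``, ``t_star``), pointwise Poisson
    log-likelihoods (for ELPD) and convergence diagnostics are returned.
    Non-convergence is flagged on the result, never silently dropped.
    """
    import emcee

    t = counts.bin_centers
    y = counts.counts.astype(float)
    variant = spec.variant
    log_prob = _make_log_prob(variant, t, y)
    rng = np.random.default_rng(spec.seed)

    x0 = _heuristic_start(variant, t, y)
    best, best_val = x0, -log_prob(x0)[0]
    starts = [x0]
    if variant != "null_constant":
        for shift in (-2.0, 0.0, 2.0):
            alt = x0.copy()
            alt[-1] = np.clip(shift, -3.9, 3.9)
            starts.append(alt)
    for s in starts:
        res = minimize(lambda th: -log_prob(th)[0], s, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-6})
        if np.isfinite(res.fun) and res.fun < best_val:
            best, best_val = res.x, res.fun
    if not np.isfinite(best_val):
        raise RuntimeError("could not find a finite-posterior starting point")

    ndim = len(spec.free_names)
    nwalkers = max(spec.n_walkers, 2 * ndim + 2)
    p0 = best[None, :] * (1 + 1e-4 * rng.standard_normal((nwalkers, ndim)))
    p0 += 1e-4 * rng.standard_normal((nwalkers, ndim))
    # nudge any invalid starts back toward the mode
    lp0 = log_prob(p0)
    for i in np.where(~np.isfinite(lp0))[0]:
        p0[i] = best

    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(spec.seed).get_state()
    state = sampler.run_mcmc(p0, spec.n_steps, progress=False)
    chain = sampler.get_chain(discard=spec.n_burn, thin=spec.thin)  # (S, W, D)
    free = chain.reshape(-1, ndim)

    acc = float(np.mean(sampler.acceptance_fraction))
    try:
        tau_int = sampler.get_autocorr_time(discard=spec.n_burn, quiet=True)
        max_tau = float(np.nanmax(tau_int))
    except Exception:  # pragma: no cover - emcee raises on very short chains
        max_tau = np.nan
    n_eff = free.shape[0] * spec.thin / max_tau if np.isfinite(max_tau) else np.nan
    converged = (0.08 < acc < 0.95) and (
        not np.isfinite(max_tau) or (spec.n_steps - spec.n_burn) > 10 * max_tau
    )
    if not converged:
        logger.warning("fit of %s flagged non-converged (acc=%.2f, tau=%.1f)",
                       variant, acc, max_tau)

    # pointwise log-likelihood on a subsample of draws (for PSIS-LOO)
    n_ll = min(n_loglik_draws, free.shape[0])
    idx = rng.choice(free.shape[0], size=n_ll, replace=False)
    lam = _rate_matrix(variant, free[idx], t)
    loglik = y[None, :] * np.log(lam) - lam - gammaln(y + 1.0)[None, :]

    return PosteriorSummary(
        spec=spec,
        draws=_natural_draws(variant, free),
        free_draws=free,
        log_likelihood=loglik,
        bin_centers=t,
        counts=counts.counts.copy(),
        diagnostics={"acceptance": acc, "max_autocorr": max_tau, "n_eff": n_eff,
                     "map_neglogpost": float(best_val)},
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Model comparison (PSIS-LOO ELPD)


@dataclass(frozen=True)
class ModelComparison:
    variants: tuple[str, ...]
    elpd: np.ndarray
    se: np.ndarray
    ranks: np.ndarray  # 0 = best

    @property
    def best(self) -> str:
        return self.variants[int(np.argmin(self.ranks))]

    def delta(self, v1: str, v2: str) -> float:
        i, j = self.variants.index(v1), self.variants.index(v2)
        return float(self.elpd[i] - self.elpd[j])


def _to_inference_data(fit: PosteriorSummary):
    import arviz as az

    ll = fit.log_likelihood[None, :, :]  # 1 chain
    return az.from_dict(
        posterior={"dummy": np.zeros((1, fit.log_likelihood.shape[0]))},
        log_likelihood={"y": ll},
    )


def compare_elpd(fits: Sequence[PosteriorSummary]) -> ModelComparison:
    """Rank fitted variants by PSIS-LOO expected log predictive density.

    All fits must be on the same data (identical counts); higher ELPD ranks
    better.
    """
    import arviz as az

    ref = fits[0].counts
    for f in fits[1:]:
        if f.counts.shape != ref.shape or np.any(f.counts != ref):
            raise ValueError("fits compare different data")
    elpds, ses = [], []
    for f in fits:
        loo = az.loo(_to_inference_data(f), pointwise=False)
        elpds.append(float(loo.elpd_loo))
        ses.append(float(loo.se))
    elpds = np.asarray(elpds)
    order = np.argsort(-elpds)
    ranks = np.empty(len(fits), dtype=int)
    ranks[order] = np.arange(len(fits))
    return ModelComparison(
        variants=tuple(f.spec.variant for f in fits),
        elpd=elpds, se=np.asarray(ses), ranks=ranks,
    )


# ---------------------------------------------------------------------------
# Threshold-crossing timing


@dataclass(frozen=True)
class ThresholdCrossing:
    level: float
    phase: str  # "response" or "recovery"
    time_mean: float
    hdi: tuple[float, float]
    n_defined: int


def _vector_bisect(f, lo, hi, iters: int = 60):
    """Vectorised bisection for f monotone between lo and hi (arrays)."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        same = np.sign(fm) == np.sign(flo)
        lo = np.where(same, mid, lo)
        flo = np.where(same, fm, flo)
        hi = np.where(same, hi, mid)
    return 0.5 * (lo + hi)


def _rate_elementwise(variant: str, free: np.ndarray, tq: np.ndarray) -> np.ndarray:
    """Rate of draw i evaluated at time tq[i] (elementwise over draws)."""
    cols = dict(zip(_FREE_NAMES[variant], free.T))
    if variant == "on_double_exp":
        return _on_rate(tq, np.exp(cols["log_r_pre"]), np.exp(cols["log_r_post"]),
                        np.exp(cols["log_k_pre"]), np.exp(cols["log_k_fast"]),
                        1 / cols["beta1"], 1 / cols["beta2"], 1 / cols["beta3"],
                        cols["t_s"])
    if variant == "on_single_exp":
        return _on_rate(tq, np.exp(cols["log_r_pre"]), np.exp(cols["log_r_post"]),
                        np.exp(cols["log_k_pre"]), 0.0,
                        1 / cols["beta1"], 1.0, 1 / cols["beta3"], cols["t_s"])
    b = cols["b"]
    a = b + cols["da"]
    u0 = b + cols["w_u0"] * cols["da"]
    if variant == "off_linear_exp":
        return _off_linear_exp_rate(tq, a, b, cols["k"], u0, b + cols["dc"],
                                    1 / cols["rate"], cols["k3"], cols["t_s"])
    if variant == "off_double_exp":
        return _off_double_exp_rate(tq, a, b, cols["k"], u0, b + cols["dc"],
                                    1 / cols["rate_slow"], b + cols["dd"],
                                    1 / cols["rate_fast"], cols["t_s"])
    raise ValueError(variant)


def threshold_crossing_times(
    fit: PosteriorSummary,
    levels: Sequence[float] = (0.10, 0.50, 0.90),
    mass: float = 0.97,
    max_draws: int = 2000,
) -> list[ThresholdCrossing]:
    """Times at which the rate completes a fraction of its departure/return.

    Response phase: the time (per posterior draw) at which the rate has
    completed ``level`` of its excursion from the pre-event baseline to the
    extremum at ``t_s``. Recovery phase: the time at which it has completed
    ``level`` of the return from the extremum to the post-event baseline (the
    late-window rate for the linear+exponential OFF variant, the asymptote
    otherwise). Draws where the branch never reaches the target inside the
    window are flagged undefined and excluded from the summary.
    """
    variant = fit.spec.variant
    if variant == "null_constant":
        raise ValueError("threshold crossings are undefined for the null model")
    for lv in levels:
        if not 0 < lv < 1:
            raise ValueError("levels must lie in (0, 1)")
    rng = np.random.default_rng(fit.spec.seed + 1)
    n = fit.free_draws.shape[0]
    idx = rng.choice(n, size=min(max_draws, n), replace=False)
    theta = fit.free_draws[idx]
    t_lo, t_hi = float(fit.bin_centers[0]), float(fit.bin_centers[-1])
    ts = theta[:, list(fit.spec.free_names).index("t_s")]

    far_past = np.full_like(ts, t_lo - 1e3)
    baseline_pre = _rate_elementwise(variant, theta, far_past)
    extremum = _rate_elementwise(variant, theta, ts)
    if variant == "off_linear_exp":
        baseline_post = _rate_elementwise(variant, theta, np.full_like(ts, t_hi))
    else:
        baseline_post = _rate_elementwise(variant, theta, np.full_like(ts, t_hi + 1e4))

    results: list[ThresholdCrossing] = []
    for phase in ("response", "recovery"):
        for lv in levels:
            if phase == "response":
                target = baseline_pre + lv * (extremum - baseline_pre)
                lo = np.full_like(ts, t_lo)
                hi = ts.copy()
            else:
                target = extremum + lv * (baseline_post - extremum)
                lo = ts.copy()
                hi = np.full_like(ts, t_hi)

            def g(tq, target=target):
                return _rate_elementwise(variant, theta, tq) - target

            g_lo, g_hi = g(lo), g(hi)
            defined = np.sign(g_lo) != np.sign(g_hi)
            times = np.full(ts.shape, np.nan)
            if np.any(defined):
                sub = np.where(defined)[0]
                th_sub = theta[sub]

                def g_sub(tq):
                    return _rate_elementwise(variant, th_sub, tq) - target[sub]

                times[sub] = _vector_bisect(g_sub, lo[sub], hi[sub])
            good = times[np.isfinite(times)]
            if good.size >= 100:
                hdi = compute_hdi(good, mass)
                mean = float(np.mean(good))
            else:
                hdi, mean = (np.nan, np.nan), np.nan
            results.append(ThresholdCrossing(level=lv, phase=phase, time_mean=mean,
                                             hdi=hdi, n_defined=int(np.isfinite(times).sum())))
    return results
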