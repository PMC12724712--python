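"""Synthetic cohort generation with the statistical structure the analyses assume.

The generator emulates the study conditions of a lightly anesthetized rodent
preparation: ON cells ramp up just before each paw withdrawal and recover on
fast + slow exponential timescales, OFF cells pause sigmoidally and recover
with a linear + exponential trajectory, NEUTRAL cells fire as regular ~10 Hz
gamma-renewal trains, ON/OFF ongoing activity carries a ~300 s quasi-periodic
latent modulation observed through a SoftPlus link with generalized-Poisson
dispersion, and the heart rate is a ~391 bpm series that can optionally share
the slow oscillation. Every generator is a pure function of its arguments and
a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .spikeio import (
    BinnedCounts, CellClass, EventTable, RateSeries, SpikeTrain,
    write_event_table, write_hr_table, write_spike_table,
)
from .evoked_bayes import OnParams, OffParams, evaluate_rate
from .latent_gp import (
    _genpois_raw_logpmf, genpois_log_norm, genpois_trunc_support,
    periodic_kernel_matrix, PeriodicKernelParams, softplus_link,
)
from scipy.special import logsumexp

# Population-level evoked parameters (counts per 50 ms bin, pooled over
# N_POOL trial windows). Time constants, switch times, OFF slope and linear
# drift follow the evoked-model posterior summaries; baselines and amplitudes
# are defaults calibrated so that posterior HDI widths from fits to the
# generated counts match the widths of the reported evoked-model posteriors
# (pooled baselines of tens of counts per 50 ms bin, consistent with the
# model's amplitude priors).
N_POOL = 300  # pooled trial-equivalents

ON_POPULATION_PARAMS = OnParams(
    r_pre=40.0, r_post=36.0, k_pre=80.0, k_fast=30.0,
    tau1=0.481, tau2=2.850, tau3=61.252, t_s=-0.176,
)
OFF_POPULATION_PARAMS = OffParams(
    a=24.0, b=1.0, k=-2.895, u0=1.4, c=16.0, tau=4.206, k3=0.063, t_s=2.234,
)

HEART_RATE_MEAN_BPM = 391.1
HEART_RATE_SD_BPM = 34.4


# ---------------------------------------------------------------------------
# Elementary samplers


def sample_inhomogeneous_poisson(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    t0: float,
    t1: float,
    seed: int | np.random.Generator,
    rate_max: float | None = None,
) -> np.ndarray:
    """Spike times on [t0, t1) from an inhomogeneous Poisson process.

    Uses thinning against the supremum rate: candidates are drawn from a
    homogeneous process at ``rate_max`` and kept with probability
    ``rate_fn(t)/rate_max``.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(t0, t1, max(int((t1 - t0) * 50), 2))
    vals = np.asarray(rate_fn(grid), dtype=float)
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("rate_fn must be nonnegative and bounded")
    sup = rate_max if rate_max is not None else float(vals.max()) * 1.05
    if sup == 0:
        return np.empty(0)
    n_cand = rng.poisson(sup * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    keep = rng.uniform(0, sup, size=n_cand) < np.asarray(rate_fn(cand), dtype=float)
    return cand[keep]


def _genpois_pmf_row(theta: float, alpha: float, y_top: int) -> np.ndarray:
    ys = np.arange(y_top + 1)
    lp = _genpois_raw_logpmf(ys, theta, alpha)
    lp = lp - logsumexp(lp)
    return np.exp(lp)


def sample_generalized_poisson(
    theta, alpha: float, seed: int | np.random.Generator, size: int | None = None
) -> np.ndarray | int:
    """Draw generalized-Poisson counts by inversion from the normalised pmf.

    ``theta`` may be a scalar (with ``size`` draws) or an array of per-draw
    values. For ``alpha < 0`` the pmf is renormalised over its truncated
    support before inversion.
    """
    if abs(alpha) >= 1:
        raise ValueError("|alpha| must be < 1")
    rng = np.random.default_rng(seed)
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    scalar = np.isscalar(theta) and size is None
    if np.any(theta_arr <= 0):
        raise ValueError("theta must be positive")
    if size is not None:
        theta_arr = np.broadcast_to(theta_arr, (size,)).astype(float)
    mu = theta_arr / (1 - alpha)
    sd = np.sqrt(theta_arr / (1 - alpha) ** 3)
    y_top = int(np.max(mu + 20 * sd) + 50)
    if alpha < 0:
        y_top = min(y_top, genpois_trunc_support(theta_arr, alpha))
    ys = np.arange(y_top + 1)
    lp = _genpois_raw_logpmf(ys[None, :], theta_arr[:, None], alpha)
    lp = lp - logsumexp(lp, axis=1, keepdims=True)
    cdf = np.cumsum(np.exp(lp), axis=1)
    u = rng.uniform(size=theta_arr.size)
    draws = np.array([int(np.searchsorted(cdf[i], u[i])) for i in range(theta_arr.size)])
    draws = np.minimum(draws, y_top)
    return int(draws[0]) if scalar else draws


# ---------------------------------------------------------------------------
# Ongoing activity


@dataclass(frozen=True)
class OngoingGroundTruth:
    period: float
    latent_amp: float
    alpha: float
    phase: float
    latent: np.ndarray     # latent values at bin centers
    mean_rate: np.ndarray  # spikes/s at bin centers


def gen_ongoing_counts(
    period: float = 300.0,
    latent_amp: float = 2.0,
    lengthscale: float = 1.0,
    alpha: float = 0.5,
    A: float = 10.0,
    duration: float = 1500.0,
    bin_width: float = 5.0,
    seed: int | np.random.Generator = 0,
    mode: str = "sinusoid",
    latent_offset: float = 0.0,
    phase: float | None = None,
) -> tuple[BinnedCounts, OngoingGroundTruth]:
    """Generate quasi-periodic ongoing spike counts on a regular bin grid.

    ``mode='sinusoid'`` uses a deterministic sinusoidal latent (sharp recovery
    tests); ``mode='gp'`` draws the latent from the periodic-kernel GP. The
    latent is passed through the scaled SoftPlus link and observed as
    generalized-Poisson counts with per-bin mean ``mu_t * bin_width``.
    """
    if duration < period:
        import logging
        logging.getLogger(__name__).warning(
            "duration %.0f s < period %.0f s: period unidentifiable", duration, period)
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration / bin_width))
    t = (np.arange(n) + 0.5) * bin_width
    ph = rng.uniform(0, 2 * np.pi) if phase is None else float(phase)
    if mode == "sinusoid":
        latent = latent_offset + latent_amp * np.sin(2 * np.pi * t / period + ph)
    elif mode == "gp":
        params = PeriodicKernelParams(max(latent_amp**2, 1e-12), period, lengthscale)
        K = periodic_kernel_matrix(t, t, params) + 1e-8 * np.eye(n)
        latent = latent_offset + rng.multivariate_normal(np.zeros(n), K, method="cholesky")
    else:
        raise ValueError(f"unknown latent mode {mode!r}")
    mu_rate = softplus_link(latent, A)
    mu_bin = np.clip(mu_rate * bin_width, 1e-9, None)
    theta = mu_bin * (1 - alpha)
    counts = sample_generalized_poisson(theta, alpha, rng)
    gt = OngoingGroundTruth(period=period, latent_amp=latent_amp, alpha=alpha,
                            phase=ph, latent=latent, mean_rate=mu_rate)
    return BinnedCounts(t0=0.0, bin_width=bin_width, counts=counts), gt


def gen_heart_rate(
    duration: float = 1500.0,
    mean_bpm: float = HEART_RATE_MEAN_BPM,
    sd_bpm: float = 5.0,
    osc_period: float = 300.0,
    osc_amp: float = 0.0,
    coupled_latent: np.ndarray | None = None,
    coupling_gain: float = 0.0,
    lag: float = 0.0,
    step: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> RateSeries:
    """Heart-rate series (bpm, 2 s step): mean + oscillation (+ coupled
    latent, lagged) + white noise."""
    if mean_bpm <= 0:
        raise ValueError("mean_bpm must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration / step))
    t = np.arange(n) * step
    values = mean_bpm + sd_bpm * rng.standard_normal(n)
    if osc_amp:
        values = values + osc_amp * np.sin(2 * np.pi * (t - lag) / osc_period)
    if coupled_latent is not None and coupling_gain:
        src_t = np.arange(coupled_latent.size, dtype=float)
        src_t *= duration / max(coupled_latent.size, 1)
        values = values + coupling_gain * np.interp(t - lag, src_t, coupled_latent,
                                                    period=duration)
    return RateSeries(t0=0.0, step=step, values=np.clip(values, 0, None))


def gen_neutral_train(
    duration: float,
    rate_hz: float = 10.0,
    shape: float = 8.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Regular tonic spike times from a gamma-renewal process.

    Shape > 1 reproduces sub-Poisson regularity (CV = 1/sqrt(shape) ~ 0.35
    for shape ~ 8), which a Poisson train cannot.
    """
    rng = np.random.default_rng(seed)
    n_expect = int(duration * rate_hz * 1.5) + 50
    isis = rng.gamma(shape, 1.0 / (shape * rate_hz), size=n_expect)
    times = np.cumsum(isis)
    while times[-1] < duration:  # pragma: no cover - generous overdraw above
        more = rng.gamma(shape, 1.0 / (shape * rate_hz), size=n_expect)
        times = np.concatenate([times, times[-1] + np.cumsum(more)])
    return times[times < duration]


def gen_evoked_counts(
    variant: str,
    params,
    pre: float = 10.0,
    post: float = 100.0,
    bin_width: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> BinnedCounts:
    """Pooled evoked counts: Poisson draws around the piecewise rate.

    The rate is taken at population (pooled) scale, i.e. already summed over
    trial-equivalents, so counts are a single Poisson draw per 50 ms bin.
    """
    rng = np.random.default_rng(seed)
    n = int(round((pre + post) / bin_width))
    centers = -pre + (np.arange(n) + 0.5) * bin_width
    lam = evaluate_rate(variant, params, centers)
    if np.any(lam <= 0):
        raise ValueError("generating rate must be positive over the window")
    return BinnedCounts(t0=-pre, bin_width=bin_width, counts=rng.poisson(lam))


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for a synthetic cohort.

    Trials arrive at 5-minute intervals (3-4 per cell); ongoing modulation has
    a ~300 s period; NEUTRAL cells fire regular ~10 Hz trains; heart rate
    averages ~391 bpm.
    """

    n_animals: int = 4
    on_cells_per_animal: int = 1
    off_cells_per_animal: int = 1
    neutral_cells_per_animal: int = 1
    trials_per_cell: int = 3
    inter_trial_interval: float = 300.0
    withdrawal_latency: float = 8.7
    ongoing_period: float = 300.0
    ongoing_latent_amp: float = 2.0
    ongoing_lengthscale: float = 1.0
    ongoing_alpha_on: float = 0.5
    ongoing_alpha_off: float = 0.3
    link_scale: float = 10.0
    duration: float = 1500.0
    hr_mean_bpm: float = HEART_RATE_MEAN_BPM
    hr_noise_sd: float = 5.0
    hr_osc_amp: float = 8.0
    hr_coupling: float = 0.0
    shared_phase_strength: float = 1.0  # 1 = cells share per-animal latent phase
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.trials_per_cell < 1:
            problems.append("trials_per_cell must be >= 1")
        if not abs(self.ongoing_alpha_on) < 1 or not abs(self.ongoing_alpha_off) < 1:
            problems.append("|alpha| must be < 1")
        if self.ongoing_period <= 0:
            problems.append("ongoing_period must be positive")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class CohortGroundTruth:
    config: CohortConfig
    evoked_on: OnParams
    evoked_off: OffParams
    cell_params: dict[str, dict] = field(default_factory=dict)
    event_times: dict[str, np.ndarray] = field(default_factory=dict)


def _cell_rate_fn(cls: CellClass, per_trial_scale: float, events: np.ndarray,
                  withdrawals: np.ndarray, period: float, amp: float, phase: float,
                  A: float, bin_width_rate: float = 0.0):
    """Session-long rate function: SoftPlus ongoing modulation plus the evoked
    deviation around each trial (rates in spikes/s, clipped at 0)."""

    def fn(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        latent = amp * np.sin(2 * np.pi * t / period + phase)
        rate = softplus_link(latent, A) * 0.3  # modest ongoing baseline
        if cls is CellClass.ON:
            base = evaluate_rate("on_double_exp", ON_POPULATION_PARAMS,
                                 np.asarray([-1e3]))[0]
            for wd in withdrawals:
                m = np.abs(t - wd) <= 110
                dev = evaluate_rate("on_double_exp", ON_POPULATION_PARAMS, t[m] - wd) - base
                rate[m] += per_trial_scale * np.clip(dev, 0, None) / 0.05
        elif cls is CellClass.OFF:
            base = OFF_POPULATION_PARAMS.a
            for wd in withdrawals:
                m = np.abs(t - wd) <= 110
                dev = evaluate_rate("off_linear_exp", OFF_POPULATION_PARAMS, t[m] - wd) - base
                rate[m] += per_trial_scale * dev / 0.05
        return np.clip(rate, 0, None)

    return fn


def gen_cohort(config: CohortConfig, out_dir: str | Path | None = None,
               ) -> tuple[list[SpikeTrain], dict[str, EventTable], dict[str, RateSeries],
                          CohortGroundTruth]:
    """Generate a full synthetic cohort; optionally write the TSV trio.

    Returns spike trains, per-animal event tables and heart-rate series plus
    the generating ground truth. Deterministic in ``config.seed``: the same
    config yields byte-identical output files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gt = CohortGroundTruth(config=config, evoked_on=ON_POPULATION_PARAMS,
                           evoked_off=OFF_POPULATION_PARAMS)
    trains: list[SpikeTrain] = []
    events: dict[str, EventTable] = {}
    hr: dict[str, RateSeries] = {}

    first_onset = 2 * config.inter_trial_interval
    onsets = first_onset + config.inter_trial_interval * np.arange(config.trials_per_cell)
    duration = max(config.duration, onsets[-1] + config.inter_trial_interval)

    per_trial_scale = 1.0 / N_POOL  # population params -> single-cell, single-trial

    for ai in range(config.n_animals):
        animal = f"A{ai:02d}"
        withdrawals = onsets + config.withdrawal_latency + 0.3 * rng.standard_normal(
            config.trials_per_cell)
        events[animal] = EventTable(
            animal_id=animal,
            trial_index=np.arange(config.trials_per_cell),
            heat_onset_s=onsets.copy(),
            withdrawal_s=withdrawals,
        )
        gt.event_times[animal] = withdrawals
        animal_phase = rng.uniform(0, 2 * np.pi)
        animal_latent = np.sin(
            2 * np.pi * np.arange(0, duration, 2.0) / config.ongoing_period + animal_phase)

        specs = ([(CellClass.ON, config.on_cells_per_animal, per_trial_scale)]
                 + [(CellClass.OFF, config.off_cells_per_animal, per_trial_scale)]
                 + [(CellClass.NEUTRAL, config.neutral_cells_per_animal, 0.0)])
        for cls, n_cells, scale in specs:
            for ci in range(n_cells):
                unit = f"{cls.value.lower()}{ci}"
                cell_seed = rng.integers(0, 2**31 - 1)
                if cls is CellClass.NEUTRAL:
                    times = gen_neutral_train(duration, seed=cell_seed)
                else:
                    phase = (animal_phase if rng.uniform() < config.shared_phase_strength
                             else rng.uniform(0, 2 * np.pi))
                    fn = _cell_rate_fn(cls, scale, onsets, withdrawals,
                                       config.ongoing_period, config.ongoing_latent_amp,
                                       phase, config.link_scale)
                    times = sample_inhomogeneous_poisson(fn, 0.0, duration, cell_seed)
                    gt.cell_params[f"{animal}/{unit}"] = {
                        "period": config.ongoing_period, "phase": phase,
                        "class": cls.value,
                    }
                trains.append(SpikeTrain(unit_id=unit, animal_id=animal, cell_class=cls,
                                         spike_times=times, t_start=0.0, t_stop=duration))
        hr[animal] = gen_heart_rate(
            duration=duration, mean_bpm=config.hr_mean_bpm, sd_bpm=config.hr_noise_sd,
            osc_period=config.ongoing_period, osc_amp=config.hr_osc_amp,
            coupled_latent=animal_latent if config.hr_coupling else None,
            coupling_gain=config.hr_coupling, seed=rng.integers(0, 2**31 - 1),
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spike_table(trains, out / "spikes.tsv", span=(0.0, duration))
        write_event_table(events.values(), out / "events.tsv")
        write_hr_table(hr, out / "hr.tsv")
    return trains, events, hr, gt
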