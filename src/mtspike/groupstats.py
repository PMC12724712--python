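"""Group-level permutation inference over per-cell metrics, respecting
per-animal exchangeability, plus end-to-end pipeline orchestration.

Cells recorded from the same animal are potentially correlated, so the unit
of exchangeability is the animal: sign-flip permutations flip all of an
animal's cells jointly, and group-label permutations move all of an animal's
cells together. P-values use the +1 correction and exact enumeration when
the permutation space is small enough.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellMetric:
    cell_id: str
    animal_id: str
    cell_class: str
    value: float


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    exact: bool
    null_mean: float
    null_sd: float
    seed: int | None = None


def _group_by_animal(metrics: list[CellMetric]) -> tuple[list[str], list[np.ndarray]]:
    animals = sorted({m.animal_id for m in metrics})
    per = [np.array([m.value for m in metrics if m.animal_id == a]) for a in animals]
    return animals, per


def signflip_median_test(metrics: list[CellMetric], n_perm: int = 10_000,
                         seed: int = 0) -> PermutationResult:
    """Two-sided test of median != 0 by per-animal sign flips.

    The statistic is the median over all cells; each permutation flips the
    sign of every cell of an animal jointly (one independent +-1 per animal).
    All 2^n_animals flips are enumerated exactly when that is cheaper than
    ``n_perm`` random draws.
    """
    animals, per = _group_by_animal(metrics)
    if len(animals) < 2:
        raise ValueError("sign-flip inference requires >= 2 animals")
    values = np.concatenate(per)
    labels = np.concatenate([[i] * len(v) for i, v in enumerate(per)])
    observed = float(np.median(values))
    n_animals = len(animals)
    exact = 2 ** n_animals <= n_perm
    if exact:
        signs_iter = np.array(list(itertools.product([1.0, -1.0], repeat=n_animals)))
    else:
        rng = np.random.default_rng(seed)
        signs_iter = rng.choice([1.0, -1.0], size=(n_perm, n_animals))
    flipped = values[None, :] * signs_iter[:, labels]
    null = np.median(flipped, axis=1)
    if exact:
        # enumeration includes the identity; p is the exact proportion
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        n_used = signs_iter.shape[0]
    else:
        p = float((1 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (1 + n_perm))
        n_used = n_perm
    return PermutationResult(observed=observed, p_value=p, n_permutations=n_used,
                             exact=exact, null_mean=float(null.mean()),
                             null_sd=float(null.std()), seed=None if exact else seed)


def permuted_mannwhitney(group_a: list[CellMetric], group_b: list[CellMetric],
                         n_perm: int = 10_000, bonferroni_m: int = 1,
                         seed: int = 0) -> PermutationResult:
    """Mann-Whitney U with an animal-level label-permutation null.

    Animals (with all their cells) are reassigned between the two groups,
    preserving group sizes in animals. The reported p-value is multiplied by
    ``bonferroni_m`` and capped at 1.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    animals_a, per_a = _group_by_animal(group_a)
    animals_b, per_b = _group_by_animal(group_b)
    all_cells = per_a + per_b
    n_a = len(animals_a)
    n_tot = n_a + len(animals_b)

    def u_stat(idx_a: tuple[int, ...]) -> float:
        va = np.concatenate([all_cells[i] for i in idx_a])
        vb = np.concatenate([all_cells[i] for i in range(n_tot) if i not in idx_a])
        return float(stats.mannwhitneyu(va, vb, alternative="two-sided").statistic)

    observed = u_stat(tuple(range(n_a)))
    # center U for two-sidedness under relabelling
    def u_dev(idx_a):
        va = np.concatenate([all_cells[i] for i in idx_a])
        vb = np.concatenate([all_cells[i] for i in range(n_tot) if i not in idx_a])
        mu = len(va) * len(vb) / 2.0
        return abs(float(stats.mannwhitneyu(va, vb, alternative="two-sided").statistic) - mu)

    from math import comb
    exact = comb(n_tot, n_a) <= n_perm
    obs_dev = u_dev(tuple(range(n_a)))
    if exact:
        combos = list(itertools.combinations(range(n_tot), n_a))
        null = np.array([u_dev(cmb) for cmb in combos])
        p = float(np.mean(null >= obs_dev - 1e-12))
        n_used = len(combos)
    else:
        rng = np.random.default_rng(seed)
        null = np.array([
            u_dev(tuple(rng.choice(n_tot, size=n_a, replace=False)))
            for _ in range(n_perm)
        ])
        p = float((1 + np.sum(null >= obs_dev - 1e-12)) / (1 + n_perm))
        n_used = n_perm
    p = min(p * bonferroni_m, 1.0)
    return PermutationResult(observed=observed, p_value=p, n_permutations=n_used,
                             exact=exact, null_mean=float(null.mean()),
                             null_sd=float(null.std()), seed=None if exact else seed)


def kruskal_wallis(groups: list[list[CellMetric]]) -> PermutationResult:
    """Rank-based Kruskal-Wallis H test across >= 3 groups (chi-square ref)."""
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis requires >= 3 groups")
    arrays = [np.array([m.value for m in g]) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    h, p = stats.kruskal(*arrays)
    return PermutationResult(observed=float(h), p_value=float(p), n_permutations=0,
                             exact=True, null_mean=float(len(groups) - 1),
                             null_sd=float(np.sqrt(2 * (len(groups) - 1))))


# ---------------------------------------------------------------------------
# Pipeline orchestration


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Run synth -> spikeio -> evoked/ongoing/GP/coherence -> group stats.

    ``config`` mirrors the YAML schema: a ``synth`` block (CohortConfig
    fields) and a ``stages`` list among {"psth", "evoked", "ongoing", "gp",
    "coherence"}. Writes per-stage TSVs and a machine-readable summary;
    stages fail loudly with stage-attributed errors, partial outputs are
    retained. Reruns with the same config and seed are byte-identical.
    """
    from . import __version__
    from .spikeio import build_psth, extract_trial_window, smooth_rate, write_psth
    from .synthdata import CohortConfig, gen_cohort
    from .ongoing_spectra import isi_stats, period_scan, default_period_grid
    from .latent_gp import GPFitConfig, fit_latent_gp
    from .coherence import bin_series, max_stat_test
    from .spikeio import bin_spikes, CellClass

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["psth", "ongoing"])
    synth_cfg = CohortConfig(**{**config.get("synth", {}), "seed": seed})
    trains, events, hr, gt = gen_cohort(synth_cfg, out_dir=out / "data")
    summary: dict = {"seed": seed, "version": __version__, "stages": {}}

    if "psth" in stages:
        windows = []
        for tr in trains:
            if tr.cell_class is CellClass.ON:
                windows.extend(extract_trial_window(tr, events[tr.animal_id], "withdrawal"))
        psth = build_psth(windows, bin_width=0.05)
        write_psth(psth, out / "psth_on.tsv")
        pk = float(psth.bin_centers[int(np.argmax(psth.summed_counts))]) if psth.n_trials else np.nan
        summary["stages"]["psth"] = {"n_trials": psth.n_trials, "peak_time_s": pk}

    if "ongoing" in stages:
        rows = []
        for tr in trains:
            st = isi_stats(tr)
            rows.append({"cell": f"{tr.animal_id}/{tr.unit_id}",
                         "class": tr.cell_class.value, "cv": st.cv,
                         "mean_isi": st.mean_isi})
        summary["stages"]["ongoing"] = rows

    if "gp" in stages:
        fits = []
        for tr in trains:
            if tr.cell_class is CellClass.NEUTRAL:
                continue
            counts = bin_spikes(tr, tr.t_start, tr.t_stop, 5.0)
            fit = fit_latent_gp(counts, GPFitConfig(seed=seed, maxiter_outer=150))
            fits.append({"cell": f"{tr.animal_id}/{tr.unit_id}",
                         "class": tr.cell_class.value,
                         "period": fit.kernel.period, "alpha": fit.alpha,
                         "r2_train": fit.pseudo_r2_train, "r2_test": fit.pseudo_r2_test})
        summary["stages"]["gp"] = fits
        if len({f["cell"].split("/")[0] for f in fits}) >= 2:
            metrics = [CellMetric(f["cell"], f["cell"].split("/")[0], f["class"],
                                  f["r2_test"]) for f in fits]
            res = signflip_median_test(metrics, seed=seed)
            summary["stages"]["gp_signflip_p"] = res.p_value

    if "coherence" in stages:
        if not config.get("heart_rate", True) or not hr:
            summary["stages"]["coherence"] = "skipped: no heart-rate series"
            logger.info("coherence stage skipped: no heart rate in config")
        else:
            rows = []
            for tr in trains[: config.get("coherence_max_cells", 2)]:
                xs = bin_series(tr, 2.0)
                ys = bin_series(hr[tr.animal_id], 2.0, t0=tr.t_start, t1=tr.t_stop)
                obs, null = max_stat_test(xs, ys, n_surrogates=config.get("n_surrogates", 1000),
                                          seed=seed)
                rows.append({"cell": f"{tr.animal_id}/{tr.unit_id}",
                             "threshold": null.threshold,
                             "n_significant": int(null.significant_freqs.size)})
            summary["stages"]["coherence"] = rows

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
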