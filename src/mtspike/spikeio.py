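"""Spike-train containers, delimited-text I/O, binning, smoothing and PSTHs.

The interchange formats are plain UTF-8 tab-separated tables:

* ``spikes.tsv`` — columns ``animal_id, unit_id, cell_class, spike_time_s``
* ``events.tsv`` — columns ``animal_id, trial_index, heat_onset_s, withdrawal_s``
  (``withdrawal_s`` empty when no withdrawal occurred)
* ``hr.tsv``     — columns ``animal_id, time_s, bpm``

All times are seconds. Bins are half-open ``[left, left + width)`` anchored at
the requested origin; the trailing partial bin is dropped so that binned counts
are conserved against the source spikes over complete bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPIKE_COLUMNS = ["animal_id", "unit_id", "cell_class", "spike_time_s"]
EVENT_COLUMNS = ["animal_id", "trial_index", "heat_onset_s", "withdrawal_s"]
HR_COLUMNS = ["animal_id", "time_s", "bpm"]


class CellClass(str, Enum):
    """Functional class of a recorded unit.

    ON cells burst and OFF cells pause just before a nocifensive paw
    withdrawal; NEUTRAL cells fire tonically and regularly (~10 Hz) with no
    stimulus-linked modulation.
    """

    ON = "ON"
    OFF = "OFF"
    NEUTRAL = "NEUTRAL"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one unit over a recording span."""

    unit_id: str
    animal_id: str
    cell_class: CellClass
    spike_times: np.ndarray  # seconds, sorted
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.t_stop <= self.t_start:
            raise ValueError("t_stop must exceed t_start")
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("spike_times must be nondecreasing")
        if times.size and (times[0] < self.t_start or times[-1] > self.t_stop):
            raise ValueError("spike_times must lie within [t_start, t_stop]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def mean_rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class EventTable:
    """Per-trial event markers for one animal's evoked protocol.

    ``withdrawal_s`` entries are NaN for trials without a withdrawal. Trials
    are kept ordered by heat onset.
    """

    animal_id: str
    trial_index: np.ndarray
    heat_onset_s: np.ndarray
    withdrawal_s: np.ndarray

    def __post_init__(self) -> None:
        onset = np.asarray(self.heat_onset_s, dtype=float)
        wd = np.asarray(self.withdrawal_s, dtype=float)
        idx = np.asarray(self.trial_index, dtype=int)
        order = np.argsort(onset, kind="stable")
        object.__setattr__(self, "heat_onset_s", onset[order])
        object.__setattr__(self, "withdrawal_s", wd[order])
        object.__setattr__(self, "trial_index", idx[order])
        present = ~np.isnan(self.withdrawal_s)
        if np.any(self.withdrawal_s[present] < self.heat_onset_s[present]):
            raise ValueError("withdrawal must not precede heat onset")

    @property
    def n_trials(self) -> int:
        return int(self.heat_onset_s.size)

    def alignment_times(self, alignment: str) -> np.ndarray:
        if alignment == "heat_onset":
            return self.heat_onset_s
        if alignment == "withdrawal":
            return self.withdrawal_s
        raise ValueError(f"unknown alignment {alignment!r}")


@dataclass(frozen=True)
class BinnedCounts:
    """Regularly binned spike counts; bins are ``[t0 + i*w, t0 + (i+1)*w)``."""

    t0: float
    bin_width: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.size and (np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer)):
            counts = counts.astype(float)
            if np.any(counts < 0) or np.any(counts != np.round(counts)):
                raise ValueError("counts must be nonnegative integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class RateSeries:
    """Regularly sampled firing (or heart) rate."""

    t0: float
    step: float
    values: np.ndarray
    smoothing_width: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.step


@dataclass(frozen=True)
class AlignedWindow:
    """One trial window with spike times shifted so the alignment event is 0."""

    trial_index: int
    animal_id: str
    unit_id: str
    alignment: str
    event_time: float
    spike_times: np.ndarray  # relative to event
    pre: float
    post: float
    included: bool
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class PSTH:
    """Peri-stimulus time histogram summed over included windows."""

    alignment: str
    pre: float
    post: float
    bin_width: float
    summed_counts: np.ndarray
    n_trials: int
    n_cells: int

    @property
    def bin_centers(self) -> np.ndarray:
        return -self.pre + (np.arange(self.summed_counts.size) + 0.5) * self.bin_width

    def as_binned_counts(self) -> BinnedCounts:
        return BinnedCounts(t0=-self.pre, bin_width=self.bin_width, counts=self.summed_counts)


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_spike_table(path: str | Path) -> list[SpikeTrain]:
    """Read ``spikes.tsv`` into one :class:`SpikeTrain` per (animal, unit).

    The recording span defaults to ``[min spike, max spike]`` per unit unless
    an optional header comment ``# t_start=<s> t_stop=<s>`` is present.
    Unsorted spike times are sorted with a logged warning.
    """
    path = Path(path)
    span = _read_span_header(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse spike table {path}: {exc}") from exc
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["spike_time_s"] = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = df["spike_time_s"].isna()
    if bad.any():
        lineno = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed spike_time_s at line {lineno}")
    trains: list[SpikeTrain] = []
    for (animal, unit), grp in df.groupby(["animal_id", "unit_id"], sort=True):
        times = grp["spike_time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            logger.warning("unit %s/%s: spike times unsorted; sorting", animal, unit)
            times = np.sort(times)
        cls = CellClass(str(grp["cell_class"].iloc[0]))
        if span is not None:
            t_start, t_stop = span
        else:
            t_start, t_stop = (float(times[0]), float(times[-1])) if times.size else (0.0, 1.0)
            t_stop = max(t_stop, t_start + 1e-9)
        trains.append(
            SpikeTrain(
                unit_id=str(unit),
                animal_id=str(animal),
                cell_class=cls,
                spike_times=times,
                t_start=t_start,
                t_stop=t_stop,
            )
        )
    return trains


def _read_span_header(path: Path) -> tuple[float, float] | None:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#") and "t_start=" in first and "t_stop=" in first:
        parts = dict(
            tok.split("=") for tok in first.lstrip("#").split() if "=" in tok
        )
        return float(parts["t_start"]), float(parts["t_stop"])
    return None


def write_spike_table(
    trains: Iterable[SpikeTrain], path: str | Path, span: tuple[float, float] | None = None
) -> None:
    """Write spike trains to ``spikes.tsv`` (round-trips with reader)."""
    rows = []
    for tr in trains:
        for t in tr.spike_times:
            rows.append((tr.animal_id, tr.unit_id, tr.cell_class.value, t))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        if span is not None:
            fh.write(f"# t_start={span[0]:.9f} t_stop={span[1]:.9f}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9f")


def read_event_table(path: str | Path) -> dict[str, EventTable]:
    """Read ``events.tsv``; returns one :class:`EventTable` per animal."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for animal, grp in df.groupby("animal_id", sort=True):
        out[str(animal)] = EventTable(
            animal_id=str(animal),
            trial_index=grp["trial_index"].to_numpy(dtype=int),
            heat_onset_s=grp["heat_onset_s"].to_numpy(dtype=float),
            withdrawal_s=grp["withdrawal_s"].to_numpy(dtype=float),
        )
    return out


def write_event_table(tables: Iterable[EventTable], path: str | Path) -> None:
    rows = []
    for tab in tables:
        for i in range(tab.n_trials):
            rows.append(
                (tab.animal_id, tab.trial_index[i], tab.heat_onset_s[i], tab.withdrawal_s[i])
            )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


def read_hr_table(path: str | Path) -> dict[str, RateSeries]:
    """Read ``hr.tsv``; one bpm series per animal (assumed regular grid)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in HR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for animal, grp in df.groupby("animal_id", sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        step = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        out[str(animal)] = RateSeries(t0=float(t[0]), step=step, values=grp["bpm"].to_numpy())
    return out


def write_hr_table(series: dict[str, RateSeries], path: str | Path) -> None:
    rows = []
    for animal, rs in series.items():
        for t, v in zip(rs.times, rs.values):
            rows.append((animal, t, v))
    df = pd.DataFrame(rows, columns=HR_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Binning / smoothing


def bin_spikes(train: SpikeTrain, t0: float, t1: float, width: float) -> BinnedCounts:
    """Bin spike counts on half-open bins ``[t0+i*w, t0+(i+1)*w)`` in [t0, t1).

    A trailing partial bin (when ``t1 - t0`` is not a multiple of ``width``)
    is dropped.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    n_bins = int(np.floor((t1 - t0) / width + 1e-12))
    if n_bins == 0:
        return BinnedCounts(t0=t0, bin_width=width, counts=np.zeros(0, dtype=np.int64))
    edges = t0 + width * np.arange(n_bins + 1)
    counts, _ = np.histogram(train.spike_times, bins=edges)
    # np.histogram closes the last bin on the right; subtract spikes exactly at
    # the final edge to keep every bin half-open.
    if np.any(train.spike_times == edges[-1]):
        counts[-1] -= int(np.sum(train.spike_times == edges[-1]))
    return BinnedCounts(t0=t0, bin_width=width, counts=counts.astype(np.int64))


def bin_counts_array(times: np.ndarray, t0: float, n_bins: int, width: float) -> np.ndarray:
    """Half-open histogram of ``times`` onto a fixed grid (helper for PSTHs)."""
    edges = t0 + width * np.arange(n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    if np.any(times == edges[-1]):
        counts[-1] -= int(np.sum(times == edges[-1]))
    return counts.astype(np.int64)


def smooth_rate(
    train: SpikeTrain,
    width: float = 2.0,
    step: float = 2.0,
    kernel: str = "boxcar",
) -> RateSeries:
    """Convert spikes to a smoothed firing rate (spikes/s).

    A boxcar kernel of ``width`` seconds centred on each sample converts
    counts to rate; samples are spaced ``step`` seconds. The first and last
    ``width`` seconds of the recording are trimmed to avoid edge artifacts
    from the smoothing window. ``kernel='gaussian'`` swaps in a Gaussian of
    SD ``width/2`` (documented extension point).
    """
    span = train.duration
    if span <= 2 * width:
        raise ValueError("recording span too short for smoothing trim")
    t_lo = train.t_start + width
    t_hi = train.t_stop - width
    n = int(np.floor((t_hi - t_lo) / step + 1e-12))
    if n <= 0:
        raise ValueError("recording span too short for smoothing trim")
    centers = t_lo + step * np.arange(n)
    if kernel == "boxcar":
        lo = np.searchsorted(train.spike_times, centers - width / 2, side="left")
        hi = np.searchsorted(train.spike_times, centers + width / 2, side="left")
        values = (hi - lo) / width
    elif kernel == "gaussian":
        sd = width / 2
        if train.n_spikes:
            diffs = centers[:, None] - train.spike_times[None, :]
            values = np.exp(-0.5 * (diffs / sd) ** 2).sum(axis=1) / (sd * np.sqrt(2 * np.pi))
        else:
            values = np.zeros(n)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return RateSeries(t0=float(centers[0]), step=step, values=values, smoothing_width=width)


# ---------------------------------------------------------------------------
# Trial windows / PSTH


def extract_trial_window(
    train: SpikeTrain,
    events: EventTable,
    alignment: str,
    pre: float = 10.0,
    post: float = 100.0,
) -> list[AlignedWindow]:
    """Extract per-trial spike windows around the alignment event.

    Spike times are shifted so the alignment event sits at 0 (window spans
    ``[-pre, +post]``). A window is flagged excluded when the recording ends
    before ``event + post`` or the next trial's event intrudes before
    ``event + post``; trials with no alignment marker are skipped with a log
    entry.
    """
    align_times = events.alignment_times(alignment)
    next_onsets = np.append(events.heat_onset_s[1:], np.inf)
    windows: list[AlignedWindow] = []
    for i in range(events.n_trials):
        ev = align_times[i]
        if np.isnan(ev):
            logger.info(
                "trial %d of animal %s: no %s marker; skipped",
                events.trial_index[i], events.animal_id, alignment,
            )
            continue
        reason = None
        if train.t_stop < ev + post:
            reason = "recording_end"
        elif next_onsets[i] < ev + post:
            reason = "next_trial"
        mask = (train.spike_times >= ev - pre) & (train.spike_times < ev + post)
        windows.append(
            AlignedWindow(
                trial_index=int(events.trial_index[i]),
                animal_id=train.animal_id,
                unit_id=train.unit_id,
                alignment=alignment,
                event_time=float(ev),
                spike_times=train.spike_times[mask] - ev,
                pre=pre,
                post=post,
                included=reason is None,
                exclusion_reason=reason,
            )
        )
    return windows


def build_psth(windows: Sequence[AlignedWindow], bin_width: float = 0.05) -> PSTH:
    """Sum included aligned windows into a population PSTH."""
    if not windows:
        return PSTH(
            alignment="withdrawal", pre=10.0, post=100.0, bin_width=bin_width,
            summed_counts=np.zeros(0, dtype=np.int64), n_trials=0, n_cells=0,
        )
    alignments = {w.alignment for w in windows}
    if len(alignments) > 1:
        raise ValueError(f"mixed alignments in PSTH input: {sorted(alignments)}")
    spans = {(w.pre, w.post) for w in windows}
    if len(spans) > 1:
        raise ValueError("windows with mixed spans cannot be pooled")
    pre, post = spans.pop()
    n_bins = int(np.floor((pre + post) / bin_width + 1e-12))
    total = np.zeros(n_bins, dtype=np.int64)
    n_included = 0
    cells = set()
    for w in windows:
        if not w.included:
            continue
        total += bin_counts_array(w.spike_times, -pre, n_bins, bin_width)
        n_included += 1
        cells.add((w.animal_id, w.unit_id))
    return PSTH(
        alignment=alignments.pop(), pre=pre, post=post, bin_width=bin_width,
        summed_counts=total, n_trials=n_included, n_cells=len(cells),
    )


def write_psth(psth: PSTH, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": psth.bin_centers, "summed_count": psth.summed_counts})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# alignment={psth.alignment} bin_width={psth.bin_width} "
            f"n_trials={psth.n_trials} n_cells={psth.n_cells}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.9f")


def read_psth(path: str | Path) -> PSTH:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    meta = dict(tok.split("=") for tok in header.lstrip("#").split() if "=" in tok)
    df = pd.read_csv(path, sep="\t", comment="#")
    bin_width = float(meta["bin_width"])
    t_first = float(df["time_s"].iloc[0]) - bin_width / 2
    counts = df["summed_count"].to_numpy(dtype=np.int64)
    pre = -t_first
    post = t_first + bin_width * len(counts)
    return PSTH(
        alignment=meta.get("alignment", "withdrawal"), pre=pre, post=post,
        bin_width=bin_width, summed_counts=counts,
        n_trials=int(meta.get("n_trials", 0)), n_cells=int(meta.get("n_cells", 0)),
    )
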