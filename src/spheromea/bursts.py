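"""Adaptive log-ISI burst detection and the burstiness metric.

Per-unit burst detection uses the classic adaptive-threshold idea: the
base-10 log interspike-interval (ISI) histogram of a bursting unit is
bimodal, with a short-ISI mode from within-burst firing and a long-ISI
mode from interburst periods.  The valley between two sufficiently
separated peaks (void parameter >= 0.7, intra-burst peak below 100 ms)
sets the per-unit ISI threshold.  When no qualifying peak pair exists
the threshold falls back to 0.1 s; when the adaptive threshold exceeds
0.1 s, only candidate bursts that fully enclose a burst detected at the
fixed 0.1 s threshold are accepted.  Bursts with fewer than
``max(3, ceil(N_total / 3000))`` spikes are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .model import Unit

__all__ = [
    "LogISIHistogram",
    "Burst",
    "log_isi_histogram",
    "find_burst_threshold",
    "detect_bursts",
    "burstiness",
    "analyze_unit",
    "FALLBACK_THRESHOLD_S",
]

#: fixed ISI threshold (s) used when the histogram shows no clear bimodality,
#: and as the inner threshold of the enclosure rule
FALLBACK_THRESHOLD_S = 0.1
#: minimum void parameter for a peak pair to count as bimodal
VOID_MIN = 0.7
#: the intra-burst peak must lie below this ISI (s)
INTRA_PEAK_MAX_S = 0.1
#: minimum spikes per burst, before the N/3000 scaling floor
MIN_BURST_SPIKES = 3
#: a histogram peak must reach this fraction of the tallest bin to count;
#: guards the void parameter against sampling-noise micro-peaks
PEAK_HEIGHT_FRAC = 0.05
#: SD (in bins) of the Gaussian smoothing applied before peak finding
SMOOTH_SIGMA_BINS = 1.5


@dataclass
class LogISIHistogram:
    """Probability mass function over uniform base-10 log ISI bins."""

    bin_edges: np.ndarray   # log10 seconds, uniform width, length N + 1
    p: np.ndarray           # probability mass per bin, sums to 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != self.bin_edges.size - 1:
            raise ValueError("need one more edge than bins")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have equal log10 width")
        if np.any(self.p < 0):
            raise ValueError("probability mass must be >= 0")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("probability mass must sum to 1")

    @property
    def n_bins(self) -> int:
        return int(self.p.size)

    @property
    def centers_log10(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def centers_s(self) -> np.ndarray:
        return 10.0 ** self.centers_log10


@dataclass
class Burst:
    """A detected burst: the closed interval [first spike, last spike]."""

    unit_id: str
    start: float
    end: float
    n_spikes: int
    spike_indices: np.ndarray

    @property
    def duration(self) -> float:
        return self.end - self.start


def log_isi_histogram(spike_times: np.ndarray, bins_per_decade: int = 10,
                      isi_range: tuple[float, float] = (1e-3, 1e2)
                      ) -> LogISIHistogram:
    """Histogram the unit's ISIs on a uniform base-10 log grid.

    ISIs outside ``isi_range`` are clipped into it.  Requires at least
    three spikes (two ISIs).
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 spikes to form an ISI histogram")
    lo, hi = isi_range
    isis = np.clip(np.diff(t), lo, hi)
    n_bins = int(round(bins_per_decade * math.log10(hi / lo)))
    edges = np.linspace(math.log10(lo), math.log10(hi), n_bins + 1)
    counts, _ = np.histogram(np.log10(isis), bins=edges)
    # clipped ISIs sitting exactly on the top edge belong to the last bin
    counts[-1] += np.count_nonzero(np.log10(isis) >= edges[-1])
    return LogISIHistogram(bin_edges=edges, p=counts / counts.sum())


def find_burst_threshold(hist: LogISIHistogram, void_min: float = VOID_MIN,
                         intra_peak_max_s: float = INTRA_PEAK_MAX_S,
                         fallback_s: float = FALLBACK_THRESHOLD_S,
                         peak_height_frac: float = PEAK_HEIGHT_FRAC
                         ) -> tuple[float, str]:
    """Derive the per-unit ISI burst threshold from the log-ISI histogram.

    Returns ``(threshold_s, flag)`` where flag is one of

    * ``"adaptive"`` - valley of a qualifying peak pair, at most 0.1 s;
    * ``"enclosure-required"`` - qualifying valley above 0.1 s, so
      detected bursts must enclose a 0.1 s burst;
    * ``"fallback"`` - no qualifying bimodality, threshold fixed at 0.1 s.
    """
    p = ndimage.gaussian_filter1d(hist.p, SMOOTH_SIGMA_BINS, mode="nearest")
    centers = hist.centers_s
    min_height = peak_height_frac * p.max()
    peaks, _ = signal.find_peaks(p, height=min_height)
    # plateau-safe: include boundary maxima
    if p.size >= 2:
        if p[0] > p[1] and p[0] >= min_height:
            peaks = np.concatenate([[0], peaks])
        if p[-1] > p[-2] and p[-1] >= min_height:
            peaks = np.concatenate([peaks, [p.size - 1]])
    peaks = np.sort(peaks.astype(int))

    best: tuple[float, int] | None = None  # (void, valley_bin)
    for a_i in range(len(peaks)):
        i = peaks[a_i]
        if centers[i] >= intra_peak_max_s:
            continue  # intra-burst peak must be below 100 ms
        for b_i in range(a_i + 1, len(peaks)):
            j = peaks[b_i]
            seg = p[i:j + 1]
            v = int(np.argmin(seg)) + i
            denom = math.sqrt(p[i] * p[j])
            if denom == 0:
                continue
            void = 1.0 - p[v] / denom
            if void >= void_min and (best is None or void > best[0]):
                best = (void, v)
    if best is None:
        return fallback_s, "fallback"
    threshold = float(centers[best[1]])
    flag = "enclosure-required" if threshold > fallback_s else "adaptive"
    return threshold, flag


def _candidate_runs(spike_times: np.ndarray, threshold: float
                    ) -> list[tuple[int, int]]:
    """Maximal runs of consecutive spikes with every ISI <= threshold.

    Returns (start_index, end_index) pairs, end inclusive; singleton
    spikes form runs of length 1.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return []
    ok = np.diff(t) <= threshold
    runs: list[tuple[int, int]] = []
    start = 0
    for i, good in enumerate(ok):
        if not good:
            runs.append((start, i))
            start = i + 1
    runs.append((start, t.size - 1))
    return runs


def detect_bursts(unit: Unit, threshold: float, flag: str = "adaptive",
                  min_spikes: int = MIN_BURST_SPIKES,
                  size_divisor: int = 3000,
                  enclosure_threshold_s: float = FALLBACK_THRESHOLD_S
                  ) -> list[Burst]:
    """Detect bursts of one unit given its ISI threshold.

    Candidate bursts are maximal runs of consecutive spikes whose ISIs
    are all <= ``threshold``.  Candidates with fewer than
    ``max(min_spikes, ceil(N_total / size_divisor))`` spikes are dropped.
    With ``flag == "enclosure-required"`` a candidate is kept only if it
    fully encloses a burst detected at the fixed 0.1 s threshold (same
    size floor applied).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = unit.spike_times
    n_total = t.size
    floor = max(min_spikes, math.ceil(n_total / size_divisor))

    runs = [(a, b) for a, b in _candidate_runs(t, threshold)
            if b - a + 1 >= floor]
    if flag == "enclosure-required":
        inner = [(a, b) for a, b in _candidate_runs(t, enclosure_threshold_s)
                 if b - a + 1 >= floor]
        runs = [(a, b) for a, b in runs
                if any(a <= ia and ib <= b for ia, ib in inner)]
    return [Burst(unit_id=unit.unit_id, start=float(t[a]), end=float(t[b]),
                  n_spikes=b - a + 1, spike_indices=np.arange(a, b + 1))
            for a, b in runs]


def burstiness(unit: Unit, bursts: list[Burst]) -> float:
    """Fraction of the unit's spikes that fall inside its bursts."""
    if unit.n_spikes == 0:
        raise ValueError("burstiness undefined for a unit without spikes")
    return sum(b.n_spikes for b in bursts) / unit.n_spikes


def analyze_unit(unit: Unit, bins_per_decade: int = 10,
                 isi_range: tuple[float, float] = (1e-3, 1e2),
                 void_min: float = VOID_MIN) -> tuple[float, str, list[Burst]]:
    """Full per-unit burst analysis: histogram -> threshold -> bursts.

    Units with fewer than three spikes are non-bursting by definition
    and return ``(nan, "too-few-spikes", [])``.
    """
    if unit.n_spikes < 3:
        return float("nan"), "too-few-spikes", []
    hist = log_isi_histogram(unit.spike_times, bins_per_decade, isi_range)
    threshold, flag = find_burst_threshold(hist, void_min=void_min)
    return threshold, flag, detect_bursts(unit, threshold, flag)
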