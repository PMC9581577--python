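"""Per-unit and pairwise activity metrics.

Covers the activity-rate definitions (a unit is "active" above 10
spikes/min; the mean firing rate averages only active units), the
Shannon entropy of the log-ISI histogram, and the pairwise correlation
of log10 instantaneous-rate vectors sampled at 320 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import LogISIHistogram
from .model import Unit

__all__ = [
    "RATE_VECTOR_FS",
    "ACTIVE_SPIKES_PER_MIN",
    "EntropyValue",
    "is_active",
    "mean_firing_rate",
    "entropy",
    "rate_vector",
    "pairwise_correlation",
    "mean_correlation",
]

#: sample rate of instantaneous-rate vectors (Hz)
RATE_VECTOR_FS = 320.0
#: activity criterion: strictly more than this many spikes per minute
ACTIVE_SPIKES_PER_MIN = 10.0


@dataclass(frozen=True)
class EntropyValue:
    unit_id: str
    entropy: float  # nats


def is_active(unit: Unit, duration: float) -> bool:
    """True iff the unit fires strictly more than 10 spikes/min."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return unit.n_spikes / (duration / 60.0) > ACTIVE_SPIKES_PER_MIN


def mean_firing_rate(units: list[Unit], duration: float) -> float | None:
    """Mean firing rate (spikes/s) over active units; None if none active."""
    rates = [u.n_spikes / duration for u in units if is_active(u, duration)]
    return float(np.mean(rates)) if rates else None


def entropy(hist: LogISIHistogram, unit_id: str = "") -> EntropyValue:
    """Shannon entropy -sum(p_i ln p_i) of the log-ISI histogram, in nats.

    Zero for a single occupied bin (clock-like firing), ln N for a
    uniform histogram; empty bins contribute nothing (0 ln 0 == 0).
    """
    p = hist.p
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("histogram must be normalized to sum to 1")
    nz = p[p > 0]
    return EntropyValue(unit_id=unit_id, entropy=float(-np.sum(nz * np.log(nz))))


def rate_vector(unit: Unit, duration: float,
                fs: float = RATE_VECTOR_FS) -> np.ndarray:
    """log10 instantaneous firing rate, piecewise constant at ``fs`` Hz.

    Each consecutive spike pair (t_i, t_{i+1}) contributes the value
    log10(1 / (t_{i+1} - t_i)) over [t_i, t_{i+1}); before the first and
    after the last spike the adjacent interval's value is extended, so
    the vector is defined over the whole recording.
    """
    t = unit.spike_times
    if t.size < 2:
        raise ValueError("need >= 2 spikes to form a rate vector")
    n = int(round(duration * fs))
    grid = np.arange(n) / fs
    log_rate = -np.log10(np.diff(t))
    idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, log_rate.size - 1)
    return log_rate[idx]


def pairwise_correlation(vectors: dict[str, np.ndarray],
                         unit_to_electrode: dict[str, str]
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero-lag Pearson correlation between all unit pairs.

    Returns ``(corr, excluded)`` DataFrames indexed by unit id.  A pair
    is excluded (correlation set to NaN, flag True) when both units sit
    on the same electrode -- spike-sorting artifacts produce spurious
    negative correlations there -- or when either vector has zero
    variance.
    """
    ids = sorted(vectors)
    if len(ids) < 2:
        raise ValueError("need >= 2 rate vectors")
    X = np.vstack([vectors[u] for u in ids])
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    excluded = np.zeros((len(ids), len(ids)), dtype=bool)
    for i in range(len(ids)):
        for j in range(len(ids)):
            if i == j:
                continue
            same = unit_to_electrode[ids[i]] == unit_to_electrode[ids[j]]
            if same or sd[i] == 0 or sd[j] == 0:
                excluded[i, j] = True
                corr[i, j] = np.nan
    return (pd.DataFrame(corr, index=ids, columns=ids),
            pd.DataFrame(excluded, index=ids, columns=ids))


def mean_correlation(corr: pd.DataFrame, excluded: pd.DataFrame) -> float | None:
    """Mean coefficient over included off-diagonal pairs (upper triangle)."""
    vals = []
    ids = corr.index
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if not excluded.iat[i, j] and np.isfinite(corr.iat[i, j]):
                vals.append(corr.iat[i, j])
    return float(np.mean(vals)) if vals else None
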