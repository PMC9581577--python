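"""PCA + scanning k-means spike sorting with automatic unit-count choice.

Detected waveforms on one electrode are projected onto their top two
principal components; k-means is then run for k = 1..k_max and the mean
within-cluster radius r(k) recorded.  For well-separated units r(k)
drops sharply once k reaches the true unit count and then resumes a
smooth power-law-like decay; the "knee" is found as the k whose log r
falls furthest below a log-log least-squares fit, accepted only when
the relative radius drop from k-1 to k exceeds a minimum (20% by
default).  Otherwise the electrode is treated as a single unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .detection import SpikeEvent
from .model import Unit

__all__ = ["SortingResult", "waveform_pca", "estimate_unit_count",
           "sort_electrode", "sort_all"]

#: minimum relative drop in mean cluster radius for a knee to be accepted
MIN_RADIUS_DROP = 0.20


@dataclass
class SortingResult:
    electrode_id: str
    chosen_k: int
    labels: np.ndarray                      # 1-based, one per event
    mean_cluster_radius_curve: np.ndarray   # r(k) for k = 1..k_max
    pc_scores: np.ndarray                   # (n_events, 2)
    units: list[Unit] = field(default_factory=list)


def waveform_pca(waveforms: np.ndarray) -> np.ndarray:
    """Project waveforms onto their top-2 principal axes.

    Returns an (n_events, 2) score array.  Requires >= 2 events of equal
    length; degenerate (zero-variance) inputs give all-zero scores.
    """
    W = np.asarray(waveforms, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need >= 2 equal-length waveforms")
    centered = W - W.mean(axis=0)
    if not np.any(centered):
        return np.zeros((W.shape[0], 2))
    n_comp = min(2, W.shape[0], W.shape[1])
    scores = PCA(n_components=n_comp).fit_transform(W)
    if n_comp < 2:
        scores = np.column_stack([scores, np.zeros(W.shape[0])])
    return scores


def _mean_cluster_radius(points: np.ndarray, labels: np.ndarray,
                         centers: np.ndarray) -> float:
    # membership-weighted mean over clusters == plain mean over points
    return float(np.mean(np.linalg.norm(points - centers[labels], axis=1)))


def estimate_unit_count(pc_scores: np.ndarray, k_max: int = 6,
                        n_restarts: int = 10, seed: int = 0
                        ) -> tuple[int, np.ndarray]:
    """Scan k-means over k = 1..k_max and pick the knee of the radius curve.

    Returns ``(chosen_k, radius_curve)``.
    """
    X = np.asarray(pc_scores, dtype=float)
    n = X.shape[0]
    k_max = min(k_max, n)
    radii = np.empty(k_max)
    labelings: list[np.ndarray] = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(X)
        radii[k - 1] = _mean_cluster_radius(X, lab, km.cluster_centers_)
        labelings.append(lab)
    if k_max == 1 or radii[0] == 0:
        return 1, radii

    # least-squares line through log r(k) vs log k; most negative residual
    # marks the knee candidate
    valid = radii > 0
    ks = np.arange(1, k_max + 1)
    logk, logr = np.log(ks[valid]), np.log(radii[valid])
    if logk.size < 2:
        return 1, radii
    slope, intercept = np.polyfit(logk, logr, 1)
    resid = np.full(k_max, np.inf)
    resid[valid] = logr - (slope * np.log(ks[valid]) + intercept)
    resid[0] = np.inf  # k = 1 is the no-structure baseline
    cand = int(np.argmin(resid)) + 1
    if resid[cand - 1] >= 0:
        return 1, radii
    drop = (radii[cand - 2] - radii[cand - 1]) / radii[cand - 2]
    if drop <= MIN_RADIUS_DROP:
        return 1, radii
    return cand, radii


def sort_electrode(events: list[SpikeEvent], k_max: int = 6,
                   n_restarts: int = 10, seed: int = 0) -> SortingResult:
    """Sort all events of one electrode into putative units.

    Fewer than two events skips sorting: every event is labelled unit 1.
    """
    if not events:
        raise ValueError("no events to sort")
    eid = events[0].electrode_id
    times = np.array([e.peak_time for e in events])
    W = np.array([e.waveform for e in events])

    if len(events) < 2:
        labels = np.ones(len(events), dtype=int)
        scores = np.zeros((len(events), 2))
        radii = np.zeros(1)
        chosen_k = 1
    else:
        scores = waveform_pca(W)
        chosen_k, radii = estimate_unit_count(scores, k_max=k_max,
                                              n_restarts=n_restarts, seed=seed)
        if chosen_k == 1:
            labels = np.ones(len(events), dtype=int)
        else:
            km = KMeans(n_clusters=chosen_k, n_init=n_restarts, random_state=seed)
            labels = km.fit_predict(scores) + 1

    units = []
    for lab in range(1, chosen_k + 1):
        idx = np.flatnonzero(labels == lab)
        order = idx[np.argsort(times[idx])]
        units.append(Unit(
            unit_id=f"{eid}u{lab}",
            electrode_id=eid,
            spike_times=times[order],
            mean_waveform=W[idx].mean(axis=0),
        ))
    return SortingResult(electrode_id=eid, chosen_k=chosen_k, labels=labels,
                         mean_cluster_radius_curve=radii, pc_scores=scores,
                         units=units)


def sort_all(events_by_electrode: dict[str, list[SpikeEvent]], k_max: int = 6,
             n_restarts: int = 10, seed: int = 0) -> list[Unit]:
    """Sort every electrode; returns the pooled unit list."""
    units: list[Unit] = []
    for eid in sorted(events_by_electrode):
        evs = events_by_electrode[eid]
        if not evs:
            continue
        units.extend(sort_electrode(evs, k_max=k_max, n_restarts=n_restarts,
                                    seed=seed).units)
    return units
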