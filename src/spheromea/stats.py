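"""Bootstrap confidence intervals and morphology-activity stratifications.

All interval estimates in the pipeline are bootstrap percentile
intervals: the data are resampled with replacement 6000 times and the
5th and 95th percentiles of the resampled means bound the interval.
Stratified comparisons link morphology to activity: per-electrode
burstiness percentile groups against clusterness, and per-MEA
network-burst-duration tertiles / correlation median splits against the
cluster ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapCI",
    "bootstrap_ci",
    "burstiness_groups",
    "stratify_meas",
    "group_cis",
    "morphology_activity_table",
    "N_RESAMPLES",
]

logger = logging.getLogger(__name__)

#: default number of bootstrap resamples
N_RESAMPLES = 6000


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval for a sample mean (nominal 90%)."""

    estimate: float
    lo: float
    hi: float
    n_resamples: int
    seed: int


def bootstrap_ci(values: np.ndarray, n_resamples: int = N_RESAMPLES,
                 seed: int = 0) -> BootstrapCI:
    """5th-95th percentile interval of resampled means.

    Deterministic for a fixed seed; degenerate (constant) data collapse
    the interval onto the mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap requires at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [5, 95])
    return BootstrapCI(estimate=float(values.mean()), lo=float(lo),
                       hi=float(hi), n_resamples=n_resamples, seed=seed)


def burstiness_groups(df: pd.DataFrame) -> pd.Series:
    """Label electrodes by burstiness percentile group.

    ``df`` needs columns ``burstiness`` and ``n_bursts``.  Electrodes
    with zero detected bursts are ``nonbursting``; the remainder are
    ranked by burstiness: ``top5`` at or above the 95th percentile
    (ties at the boundary included), ``p1_3`` between the 1st and 3rd
    percentiles inclusive, everything else ``other``.
    """
    if df.empty:
        raise ValueError("no electrodes to group")
    labels = pd.Series("other", index=df.index, dtype=object)
    nonbursting = df["n_bursts"] == 0
    labels[nonbursting] = "nonbursting"
    bursting = df.loc[~nonbursting, "burstiness"].astype(float)
    if not bursting.empty:
        p95 = np.percentile(bursting, 95)
        p1, p3 = np.percentile(bursting, [1, 3])
        labels[bursting[bursting >= p95].index] = "top5"
        labels[bursting[(bursting >= p1) & (bursting <= p3)].index] = "p1_3"
    return labels


def stratify_meas(df: pd.DataFrame, key: str, n_groups: int) -> pd.Series:
    """Quantile-based group assignment of MEAs, separately per date.

    ``df`` needs columns ``mea_id``, ``date`` and ``key``.  Within each
    date, MEAs are sorted ascending by the key (ties broken by MEA id)
    and split into ``n_groups`` contiguous groups; when the count does
    not divide evenly the earlier (lower-valued) groups take the extra
    members (7 MEAs in tertiles -> 3/2/2).  Dates with fewer than
    ``n_groups`` MEAs are skipped with a log message.  Labels are
    integers 0 (lowest key values) .. n_groups - 1.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    out = pd.Series(pd.NA, index=df.index, dtype="Int64")
    for date, sub in df.groupby("date"):
        sub = sub.dropna(subset=[key])
        if len(sub) < n_groups:
            logger.info("date %s skipped: %d MEAs < %d groups",
                        date, len(sub), n_groups)
            continue
        order = sub.sort_values([key, "mea_id"]).index
        base, extra = divmod(len(order), n_groups)
        sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
        pos = 0
        for g, size in enumerate(sizes):
            out[order[pos:pos + size]] = g
            pos += size
    return out


def group_cis(df: pd.DataFrame, value_col: str, group_col: str,
              n_resamples: int = N_RESAMPLES, seed: int = 0) -> pd.DataFrame:
    """Bootstrap CI of the mean of ``value_col`` within each group."""
    rows = []
    for g, sub in df.groupby(group_col, dropna=True):
        vals = sub[value_col].dropna().to_numpy()
        if vals.size == 0:
            continue
        ci = bootstrap_ci(vals, n_resamples=n_resamples, seed=seed)
        rows.append({group_col: g, "n": vals.size, "mean": ci.estimate,
                     "lo": ci.lo, "hi": ci.hi})
    return pd.DataFrame(rows)


def morphology_activity_table(electrode_df: pd.DataFrame,
                              mea_df: pd.DataFrame,
                              n_resamples: int = N_RESAMPLES,
                              seed: int = 0) -> dict[str, pd.DataFrame]:
    """Join morphology and activity at electrode and MEA level.

    ``electrode_df``: one row per electrode per recording with columns
    ``mea_id, date, burstiness, n_bursts, clusterness``.
    ``mea_df``: one row per MEA per date with columns
    ``mea_id, date, cluster_ratio, nb_duration, mean_correlation``.

    Returns per-electrode and per-MEA tables with group labels plus
    per-group bootstrap CI summaries (clusterness by burstiness group;
    cluster ratio by NB-duration tertile and correlation half).
    Unmatched or empty inputs degrade gracefully: each table is built
    from whatever rows are available.
    """
    out: dict[str, pd.DataFrame] = {}

    edf = electrode_df.copy()
    if not edf.empty:
        edf["burstiness_group"] = burstiness_groups(edf)
        out["per_electrode"] = edf
        out["clusterness_by_burstiness"] = group_cis(
            edf.dropna(subset=["clusterness"]), "clusterness",
            "burstiness_group", n_resamples, seed)
    else:
        out["per_electrode"] = edf

    mdf = mea_df.copy()
    if not mdf.empty:
        mdf["nb_duration_tertile"] = stratify_meas(mdf, "nb_duration", 3)
        mdf["correlation_half"] = stratify_meas(mdf, "mean_correlation", 2)
        out["per_mea"] = mdf
        out["cluster_ratio_by_nb_tertile"] = group_cis(
            mdf.dropna(subset=["cluster_ratio"]), "cluster_ratio",
            "nb_duration_tertile", n_resamples, seed)
        out["cluster_ratio_by_correlation_half"] = group_cis(
            mdf.dropna(subset=["cluster_ratio"]), "cluster_ratio",
            "correlation_half", n_resamples, seed)
    else:
        out["per_mea"] = mdf
    return out
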