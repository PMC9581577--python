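"""End-to-end orchestration: raw recording -> reports.

``analyze_recording`` runs the electrophysiology chain (filter ->
detect -> sort -> bursts -> network bursts -> metrics) on one
recording; ``analyze_image`` runs the imaging chain on one montage;
``run_pipeline`` ties multiple MEAs together, joins morphology with
activity, and writes tidy CSV/JSON reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as burst_mod
from . import detection, imaging, metrics, network, sorting, stats
from .config import RunConfig
from .io import read_recording, units_to_csv
from .model import RawRecording, Unit

__all__ = ["RecordingReport", "analyze_recording", "analyze_image",
           "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RecordingReport:
    """All per-recording analysis products."""

    units: list[Unit]
    bursts_by_unit: dict[str, list[burst_mod.Burst]]
    thresholds: dict[str, tuple[float, str]]
    nbs: list[network.NetworkBurst]
    unit_table: pd.DataFrame
    nb_count_per_10min: float
    nb_mean_duration: float | None
    mfr: float | None
    mean_correlation: float | None
    correlation: pd.DataFrame | None = None
    excluded_pairs: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def analyze_recording(rec: RawRecording, config: RunConfig | None = None
                      ) -> RecordingReport:
    """Run the full electrophysiology chain on one recording."""
    cfg = config or RunConfig()
    filtered = detection.bandpass_filter(rec, cfg.filter_low_hz,
                                         cfg.filter_high_hz, cfg.filter_order)
    events = detection.detect_all(filtered, k=cfg.detect_k_sd,
                                  dead_time=cfg.dead_time_s,
                                  pre=cfg.waveform_pre_s,
                                  post=cfg.waveform_post_s)
    units = sorting.sort_all(events, k_max=cfg.sort_k_max,
                             n_restarts=cfg.sort_n_restarts,
                             seed=cfg.subseed("sorting"))

    thresholds: dict[str, tuple[float, str]] = {}
    bursts_by_unit: dict[str, list[burst_mod.Burst]] = {}
    for u in units:
        thr, flag, bs = burst_mod.analyze_unit(
            u, bins_per_decade=cfg.bins_per_decade,
            isi_range=cfg.isi_range_s, void_min=cfg.void_min)
        thresholds[u.unit_id] = (thr, flag)
        bursts_by_unit[u.unit_id] = bs

    series = network.burst_count_series(bursts_by_unit, rec.duration,
                                        dt=cfg.nb_dt_s)
    thr_nb = network.nb_threshold(series)
    nbs = network.detect_network_bursts(series, thr_nb, units, bursts_by_unit,
                                        min_spikes=cfg.min_nb_spikes,
                                        size_divisor=cfg.nb_size_divisor)
    summary = network.nb_summary(nbs, rec.duration)

    # per-unit metric table
    rows = []
    for u in units:
        active = metrics.is_active(u, rec.duration)
        b = bursts_by_unit[u.unit_id]
        ent = np.nan
        if u.n_spikes >= 3:
            hist = burst_mod.log_isi_histogram(u.spike_times,
                                               cfg.bins_per_decade,
                                               cfg.isi_range_s)
            ent = metrics.entropy(hist, u.unit_id).entropy
        rows.append({
            "unit_id": u.unit_id,
            "electrode_id": u.electrode_id,
            "n_spikes": u.n_spikes,
            "active": active,
            "firing_rate_hz": u.n_spikes / rec.duration,
            "n_bursts": len(b),
            "burstiness": (burst_mod.burstiness(u, b)
                           if u.n_spikes else np.nan),
            "network_burstiness": (network.network_burstiness(u, nbs)
                                   if u.n_spikes else np.nan),
            "entropy_nats": ent,
        })
    unit_table = pd.DataFrame(rows)

    # pairwise correlation over active units on >= 2 electrodes
    corr = excl = None
    mean_corr = None
    active_units = [u for u in units
                    if metrics.is_active(u, rec.duration) and u.n_spikes >= 2]
    if len(active_units) >= 2 and len({u.electrode_id for u in active_units}) >= 2:
        vectors = {u.unit_id: metrics.rate_vector(u, rec.duration,
                                                  cfg.rate_vector_fs)
                   for u in active_units}
        corr, excl = metrics.pairwise_correlation(
            vectors, {u.unit_id: u.electrode_id for u in active_units})
        mean_corr = metrics.mean_correlation(corr, excl)

    return RecordingReport(
        units=units, bursts_by_unit=bursts_by_unit, thresholds=thresholds,
        nbs=nbs, unit_table=unit_table,
        nb_count_per_10min=summary["count_per_10min"],
        nb_mean_duration=summary["mean_duration_s"],
        mfr=metrics.mean_firing_rate(units, rec.duration),
        mean_correlation=mean_corr, correlation=corr, excluded_pairs=excl)


def analyze_image(img: np.ndarray, um_per_px: float, layout,
                  config: RunConfig | None = None,
                  origin_um: tuple[float, float] = (0.0, 0.0)
                  ) -> imaging.ClusterMap:
    """Run the imaging chain on one stitched phase-contrast montage."""
    cfg = config or RunConfig()
    clean = imaging.inpaint_electrodes(img)
    hue = imaging.hue_map(clean, um_per_px, cfg.sigma_low_um,
                          cfg.sigma_high_um, cfg.red_over_blue)
    mask = imaging.segment_clusters(hue, k=cfg.segment_k_sd)
    scores = imaging.electrode_clusterness(
        hue, layout, origin_um=origin_um,
        window_um=cfg.clusterness_window_um,
        sigma_um=cfg.clusterness_window_um / 2.0)
    return imaging.ClusterMap(mask=mask,
                              cluster_ratio=imaging.cluster_ratio(mask),
                              per_electrode_scores=scores)


def _electrode_rows(report: RecordingReport, mea_id: str, date: str,
                    scores: dict[str, float] | None) -> pd.DataFrame:
    per_unit = report.unit_table
    if per_unit.empty:
        return pd.DataFrame()
    g = per_unit.groupby("electrode_id").agg(
        burstiness=("burstiness", "mean"), n_bursts=("n_bursts", "sum"))
    g = g.reset_index()
    g["mea_id"], g["date"] = mea_id, date
    g["clusterness"] = [scores.get(e, np.nan) if scores else np.nan
                        for e in g["electrode_id"]]
    return g


def run_pipeline(recording_paths: list[str | Path],
                 image_inputs: list[tuple[np.ndarray, float, str]] | None = None,
                 config: RunConfig | None = None,
                 out_dir: str | Path = "spheromea_out") -> Path:
    """Analyze a batch of MEAs and write CSV/JSON reports.

    ``image_inputs`` pairs each montage with its um/px scale and MEA id.
    Failures are isolated per MEA: a failing input is logged and
    skipped, the rest of the batch still completes.
    """
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    image_by_mea: dict[str, imaging.ClusterMap] = {}
    failures: list[str] = []
    for img, scale, mea_id in (image_inputs or []):
        try:
            from .model import standard_layout
            image_by_mea[mea_id] = analyze_image(img, scale, standard_layout(),
                                                 cfg)
        except Exception:
            logger.exception("image for %s failed", mea_id)
            failures.append(f"image:{mea_id}")

    electrode_rows, mea_rows = [], []
    for path in recording_paths:
        try:
            rec = read_recording(path)
            mea_id = rec.metadata.mea_id
            date = str(rec.metadata.div)
            report = analyze_recording(rec, cfg)
            units_to_csv(report.units, out / f"{mea_id}_units.csv")
            report.unit_table.to_csv(out / f"{mea_id}_unit_metrics.csv",
                                     index=False)
            pd.DataFrame(
                [(nb.start, nb.end, nb.n_spikes, len(nb.participating_units))
                 for nb in report.nbs],
                columns=["start_s", "end_s", "n_spikes", "n_units"],
            ).to_csv(out / f"{mea_id}_network_bursts.csv", index=False)

            cmap = image_by_mea.get(mea_id)
            scores = cmap.per_electrode_scores if cmap else None
            electrode_rows.append(_electrode_rows(report, mea_id, date, scores))
            mea_rows.append({
                "mea_id": mea_id, "date": date,
                "mfr": report.mfr,
                "nb_count_per_10min": report.nb_count_per_10min,
                "nb_duration": report.nb_mean_duration,
                "mean_correlation": report.mean_correlation,
                "cluster_ratio": cmap.cluster_ratio if cmap else np.nan,
            })
        except Exception:
            logger.exception("recording %s failed", path)
            failures.append(f"recording:{path}")

    edf = (pd.concat(electrode_rows, ignore_index=True)
           if electrode_rows else pd.DataFrame())
    mdf = pd.DataFrame(mea_rows)
    tables = stats.morphology_activity_table(
        edf, mdf, n_resamples=cfg.n_resamples, seed=cfg.subseed("bootstrap"))
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)

    manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                "n_recordings": len(recording_paths),
                "n_images": len(image_inputs or []),
                "failures": failures}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.json").write_text(cfg.to_json())
    if failures:
        logger.warning("%d inputs failed: %s", len(failures), failures)
    return out
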