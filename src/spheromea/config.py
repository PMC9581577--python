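"""Run configuration: every tunable of the pipeline in one place.

Defaults reproduce the analysis conditions the pipeline was designed
for (250-3000 Hz order-2 band-pass, +-5 SD detection, >10 spikes/min
activity criterion, burst floors 3 and N/3000 with the 0.1 s fallback,
NB threshold at top-decile-mean/3 with floors 10 and N/300, 320 Hz rate
vectors, 6000 bootstrap resamples, 1.4 SD image segmentation, 31 um
clusterness window) plus the package's own operational constants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # filtering / detection
    filter_low_hz: float = 250.0
    filter_high_hz: float = 3000.0
    filter_order: int = 2
    detect_k_sd: float = 5.0
    dead_time_s: float = 1e-3
    waveform_pre_s: float = 1e-3
    waveform_post_s: float = 2e-3
    # sorting
    sort_k_max: int = 6
    sort_n_restarts: int = 10
    # bursts
    bins_per_decade: int = 10
    isi_range_s: tuple[float, float] = (1e-3, 1e2)
    void_min: float = 0.7
    intra_peak_max_s: float = 0.1
    fallback_threshold_s: float = 0.1
    min_burst_spikes: int = 3
    burst_size_divisor: int = 3000
    # network bursts
    nb_dt_s: float = 1e-3
    min_nb_spikes: int = 10
    nb_size_divisor: int = 300
    # metrics
    active_spikes_per_min: float = 10.0
    rate_vector_fs: float = 320.0
    # statistics
    n_resamples: int = 6000
    # imaging
    segment_k_sd: float = 1.4
    sigma_low_um: float = 15.0
    sigma_high_um: float = 300.0
    red_over_blue: bool = True
    clusterness_window_um: float = 31.0
    # reproducibility
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["isi_range_s"] = list(d["isi_range_s"])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        if "isi_range_s" in d:
            d["isi_range_s"] = tuple(d["isi_range_s"])
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def subseed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)
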