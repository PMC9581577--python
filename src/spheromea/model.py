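"""Core data model for MEA recordings.

Conventions used throughout the package:

* voltages are microvolts (uV),
* times are seconds, float, zero-based from recording start,
* electrode ids are strings (two-digit column-row labels for the
  standard 60-site layout),
* spatial coordinates are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "CultureMetadata",
    "RawRecording",
    "Unit",
    "standard_layout",
    "seeding_density",
]


@dataclass
class ElectrodeLayout:
    """Planar electrode grid of an MEA.

    Parameters
    ----------
    electrode_ids
        Unique string labels, one per recording electrode.
    x, y
        Electrode centre positions in micrometres.
    radius_um
        Electrode disc radius (default 30 um for TiN 60MEA electrodes).
    pitch_um
        Centre-to-centre spacing of the grid (default 200 um).
    reference_id
        Optional id of the internal reference electrode.
    """

    electrode_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    radius_um: float = 30.0
    pitch_um: float = 200.0
    reference_id: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.electrode_ids) != len(set(self.electrode_ids)):
            raise ValueError("electrode ids must be unique")
        if not (len(self.electrode_ids) == self.x.size == self.y.size):
            raise ValueError("ids and positions must have equal length")
        pos = set(zip(self.x.tolist(), self.y.tolist()))
        if len(pos) != self.x.size:
            raise ValueError("electrode positions must be pairwise distinct")
        if self.radius_um <= 0 or self.pitch_um <= 0:
            raise ValueError("radius and pitch must be positive")

    def __len__(self) -> int:
        return len(self.electrode_ids)

    def position(self, electrode_id: str) -> tuple[float, float]:
        i = self.electrode_ids.index(electrode_id)
        return float(self.x[i]), float(self.y[i])


def standard_layout(radius_um: float = 30.0, pitch_um: float = 200.0) -> ElectrodeLayout:
    """The conventional 60-site MEA grid: 8x8 minus the four corners.

    Sites are labelled ``<column><row>`` (1-based).  Site ``15`` is the
    internal reference, leaving 59 recording electrodes.
    """
    ids, xs, ys = [], [], []
    for col in range(1, 9):
        for row in range(1, 9):
            if (col, row) in {(1, 1), (1, 8), (8, 1), (8, 8)}:
                continue
            label = f"{col}{row}"
            if label == "15":
                continue
            ids.append(label)
            xs.append((col - 1) * pitch_um)
            ys.append((row - 1) * pitch_um)
    return ElectrodeLayout(ids, np.array(xs), np.array(ys), radius_um, pitch_um,
                           reference_id="15")


@dataclass
class CultureMetadata:
    """Culture provenance for one MEA.

    ``astrocyte_ratio`` is the astrocyte fraction of seeded cells (the
    study conditions were 0.15 and 0.50, but any fraction in [0, 1] is
    allowed).  ``seeded_area_mm2`` is the area the initial cell droplet
    spreads over.
    """

    div: int = 0
    cell_density_condition: str = "high"
    astrocyte_ratio: float = 0.5
    mea_history: str = "new"
    n_neurons_seeded: int = 0
    n_astrocytes_seeded: int = 0
    seeded_area_mm2: float = 25.5
    mea_id: str = "mea"

    def __post_init__(self) -> None:
        if self.div < 0:
            raise ValueError("DIV must be >= 0")
        if not 0.0 <= self.astrocyte_ratio <= 1.0:
            raise ValueError("astrocyte_ratio must lie in [0, 1]")
        if self.cell_density_condition not in ("high", "low"):
            raise ValueError("cell_density_condition must be 'high' or 'low'")
        if self.mea_history not in ("new", "used"):
            raise ValueError("mea_history must be 'new' or 'used'")
        if self.seeded_area_mm2 <= 0:
            raise ValueError("seeded_area_mm2 must be positive")
        if self.n_neurons_seeded < 0 or self.n_astrocytes_seeded < 0:
            raise ValueError("cell counts must be >= 0")


def seeding_density(meta: CultureMetadata) -> int:
    """Initial cell density in cells/mm^2, rounded to the nearest integer.

    Computed from live-cell counts at seeding divided by the seeded area.
    """
    if meta.seeded_area_mm2 <= 0:
        raise ValueError("seeded area must be positive")
    dens = (meta.n_neurons_seeded + meta.n_astrocytes_seeded) / meta.seeded_area_mm2
    return int(round(dens))


@dataclass
class RawRecording:
    """Multichannel extracellular voltage recording.

    ``traces`` maps electrode id to a 1-D voltage series in uV; all
    traces share ``sample_rate`` and ``duration``.
    """

    traces: dict[str, np.ndarray]
    sample_rate: float = 32000.0
    duration: float = 600.0
    layout: ElectrodeLayout = field(default_factory=standard_layout)
    metadata: CultureMetadata = field(default_factory=CultureMetadata)

    def __post_init__(self) -> None:
        n_expected = int(round(self.duration * self.sample_rate))
        if n_expected <= 0:
            raise ValueError("recording must contain at least one sample")
        for eid, tr in self.traces.items():
            if eid not in self.layout.electrode_ids:
                raise ValueError(f"trace electrode {eid!r} not present in layout")
            if len(tr) != n_expected:
                raise ValueError(
                    f"trace {eid!r} has {len(tr)} samples, expected {n_expected}"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def electrode_ids(self) -> list[str]:
        return list(self.traces)


@dataclass
class Unit:
    """A sorted putative neuron on one electrode."""

    unit_id: str
    electrode_id: str
    spike_times: np.ndarray
    mean_waveform: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike_times must be strictly increasing")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike times must be non-negative")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)
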