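"""Readers and writers for the supported on-disk formats.

Recordings live in a self-describing HDF5 container with one analog
stream group and one dataset per channel::

    /recording            attrs: sample_rate_hz, duration_s
    /recording/analog/<electrode_id>   float32 uV, attrs: sample_rate_hz, unit
    /layout               datasets electrode_ids, x_um, y_um;
                          attrs radius_um, pitch_um, reference_id
    /metadata             attr json (CultureMetadata as JSON)

Culture metadata and layout may alternatively come from a JSON sidecar
(`<recording>.json`) when absent from the file.  Unit spike times are
exchanged as CSV with columns unit_id, electrode_id, spike_time_s.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import CultureMetadata, ElectrodeLayout, RawRecording, Unit

__all__ = [
    "FormatError",
    "read_recording",
    "write_recording",
    "units_to_csv",
    "units_from_csv",
    "layout_to_dict",
    "layout_from_dict",
    "metadata_to_dict",
    "metadata_from_dict",
]


class FormatError(ValueError):
    """A container file does not have the expected structure."""


def layout_to_dict(layout: ElectrodeLayout) -> dict:
    return {
        "electrode_ids": list(layout.electrode_ids),
        "x_um": layout.x.tolist(),
        "y_um": layout.y.tolist(),
        "radius_um": layout.radius_um,
        "pitch_um": layout.pitch_um,
        "reference_id": layout.reference_id,
    }


def layout_from_dict(d: dict) -> ElectrodeLayout:
    return ElectrodeLayout(
        electrode_ids=[str(e) for e in d["electrode_ids"]],
        x=np.asarray(d["x_um"], dtype=float),
        y=np.asarray(d["y_um"], dtype=float),
        radius_um=float(d.get("radius_um", 30.0)),
        pitch_um=float(d.get("pitch_um", 200.0)),
        reference_id=d.get("reference_id"),
    )


def metadata_to_dict(meta: CultureMetadata) -> dict:
    return dataclasses.asdict(meta)


def metadata_from_dict(d: dict) -> CultureMetadata:
    fields = {f.name for f in dataclasses.fields(CultureMetadata)}
    return CultureMetadata(**{k: v for k, v in d.items() if k in fields})


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording to the HDF5 container; lossless at float32."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("recording")
        g.attrs["sample_rate_hz"] = float(rec.sample_rate)
        g.attrs["duration_s"] = float(rec.duration)
        analog = g.create_group("analog")
        for eid, tr in rec.traces.items():
            d = analog.create_dataset(eid, data=np.asarray(tr, dtype=np.float32))
            d.attrs["sample_rate_hz"] = float(rec.sample_rate)
            d.attrs["unit"] = "uV"
        lay = f.create_group("layout")
        lay.create_dataset("electrode_ids",
                           data=np.array(rec.layout.electrode_ids, dtype="S"))
        lay.create_dataset("x_um", data=rec.layout.x)
        lay.create_dataset("y_um", data=rec.layout.y)
        lay.attrs["radius_um"] = rec.layout.radius_um
        lay.attrs["pitch_um"] = rec.layout.pitch_um
        if rec.layout.reference_id is not None:
            lay.attrs["reference_id"] = rec.layout.reference_id
        f.create_group("metadata").attrs["json"] = json.dumps(
            metadata_to_dict(rec.metadata))


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        If the analog stream group is missing or channels disagree on
        sample rate.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "recording" not in f or "analog" not in f["recording"]:
            raise FormatError(
                f"{path.name}: missing group '/recording/analog'")
        analog = f["recording"]["analog"]
        if len(analog) == 0:
            raise FormatError(f"{path.name}: analog stream contains no channels")
        rates = {float(analog[k].attrs.get(
            "sample_rate_hz", f["recording"].attrs.get("sample_rate_hz", 0.0)))
            for k in analog}
        if len(rates) != 1:
            raise FormatError(
                f"{path.name}: channels disagree on sample rate: {sorted(rates)}")
        sample_rate = rates.pop()
        duration = float(f["recording"].attrs["duration_s"])
        traces = {str(k): np.asarray(analog[k][...], dtype=np.float32)
                  for k in analog}

        layout = None
        if "layout" in f:
            lay = f["layout"]
            layout = ElectrodeLayout(
                electrode_ids=[e.decode() for e in lay["electrode_ids"][...]],
                x=lay["x_um"][...],
                y=lay["y_um"][...],
                radius_um=float(lay.attrs.get("radius_um", 30.0)),
                pitch_um=float(lay.attrs.get("pitch_um", 200.0)),
                reference_id=(str(lay.attrs["reference_id"])
                              if "reference_id" in lay.attrs else None),
            )
        meta = None
        if "metadata" in f and "json" in f["metadata"].attrs:
            meta = metadata_from_dict(json.loads(f["metadata"].attrs["json"]))

    # sidecar config fills in whatever the container lacks
    sidecar = path.with_suffix(path.suffix + ".json")
    if (layout is None or meta is None) and sidecar.exists():
        side = json.loads(sidecar.read_text())
        if layout is None and "layout" in side:
            layout = layout_from_dict(side["layout"])
        if meta is None and "metadata" in side:
            meta = metadata_from_dict(side["metadata"])
    if layout is None:
        from .model import standard_layout
        layout = standard_layout()
    if meta is None:
        meta = CultureMetadata()
    return RawRecording(traces=traces, sample_rate=sample_rate,
                        duration=duration, layout=layout, metadata=meta)


def units_to_csv(units: list[Unit], path: str | Path) -> None:
    rows = [(u.unit_id, u.electrode_id, t)
            for u in units for t in u.spike_times]
    pd.DataFrame(rows, columns=["unit_id", "electrode_id", "spike_time_s"]).to_csv(
        path, index=False)


def units_from_csv(path: str | Path) -> list[Unit]:
    df = pd.read_csv(path, dtype={"unit_id": str, "electrode_id": str})
    units = []
    for (uid, eid), grp in df.groupby(["unit_id", "electrode_id"], sort=True):
        units.append(Unit(unit_id=uid, electrode_id=eid,
                          spike_times=np.sort(grp["spike_time_s"].to_numpy())))
    return units
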