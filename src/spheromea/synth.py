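"""Ground-truthed synthetic recordings and images.

The generator emulates the statistical structure the pipeline assumes:

* recordings -- units firing as inhomogeneous Poisson processes with a
  2 ms refractory period, piecewise-constant rates (low asynchronous
  baseline, elevated rate inside per-unit burst epochs and array-wide
  network-burst epochs), each spike rendering a biphasic template over
  Gaussian background noise;
* images -- a pale textured background, red-shifted soft-edged discs
  for cell clusters, optional darker strands between clusters, and
  near-black electrode discs on the grid.

Everything is deterministic under a fixed seed, and ground truth (spike
times, burst epochs, NB epochs, cluster masks) is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CultureMetadata, ElectrodeLayout, RawRecording, standard_layout

__all__ = [
    "UnitPlan",
    "RecordingScenario",
    "RecordingGroundTruth",
    "generate_recording",
    "spike_template",
    "ImageScenario",
    "generate_image",
    "reference_recording_scenario",
    "reference_image_scenario",
]

#: absolute refractory period of generated spike trains (s)
REFRACTORY_S = 2e-3


@dataclass
class UnitPlan:
    """Firing plan of one synthetic unit.

    The unit fires at ``baseline_rate_hz`` outside bursts, at
    ``burst_rate_hz`` inside its own ``burst_epochs`` and, when
    ``follows_nb``, inside the scenario's network-burst epochs.
    ``amplitude_uv`` is the (signed-peak) template amplitude;
    ``polarity`` flips the dominant phase so two units on one electrode
    separate in PCA space.
    """

    electrode_id: str
    amplitude_uv: float = 20.0
    baseline_rate_hz: float = 0.5
    burst_rate_hz: float = 100.0
    burst_epochs: list[tuple[float, float]] = field(default_factory=list)
    follows_nb: bool = True
    polarity: int = -1


@dataclass
class RecordingScenario:
    units: list[UnitPlan]
    nb_epochs: list[tuple[float, float]] = field(default_factory=list)
    noise_sd_uv: float = 3.0
    duration: float = 600.0
    sample_rate: float = 32000.0
    seed: int = 0
    amplitude_jitter: float = 0.10

    def __post_init__(self) -> None:
        for plan in self.units:
            for t0, t1 in plan.burst_epochs:
                if not 0 <= t0 < t1 <= self.duration:
                    raise ValueError("burst epochs must lie within the recording")
            if plan.baseline_rate_hz < 0 or plan.burst_rate_hz < 0:
                raise ValueError("rates must be >= 0")
        for t0, t1 in self.nb_epochs:
            if not 0 <= t0 < t1 <= self.duration:
                raise ValueError("NB epochs must lie within the recording")


@dataclass
class RecordingGroundTruth:
    spike_times: dict[str, np.ndarray]          # unit id -> times (s)
    unit_electrode: dict[str, str]
    burst_epochs: dict[str, list[tuple[float, float]]]
    nb_epochs: list[tuple[float, float]]


def spike_template(sample_rate: float, span_s: float = 1.5e-3,
                   polarity: int = -1) -> np.ndarray:
    """Biphasic extracellular spike template, unit peak amplitude.

    Difference of two Gaussians: a sharp dominant phase followed by a
    slower rebound of opposite sign.
    """
    n = int(round(span_s * sample_rate))
    t = np.arange(n) / sample_rate
    sharp = np.exp(-((t - 0.35e-3) ** 2) / (2 * (0.1e-3) ** 2))
    slow = 0.45 * np.exp(-((t - 0.75e-3) ** 2) / (2 * (0.25e-3) ** 2))
    w = sharp - slow
    w = w / np.abs(w).max()
    return polarity * w


def _epochs_of(plan: UnitPlan, scn: RecordingScenario
               ) -> list[tuple[float, float]]:
    eps = list(plan.burst_epochs)
    if plan.follows_nb:
        eps += list(scn.nb_epochs)
    return sorted(eps)


def _piecewise_rate(plan: UnitPlan, scn: RecordingScenario
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Segment boundaries and the rate on each segment."""
    cuts = {0.0, scn.duration}
    for t0, t1 in _epochs_of(plan, scn):
        cuts.update((t0, t1))
    bounds = np.array(sorted(cuts))
    rates = np.empty(bounds.size - 1)
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        mid = (a + b) / 2
        in_burst = any(t0 <= mid < t1 for t0, t1 in _epochs_of(plan, scn))
        rates[i] = plan.burst_rate_hz if in_burst else plan.baseline_rate_hz
    return bounds, rates


def _draw_spike_train(plan: UnitPlan, scn: RecordingScenario,
                      rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson with piecewise-constant rate and refractory."""
    bounds, rates = _piecewise_rate(plan, scn)
    times: list[float] = []
    t, seg = 0.0, 0
    while t < scn.duration:
        while seg < rates.size - 1 and t >= bounds[seg + 1]:
            seg += 1
        r = rates[seg]
        if r <= 0:
            t = bounds[seg + 1] if seg < rates.size - 1 else scn.duration
            continue
        gap = max(rng.exponential(1.0 / r), REFRACTORY_S)
        if t + gap >= bounds[seg + 1]:
            # re-draw in the next segment; valid by memorylessness
            t = bounds[seg + 1] if seg < rates.size - 1 else scn.duration
            continue
        t += gap
        times.append(t)
    return np.asarray(times)


def generate_recording(scn: RecordingScenario
                       ) -> tuple[RawRecording, RecordingGroundTruth]:
    """Render the scenario to voltage traces plus ground truth.

    Spike amplitudes jitter by ``amplitude_jitter`` (relative SD) to
    exercise sorting; amplitudes should be chosen >= 6x the noise SD so
    detection at 5 SD recovers them.
    """
    rng = np.random.default_rng(scn.seed)
    n = int(round(scn.duration * scn.sample_rate))

    electrode_ids = sorted({p.electrode_id for p in scn.units})
    layout = standard_layout()
    for eid in electrode_ids:
        if eid not in layout.electrode_ids:
            raise ValueError(f"unknown electrode id {eid!r}")
    traces = {eid: rng.normal(0.0, scn.noise_sd_uv, n).astype(np.float32)
              for eid in electrode_ids}

    gt_spikes: dict[str, np.ndarray] = {}
    gt_electrode: dict[str, str] = {}
    gt_bursts: dict[str, list[tuple[float, float]]] = {}
    counters: dict[str, int] = {}
    for plan in scn.units:
        k = counters.get(plan.electrode_id, 0) + 1
        counters[plan.electrode_id] = k
        uid = f"{plan.electrode_id}u{k}"
        spikes = _draw_spike_train(plan, scn, rng)
        template = spike_template(scn.sample_rate, polarity=plan.polarity)
        if template.size > n:
            raise ValueError("template longer than the recording")
        tr = traces[plan.electrode_id]
        for t_sp in spikes:
            i0 = int(round(t_sp * scn.sample_rate))
            if i0 + template.size > n:
                continue
            amp = plan.amplitude_uv * (1 + scn.amplitude_jitter * rng.normal())
            tr[i0:i0 + template.size] += (amp * template).astype(np.float32)
        gt_spikes[uid] = spikes
        gt_electrode[uid] = plan.electrode_id
        gt_bursts[uid] = _epochs_of(plan, scn)

    meta = CultureMetadata(mea_id="synthetic")
    rec = RawRecording(traces=traces, sample_rate=scn.sample_rate,
                       duration=scn.duration, layout=layout, metadata=meta)
    truth = RecordingGroundTruth(spike_times=gt_spikes,
                                 unit_electrode=gt_electrode,
                                 burst_epochs=gt_bursts,
                                 nb_epochs=list(scn.nb_epochs))
    return rec, truth


def reference_recording_scenario(seed: int = 0) -> RecordingScenario:
    """The canonical end-to-end validation scenario.

    Five units on four electrodes (two share electrode 12 with opposite
    template polarity, exercising sorting and same-electrode pair
    exclusion), a 10-minute recording at 32 kHz, 3 uV background noise,
    24 uV spikes (8x noise SD), 0.5 Hz asynchronous baseline firing and
    eight array-wide 1.2 s network-burst epochs at 80 Hz in-burst rate.
    """
    nb_epochs = [(40.0 + 70.0 * i, 41.2 + 70.0 * i) for i in range(8)]
    plans = [
        UnitPlan("12", amplitude_uv=24.0, baseline_rate_hz=0.5,
                 burst_rate_hz=80.0, polarity=-1),
        UnitPlan("12", amplitude_uv=24.0, baseline_rate_hz=0.5,
                 burst_rate_hz=80.0, polarity=+1),
        UnitPlan("13", amplitude_uv=24.0, baseline_rate_hz=0.5,
                 burst_rate_hz=80.0, polarity=-1),
        UnitPlan("14", amplitude_uv=24.0, baseline_rate_hz=0.5,
                 burst_rate_hz=80.0, polarity=-1),
        UnitPlan("21", amplitude_uv=24.0, baseline_rate_hz=0.5,
                 burst_rate_hz=80.0, polarity=-1),
    ]
    return RecordingScenario(units=plans, nb_epochs=nb_epochs,
                             noise_sd_uv=3.0, duration=600.0,
                             sample_rate=32000.0, seed=seed)


def reference_image_scenario(seed: int = 0) -> "ImageScenario":
    """Canonical imaging validation scene: three clusters of 80-100 um
    radius on a 1.8 x 1.8 mm canvas covering the electrode grid."""
    return ImageScenario(
        shape=(720, 720), um_per_px=2.5,
        layout=standard_layout(), origin_um=(-200.0, -200.0),
        clusters=[(250.0, 250.0, 90.0), (800.0, 1000.0, 100.0),
                  (1200.0, 400.0, 80.0)],
        seed=seed)


@dataclass
class ImageScenario:
    """Scene description for a synthetic phase-contrast montage."""

    shape: tuple[int, int] = (800, 800)       # (rows, cols) px
    um_per_px: float = 2.5
    layout: ElectrodeLayout | None = None
    origin_um: tuple[float, float] = (0.0, 0.0)
    clusters: list[tuple[float, float, float]] = field(default_factory=list)
    # (x_um, y_um, radius_um); contrast below applies to all
    red_shift: float = 0.18
    background_rgb: tuple[float, float, float] = (0.62, 0.60, 0.58)
    texture_sd: float = 0.015
    edge_softness_um: float = 5.0
    draw_electrodes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        for cx, cy, r in self.clusters:
            if not (0 <= cx <= w * self.um_per_px and 0 <= cy <= h * self.um_per_px):
                raise ValueError("cluster centre outside the canvas")
            if r <= 0:
                raise ValueError("cluster radius must be positive")
        if self.red_shift <= 0:
            raise ValueError("contrast must be positive")


def generate_image(scn: ImageScenario) -> tuple[np.ndarray, np.ndarray]:
    """Render the scene; returns ``(rgb float image, true cluster mask)``.

    Clusters raise the red channel and lower the blue channel by the
    red-shift contrast with a soft (logistic) edge; electrodes are drawn
    as grayscale-0 discs.  The true mask marks pixels within any cluster
    radius.
    """
    rng = np.random.default_rng(scn.seed)
    h, w = scn.shape
    yy, xx = np.mgrid[0:h, 0:w]
    x_um = xx * scn.um_per_px + scn.origin_um[0]
    y_um = yy * scn.um_per_px + scn.origin_um[1]

    img = np.empty((h, w, 3))
    for c, bg in enumerate(scn.background_rgb):
        img[:, :, c] = bg + rng.normal(0.0, scn.texture_sd, (h, w))

    true_mask = np.zeros((h, w), dtype=bool)
    soft = max(scn.edge_softness_um, 1e-6)
    for cx, cy, r in scn.clusters:
        d = np.hypot(x_um - cx, y_um - cy)
        profile = 1.0 / (1.0 + np.exp((d - r) / soft))
        img[:, :, 0] += scn.red_shift * profile        # redder
        img[:, :, 2] -= scn.red_shift * profile        # less blue
        img[:, :, 1] -= 0.3 * scn.red_shift * profile  # slightly darker overall
        true_mask |= d <= r

    if scn.draw_electrodes and scn.layout is not None:
        rad = scn.layout.radius_um
        for ex, ey in zip(scn.layout.x, scn.layout.y):
            d = np.hypot(x_um - ex, y_um - ey)
            img[d <= rad] = 0.0
    return np.clip(img, 0.0, 1.0), true_mask
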