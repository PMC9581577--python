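import numpy as np
import pytest

from spheromea.model import Unit
from spheromea.synth import RecordingScenario, UnitPlan, generate_recording


def bursty_train(n_bursts: int, spikes_per_burst: int, in_isi: float,
                 gap: float, rng: np.random.Generator | None = None,
                 jitter: float = 0.0) -> np.ndarray:
    """Deterministic (optionally jittered) bursty spike train."""
    times, t = [], 0.0
    for _ in range(n_bursts):
        t += gap
        for _ in range(spikes_per_burst):
            times.append(t)
            step = in_isi
            if rng is not None and jitter > 0:
                step *= rng.uniform(1 - jitter, 1 + jitter)
            t += step
    return np.array(times)


@pytest.fixture
def unit_factory():
    def make(spike_times, unit_id="u1", electrode_id="12"):
        return Unit(unit_id=unit_id, electrode_id=electrode_id,
                    spike_times=np.asarray(spike_times, dtype=float))
    return make


@pytest.fixture(scope="session")
def small_recording():
    """3-electrode, 40 s recording with 4 programmed NB epochs."""
    nb = [(8.0, 9.0), (18.0, 19.2), (28.0, 29.0), (36.0, 37.0)]
    plans = [UnitPlan(electrode_id=e, amplitude_uv=24.0, baseline_rate_hz=0.6,
                      burst_rate_hz=80.0) for e in ("12", "13", "14")]
    scn = RecordingScenario(units=plans, nb_epochs=nb, duration=40.0,
                            noise_sd_uv=3.0, seed=7)
    rec, truth = generate_recording(scn)
    return rec, truth, scn
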