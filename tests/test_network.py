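import numpy as np
import pytest

from oracles import top_decile_third
from spheromea.bursts import Burst
from spheromea.model import RawRecording, Unit, standard_layout
from spheromea.network import (BurstCountSeries, activity_map,
                               burst_count_series, detect_network_bursts,
                               nb_summary, nb_threshold, network_burstiness)


def _burst(uid, start, end, n=10):
    return Burst(unit_id=uid, start=start, end=end, n_spikes=n,
                 spike_indices=np.arange(n))


class TestBurstCountSeries:
    def test_no_bursts_all_zero(self):
        s = burst_count_series({}, duration=10.0)
        assert s.counts.size == 10_000
        assert not s.counts.any()

    def test_single_interval_indicator(self):
        s = burst_count_series({"u1": [_burst("u1", 1.0, 2.0)]}, duration=5.0)
        t = s.times()
        inside = (t >= 1.0) & (t <= 2.0)
        assert np.all(s.counts[inside] == 1)
        assert np.all(s.counts[~inside] == 0)

    def test_overlap_counts_two(self):
        s = burst_count_series(
            {"u1": [_burst("u1", 1.0, 2.0)], "u2": [_burst("u2", 1.5, 2.5)]},
            duration=5.0)
        t = s.times()
        assert np.all(s.counts[(t >= 1.5) & (t <= 2.0)] == 2)
        assert np.all(s.counts[(t >= 1.0) & (t < 1.5)] == 1)
        assert np.all(s.counts[(t > 2.0) & (t <= 2.5)] == 1)


class TestNBThreshold:
    def test_constant_series(self):
        s = BurstCountSeries(counts=np.full(1000, 6), dt=1e-3)
        assert nb_threshold(s) == pytest.approx(2.0)

    def test_1_to_100_example(self):
        s = BurstCountSeries(counts=np.arange(1, 101), dt=1e-3)
        assert nb_threshold(s) == pytest.approx(95.5 / 3.0)

    def test_all_zero_series(self):
        s = BurstCountSeries(counts=np.zeros(100), dt=1e-3)
        assert nb_threshold(s) == 0.0

    def test_matches_sort_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = rng.integers(0, 12, size=rng.integers(10, 500))
            s = BurstCountSeries(counts=c, dt=1e-3)
            assert nb_threshold(s) == pytest.approx(
                top_decile_third(c.tolist()), rel=1e-12)


def _units_bursting_together(n_units=5, epoch=(1.0, 2.0), n_inside=12,
                             duration=10.0):
    """Units whose spikes sit inside one synchronous burst epoch."""
    units, bursts = [], {}
    t0, t1 = epoch
    for i in range(n_units):
        times = np.linspace(t0, t1, n_inside)
        u = Unit(f"u{i}", f"1{2+i}", times)
        units.append(u)
        bursts[u.unit_id] = [_burst(u.unit_id, times[0], times[-1], n_inside)]
    return units, bursts


class TestDetectNetworkBursts:
    def test_synchronous_epoch_detected(self):
        units, bursts = _units_bursting_together()
        s = burst_count_series(bursts, duration=10.0)
        nbs = detect_network_bursts(s, 1.5, units, bursts)
        assert len(nbs) == 1
        assert nbs[0].start == pytest.approx(1.0, abs=2e-3)
        assert nbs[0].end == pytest.approx(2.0, abs=2e-3)
        assert nbs[0].n_spikes == 60
        assert len(nbs[0].participating_units) == 5

    def test_small_candidate_rejected(self):
        units, bursts = _units_bursting_together(n_units=2, n_inside=4)
        s = burst_count_series(bursts, duration=10.0)
        nbs = detect_network_bursts(s, 1.5, units, bursts)
        assert nbs == []  # 8 spikes < 10-spike floor

    def test_size_divisor_floor(self):
        # 6000 bursting spikes on the array -> per-NB floor of 20
        units, bursts = _units_bursting_together(n_units=3, n_inside=5)
        big = Unit("big", "21", np.linspace(5.0, 9.0, 5985))
        units.append(big)
        bursts["big"] = [_burst("big", 5.0, 9.0, 5985)]
        s = burst_count_series(bursts, duration=10.0)
        nbs = detect_network_bursts(s, 0.5, units, bursts)
        # the 15-spike synchronous candidate fails the n/300 floor
        assert all(not (nb.start < 3.0) for nb in nbs)

    def test_raising_threshold_shrinks_nb_support(self):
        # the supra-threshold time support is nested across thresholds,
        # so every NB at a higher threshold lies inside one at a lower
        rng = np.random.default_rng(1)
        bursts = {}
        units = []
        for i in range(6):
            t = np.unique(np.round(np.sort(rng.uniform(0, 10, 200)), 4))
            u = Unit(f"u{i}", f"1{2+i}", t)
            units.append(u)
            bursts[u.unit_id] = [
                _burst(u.unit_id, a, a + rng.uniform(0.2, 1.0))
                for a in rng.uniform(0, 9, 5)]
        s = burst_count_series(bursts, duration=10.0)
        prev = None
        for thr in (1.0, 2.0, 3.0):
            nbs = detect_network_bursts(s, thr, units, bursts,
                                        min_spikes=1, size_divisor=10**9)
            spans = [(nb.start, nb.end) for nb in nbs]
            if prev is not None:
                for a, b in spans:
                    assert any(pa <= a and b <= pb for pa, pb in prev)
            prev = spans

    def test_zero_threshold_does_not_label_silence(self):
        units, bursts = _units_bursting_together()
        s = burst_count_series(bursts, duration=10.0)
        nbs = detect_network_bursts(s, 0.0, units, bursts)
        assert len(nbs) == 1  # only the epoch, not the whole recording


class TestNetworkBurstiness:
    def test_no_nbs_zero(self, unit_factory):
        u = unit_factory([1.0, 2.0, 3.0])
        assert network_burstiness(u, []) == 0.0

    def test_all_inside_one(self, unit_factory):
        from spheromea.network import NetworkBurst
        u = unit_factory([1.0, 1.5, 2.0])
        nb = NetworkBurst(start=0.5, end=2.5, n_spikes=3,
                          participating_units=["u1"])
        assert network_burstiness(u, [nb]) == 1.0

    def test_partial_fraction(self, unit_factory):
        from spheromea.network import NetworkBurst
        t = np.arange(50) * 0.1
        u = unit_factory(t)
        nb = NetworkBurst(start=0.0, end=t[19] + 1e-9, n_spikes=20,
                          participating_units=["u1"])
        assert network_burstiness(u, [nb]) == pytest.approx(0.4)


class TestNBSummary:
    def test_count_scaling(self):
        from spheromea.network import NetworkBurst
        nbs = [NetworkBurst(i, i + 0.5, 20, []) for i in range(6)]
        out = nb_summary(nbs, duration=300.0)
        assert out["count_per_10min"] == pytest.approx(12.0)

    def test_mean_duration(self):
        from spheromea.network import NetworkBurst
        nbs = [NetworkBurst(0.0, 1.0, 20, []), NetworkBurst(5.0, 8.0, 20, [])]
        out = nb_summary(nbs, duration=600.0)
        assert out["mean_duration_s"] == pytest.approx(2.0)

    def test_empty_list(self):
        out = nb_summary([], duration=600.0)
        assert out["count_per_10min"] == 0.0
        assert out["mean_duration_s"] is None


class TestActivityMap:
    def _recording(self, traces, fs=1000.0):
        lay = standard_layout()
        dur = len(next(iter(traces.values()))) / fs
        return RawRecording(traces=traces, sample_rate=fs, duration=dur,
                            layout=lay)

    def test_zero_signal_zero_map(self):
        rec = self._recording({"12": np.zeros(1000, dtype=np.float32)})
        amap = activity_map(rec, (0.0, 1.0))
        assert amap["12"] == 0.0

    def test_sine_mean_rectified(self):
        fs = 1000.0
        t = np.arange(10_000) / fs
        x = (5.0 * np.sin(2 * np.pi * 50 * t)).astype(np.float32)
        rec = self._recording({"12": x}, fs)
        amap = activity_map(rec, (0.0, 10.0))
        assert amap["12"] == pytest.approx(2 / np.pi * 5.0, rel=0.01)

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3, 1000).astype(np.float32)
        a1 = activity_map(self._recording({"12": x}), (0.0, 1.0))
        a2 = activity_map(self._recording({"12": -x}), (0.0, 1.0))
        assert a1["12"] == pytest.approx(a2["12"])

    def test_empty_window_rejected(self):
        rec = self._recording({"12": np.zeros(1000, dtype=np.float32)})
        with pytest.raises(ValueError):
            activity_map(rec, (0.5, 0.5))
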