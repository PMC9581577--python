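"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results by the most literal route
possible (run scanning, sorting, direct summation, closed forms) and
share no code with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np


def butterworth_gain(freq: float, low: float, high: float, order: int) -> float:
    """Analytic squared-magnitude response of a zero-phase Butterworth
    band-pass (forward-backward doubles the magnitude response)."""
    w, w1, w2 = 2 * math.pi * freq, 2 * math.pi * low, 2 * math.pi * high
    # |H|^2 of the band-pass prototype evaluated at w
    bw, w0sq = w2 - w1, w1 * w2
    x = (w**2 - w0sq) / (bw * w)
    mag2 = 1.0 / (1.0 + x ** (2 * order))
    return mag2  # filtfilt applies |H|^2


def scan_bursts(spike_times, threshold: float, flag: str
                ) -> list[tuple[int, int]]:
    """Literal run-scanner applying the three burst rules.

    Rules: maximal runs of consecutive ISIs <= threshold; drop runs of
    fewer than max(3, ceil(N/3000)) spikes; when the threshold exceeds
    0.1 s keep only runs that fully enclose a surviving 0.1 s run.
    Returns (first index, last index) pairs.
    """
    t = list(spike_times)
    n = len(t)
    floor = max(3, math.ceil(n / 3000))

    def runs(thr):
        out, start = [], 0
        for i in range(1, n):
            if t[i] - t[i - 1] > thr:
                out.append((start, i - 1))
                start = i
        if n:
            out.append((start, n - 1))
        return [(a, b) for a, b in out if b - a + 1 >= floor]

    cand = runs(threshold)
    if flag == "enclosure-required":
        inner = runs(0.1)
        cand = [(a, b) for a, b in cand
                if any(a <= ia and ib <= b for ia, ib in inner)]
    return cand


def top_decile_third(values) -> float:
    """Sort-based mean of the top decile divided by three."""
    v = sorted(values)
    n = len(v)
    # linear-interpolation 90th percentile, as numpy defines it
    pos = 0.9 * (n - 1)
    lo = int(math.floor(pos))
    frac = pos - lo
    q90 = v[lo] if lo + 1 >= n else v[lo] + frac * (v[lo + 1] - v[lo])
    top = [x for x in v if x >= q90]
    return sum(top) / len(top) / 3.0


def entropy_direct(p) -> float:
    """Direct-summation Shannon entropy in nats."""
    return float(-sum(pi * math.log(pi) for pi in p if pi > 0))


def poisson_train(rate: float, duration: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson spike train (no refractory)."""
    t, out = 0.0, []
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            return np.array(out)
        out.append(t)
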