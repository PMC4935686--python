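"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorized code paths of the package: the STTC
oracle builds tiling sets by explicit interval merging and per-spike
membership loops; the burst oracle splits trains with a different primitive
than the detector's run scan.
"""

from __future__ import annotations

import numpy as np


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def sttc_bruteforce(a, b, dt, span):
    """STTC by explicit interval union and membership tests."""
    t0, t1 = span
    a = [t for t in a if t0 <= t < t1]
    b = [t for t in b if t0 <= t < t1]
    if not a or not b:
        return float("nan")

    def tiling(ts):
        return _merge_intervals([(max(t - dt, t0), min(t + dt, t1)) for t in ts])

    def coverage(intervals):
        return sum(e - s for s, e in intervals) / (t1 - t0)

    def proportion(ts, other):
        hits = 0
        for t in ts:
            if any(abs(t - u) <= dt for u in other):
                hits += 1
        return hits / len(ts)

    ta, tb = coverage(tiling(a)), coverage(tiling(b))
    pa, pb = proportion(a, b), proportion(b, a)
    total = 0.0
    for p, t in ((pa, tb), (pb, ta)):
        denom = 1.0 - p * t
        if abs(denom) >= 1e-12:
            total += (p - t) / denom
    return 0.5 * total


def tiling_coverage_grid(ts, dt, span, n_grid=200_000):
    """Monte-Carlo-free grid estimate of the tiling coverage fraction."""
    t0, t1 = span
    grid = t0 + (np.arange(n_grid) + 0.5) * (t1 - t0) / n_grid
    covered = np.zeros(n_grid, dtype=bool)
    for t in ts:
        covered |= np.abs(grid - t) <= dt
    return covered.mean()


def bursts_bruteforce(ts, max_isi_s, min_spikes):
    """Burst intervals via np.split at large ISIs (independent primitive)."""
    ts = np.asarray(ts, dtype=float)
    if ts.size == 0:
        return []
    gaps = np.flatnonzero(np.diff(ts) > max_isi_s) + 1
    return [
        (run[0], run[-1], run.size)
        for run in np.split(ts, gaps)
        if run.size >= min_spikes
    ]
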