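"""Functional connectivity via the spike time tiling coefficient (STTC).

The STTC (Cutts & Eglen) quantifies pairwise spike-train correlation in a
firing-rate-insensitive way. For trains A and B over a span:

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ]

where ``T_X`` is the fraction of the span covered by the union of +/-dt
windows around X's spikes (clipped to the span) and ``P_X`` is the fraction
of X's spikes falling within +/-dt of any spike of the other train. The
coefficient lies in [-1, 1] and equals 1 for identical non-empty trains.

Network tracking proceeds hourly: compute the STTC matrix over active
channels (MFR > 0.01 spike/s) per window, keep the 100 edges with the
largest basal coefficients, and follow their decrease (drop > 20% of the
basal reference, a cutoff the basal mean + 3 SD criterion reproduces) and
deletion (edge undefined because an endpoint fell inactive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SpikeTrainSet, ValidationError

__all__ = [
    "SttcParams",
    "EdgeSet",
    "sttc",
    "sttc_matrix",
    "select_top_edges",
    "attach_window",
    "basal_variation_threshold",
    "edge_decreases",
    "deleted_edges",
    "export_connectivity_map",
]


@dataclass(frozen=True)
class SttcParams:
    """STTC and edge-tracking configuration.

    ``dt_s`` is the tiling half-window; it is not standardized and must be
    chosen deliberately — the default 0.05 s is of the order of in-burst
    co-activation and is recorded in every output.
    """

    dt_s: float = 0.05
    active_mfr_min: float = 0.01
    window_len_s: float = 3600.0
    top_n: int = 100
    decrease_threshold_pct: float = 20.0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValidationError("dt_s must be positive")
        if not 0 < self.decrease_threshold_pct < 100:
            raise ValidationError("decrease_threshold_pct must be in (0, 100)")


def _tiling_fraction(ts: np.ndarray, dt: float, t0: float, t1: float) -> float:
    """Fraction of [t0, t1) covered by the union of [t-dt, t+dt] windows."""
    starts = np.clip(ts - dt, t0, t1)
    ends = np.clip(ts + dt, t0, t1)
    prev_max_end = np.r_[-np.inf, np.maximum.accumulate(ends)[:-1]]
    covered = np.maximum(0.0, ends - np.maximum(starts, prev_max_end)).sum()
    return float(covered) / (t1 - t0)


def _proportion_within(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Fraction of spikes in `a` within +/-dt of some spike in `b`."""
    idx = np.searchsorted(b, a)
    left = np.where(idx > 0, a - b[np.maximum(idx - 1, 0)], np.inf)
    right = np.where(idx < b.size, b[np.minimum(idx, b.size - 1)] - a, np.inf)
    return float((np.minimum(left, right) <= dt).mean())


def sttc(
    train_a: np.ndarray,
    train_b: np.ndarray,
    dt_s: float,
    span: tuple[float, float],
) -> float:
    """Spike time tiling coefficient of two sorted trains over ``span``.

    Returns NaN (undefined) if either train is empty within the span; a
    degenerate term denominator (``P·T == 1`` for non-identical statistics)
    contributes 0.
    """
    t0, t1 = span
    if t1 <= t0:
        raise ValidationError("span must have positive length")
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    a = a[(a >= t0) & (a < t1)]
    b = b[(b >= t0) & (b < t1)]
    if a.size == 0 or b.size == 0:
        return float("nan")
    ta = _tiling_fraction(a, dt_s, t0, t1)
    tb = _tiling_fraction(b, dt_s, t0, t1)
    pa = _proportion_within(a, b, dt_s)
    pb = _proportion_within(b, a, dt_s)
    terms = []
    for p, t in ((pa, tb), (pb, ta)):
        denom = 1.0 - p * t
        terms.append(0.0 if abs(denom) < 1e-12 else (p - t) / denom)
    return 0.5 * (terms[0] + terms[1])


def sttc_matrix(
    spikes: SpikeTrainSet,
    params: SttcParams,
    window: tuple[float, float],
) -> pd.DataFrame:
    """Symmetric STTC matrix over channels active in ``window``.

    A channel is active when its MFR strictly exceeds
    ``params.active_mfr_min``; entries involving inactive channels are NaN
    (missing). Diagonal entries are left NaN as well (self-pairs carry no
    information here).
    """
    start, end = window
    channels = spikes.channels
    mat = pd.DataFrame(np.nan, index=channels, columns=channels, dtype=float)
    trains = {
        ch: ts[(ts >= start) & (ts < end)] for ch, ts in spikes.trains.items()
    }
    active = [
        ch for ch in channels if trains[ch].size / (end - start) > params.active_mfr_min
    ]
    if len(active) < 2:
        warnings.warn("fewer than 2 active channels in window", stacklevel=2)
        return mat
    for i, ch_a in enumerate(active):
        for ch_b in active[i + 1 :]:
            v = sttc(trains[ch_a], trains[ch_b], params.dt_s, (start, end))
            mat.loc[ch_a, ch_b] = v
            mat.loc[ch_b, ch_a] = v
    return mat


@dataclass
class EdgeSet:
    """Selected electrode pairs and their per-window STTC time courses.

    ``basal_reference`` maps each unordered pair (stored once, lexicographic
    order) to its basal STTC; ``values`` holds one column per window index,
    NaN marking a missing (undefined) coefficient.
    """

    basal_reference: pd.Series
    values: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for a, b in self.basal_reference.index:
            if a == b:
                raise ValidationError("self-pairs are not edges")
            if not a < b:
                raise ValidationError("edges must be stored with electrode_a < electrode_b")
        if self.values.empty:
            self.values = pd.DataFrame(index=self.basal_reference.index)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.basal_reference.index)

    def to_frame(self) -> pd.DataFrame:
        """Long format: electrode_a, electrode_b, window_index, sttc."""
        rows = []
        for (a, b), row in self.values.iterrows():
            for wi, v in row.items():
                rows.append((a, b, wi, v))
        return pd.DataFrame(rows, columns=["electrode_a", "electrode_b", "window_index", "sttc"])


def _matrix_edges(mat: pd.DataFrame) -> pd.Series:
    """Defined unordered pairs of a symmetric STTC matrix as a Series."""
    out = {}
    cols = list(mat.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            v = mat.loc[a, b]
            if np.isfinite(v):
                out[(a, b) if a < b else (b, a)] = float(v)
    return pd.Series(out, dtype=float)


def select_top_edges(
    basal_matrices: list[pd.DataFrame], top_n: int, agg: str = "mean"
) -> EdgeSet:
    """Edges with the largest basal STTC (reference = mean over basal windows).

    The reference aggregates each edge over the basal windows where it is
    defined (``agg`` may be ``"mean"`` or ``"max"``). Ties at the cutoff are
    broken lexicographically by electrode pair; with fewer than `top_n`
    defined edges, all are kept.
    """
    if not basal_matrices:
        raise ValidationError("at least one basal matrix required")
    per_window = [_matrix_edges(m) for m in basal_matrices]
    combined = pd.concat(per_window, axis=1)
    if combined.dropna(how="all").empty:
        raise ValidationError("no defined edges in the basal windows")
    if agg == "mean":
        ref = combined.mean(axis=1, skipna=True)
    elif agg == "max":
        ref = combined.max(axis=1, skipna=True)
    else:
        raise ValidationError("agg must be 'mean' or 'max'")
    ref = ref.dropna()
    order = sorted(ref.index, key=lambda e: (-ref[e], e))
    chosen = order[: min(top_n, len(order))]
    ref = ref.loc[chosen]
    ref.index = pd.MultiIndex.from_tuples(chosen, names=["electrode_a", "electrode_b"])
    return EdgeSet(basal_reference=ref)


def attach_window(edge_set: EdgeSet, window_index: int, matrix: pd.DataFrame) -> None:
    """Record the STTC of each tracked edge in one window (NaN = missing)."""
    vals = []
    for a, b in edge_set.edges:
        if a in matrix.index and b in matrix.columns:
            vals.append(matrix.loc[a, b])
        else:
            vals.append(np.nan)
    edge_set.values[window_index] = vals


def basal_variation_threshold(
    edge_set: EdgeSet,
    basal_window_indices: list[int],
    fixed_default_pct: float = 20.0,
) -> tuple[float, bool]:
    """Data-driven decrease threshold: mean + 3 SD of basal variation.

    Percent changes of each edge between consecutive basal windows are
    pooled; the threshold is ``mean + 3*SD`` (sample SD) of the absolute
    decreases. With fewer than two basal windows, or no decreases observed,
    the fixed default applies. Returns ``(threshold_pct, used_fallback)``.
    """
    if len(basal_window_indices) < 2:
        warnings.warn("single basal window: falling back to fixed threshold", stacklevel=2)
        return fixed_default_pct, True
    drops: list[float] = []
    sub = edge_set.values[basal_window_indices]
    for _, row in sub.iterrows():
        vals = row.to_numpy(dtype=float)
        for prev, cur in zip(vals, vals[1:]):
            if np.isfinite(prev) and np.isfinite(cur) and prev != 0:
                change = 100.0 * (cur - prev) / prev
                if change < 0:
                    drops.append(abs(change))
    if not drops:
        return fixed_default_pct, True
    arr = np.asarray(drops)
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return float(arr.mean() + 3.0 * sd), False


def edge_decreases(
    edge_set: EdgeSet, window_index: int, threshold_pct: float
) -> tuple[float, list[tuple[str, str]]]:
    """Fraction (and list) of tracked edges dropping more than the threshold.

    An edge is flagged when ``(basal - current)/basal * 100 > threshold``;
    the fraction is over edges defined in the window.
    """
    flagged: list[tuple[str, str]] = []
    defined = 0
    col = edge_set.values[window_index]
    for edge in edge_set.edges:
        cur = col[edge]
        basal = edge_set.basal_reference[edge]
        if not np.isfinite(cur) or not np.isfinite(basal) or basal == 0:
            continue
        defined += 1
        if 100.0 * (basal - cur) / basal > threshold_pct:
            flagged.append(edge)
    fraction = len(flagged) / defined if defined else float("nan")
    return fraction, flagged


def deleted_edges(edge_set: EdgeSet, window_indices: list[int]) -> float:
    """Fraction of tracked edges missing (undefined) in every listed window.

    "Deleted" means the coefficient cannot be computed because at least one
    endpoint channel fell inactive — applied over all post-treatment windows
    this yields the permanently-lost connections.
    """
    if not window_indices:
        raise ValidationError("window_indices must be non-empty")
    sub = edge_set.values[window_indices]
    gone = (~np.isfinite(sub.to_numpy(dtype=float))).all(axis=1)
    return float(gone.mean())


def export_connectivity_map(
    edge_set: EdgeSet,
    window_index: int,
    grid: dict[str, tuple[int, int]] | None,
    csv_path: str | Path,
    png_path: str | Path | None = None,
) -> None:
    """Write the edge list CSV and, when grid metadata exists, a map figure.

    The CSV always contains one row per tracked edge (missing STTC as empty
    value). The figure draws electrodes on the 8x8 layout and colors each
    defined edge by its STTC; without grid metadata only the CSV is written.
    """
    col = edge_set.values[window_index]
    df = pd.DataFrame(
        [(a, b, col[(a, b)]) for a, b in edge_set.edges],
        columns=["electrode_a", "electrode_b", "sttc"],
    )
    df.to_csv(csv_path, index=False, float_format="%.9g", na_rep="")
    if png_path is None:
        return
    if grid is None:
        warnings.warn("no grid metadata: connectivity map not drawn", stacklevel=2)
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for ch, (row, colpos) in grid.items():
        ax.plot(colpos, row, "o", color="0.7", ms=4, zorder=1)
    finite = df.dropna(subset=["sttc"])
    if len(finite):
        vmin, vmax = finite.sttc.min(), finite.sttc.max()
        cmap = plt.get_cmap("viridis")
        for r in finite.itertuples():
            if r.electrode_a not in grid or r.electrode_b not in grid:
                continue
            ra, ca = grid[r.electrode_a]
            rb, cb = grid[r.electrode_b]
            frac = 0.5 if vmax == vmin else (r.sttc - vmin) / (vmax - vmin)
            ax.plot([ca, cb], [ra, rb], color=cmap(frac), lw=1.0, zorder=2)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_title(f"STTC map, window {window_index}")
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
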