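"""Multi-unit activity branch: filtering, spike/burst detection, metrics.

The >300 Hz component of the extracellular signal (MUA) carries the spiking
of neurons near each electrode. Spikes are detected on the high-pass
filtered trace by a hard negative threshold at ``-k * sigma_n`` (k = 5 by
default), bursts by an inter-spike-interval rule, and three network-level
metrics summarize the regime:

* MFR — mean firing rate, spikes/s per channel, averaged over channels;
* IBR — inverse burst ratio, percentage of spikes outside bursts;
* BI — burstiness index (Wagenaar-style): with all network spikes binned in
  1 s bins, ``BI = (f15 - 0.15) / 0.85`` where ``f15`` is the spike fraction
  captured by the 15% most populated bins. 0 = tonic firing, 1 = all spikes
  concentrated in few bins.

Metric values are normalized to the basal (pre-treatment) reference for
cross-experiment comparability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Burst, BurstList, RawRecording, SpikeTrainSet, ValidationError, METRICS_COLUMNS

__all__ = [
    "DetectionParams",
    "BurstParams",
    "highpass_filter",
    "estimate_noise_sigma",
    "detect_spikes",
    "detect_bursts",
    "detect_bursts_all",
    "mean_firing_rate",
    "inverse_burst_ratio",
    "burstiness_index",
    "percent_change",
    "compute_metrics",
    "normalize_to_basal",
]

#: MAD-to-SD consistency constant for a Gaussian.
MAD_SCALE = 0.6745


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection configuration.

    ``threshold_factor`` k sets the hard threshold at ``-k * sigma_n``
    (negative polarity by default); ``dead_time_ms`` suppresses re-triggering
    after each detected spike.
    """

    hp_cutoff_hz: float = 300.0
    hp_order: int = 2
    threshold_factor: float = 5.0
    dead_time_ms: float = 2.0
    polarity: str = "negative"  # "negative" | "positive" | "both"

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValidationError("threshold_factor must be positive")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValidationError("polarity must be negative, positive or both")


@dataclass(frozen=True)
class BurstParams:
    """ISI burst detector: runs of >=`min_spikes_per_burst` spikes with
    consecutive inter-spike intervals <= `max_isi_ms`."""

    max_isi_ms: float = 100.0
    min_spikes_per_burst: int = 3

    def __post_init__(self) -> None:
        if self.max_isi_ms <= 0:
            raise ValidationError("max_isi_ms must be positive")
        if self.min_spikes_per_burst < 2:
            raise ValidationError("min_spikes_per_burst must be >= 2")


def highpass_filter(
    rec: RawRecording, p: DetectionParams = DetectionParams(), causal: bool = False
) -> np.ndarray:
    """Butterworth high-pass per channel, output in microvolts.

    Zero-phase (forward-backward) by default so spike timestamps carry no
    group delay; `causal` gives the single-pass response of an online
    filter. Requires ``sampling_rate_hz > 2 * hp_cutoff_hz``.
    """
    if rec.sampling_rate_hz <= 2 * p.hp_cutoff_hz:
        raise ValidationError("high-pass cutoff must be below Nyquist")
    sos = sps.butter(
        p.hp_order, p.hp_cutoff_hz, btype="highpass", fs=rec.sampling_rate_hz, output="sos"
    )
    x = rec.in_uV()
    if causal:
        return sps.sosfilt(sos, x, axis=0)
    return sps.sosfiltfilt(sos, x, axis=0)


def estimate_noise_sigma(filtered: np.ndarray) -> np.ndarray:
    """Robust per-channel noise SD: ``median(|x|) / 0.6745``.

    The median absolute deviation is insensitive to the sparse large
    deflections produced by spikes, unlike the raw SD. All-zero channels
    yield sigma 0 (flagged with a warning); callers must not threshold them.
    """
    x = np.atleast_2d(filtered.T).T  # ensure [n_samples, n_channels]
    sigma = np.median(np.abs(x), axis=0) / MAD_SCALE
    if (sigma == 0).any():
        warnings.warn("all-zero channel(s): noise sigma estimated as 0", stacklevel=2)
    return sigma


def detect_spikes(
    filtered: np.ndarray,
    p: DetectionParams,
    sampling_rate_hz: float,
    channel_ids: list[str],
    t0_s: float = 0.0,
    sigma_n: np.ndarray | None = None,
) -> SpikeTrainSet:
    """Hard-threshold spike detection on the high-pass trace.

    A spike is declared at each threshold crossing (``x < -k*sigma_n`` for
    negative polarity); its timestamp is the extremum within the dead time
    after the crossing, and further crossings within ``dead_time_ms`` are
    suppressed. Channels with ``sigma_n == 0`` produce no spikes.
    """
    x = np.atleast_2d(filtered.T).T
    n, n_ch = x.shape
    if len(channel_ids) != n_ch:
        raise ValidationError("channel_ids length mismatch")
    if sigma_n is None:
        sigma_n = estimate_noise_sigma(x)
    sigma_n = np.asarray(sigma_n, dtype=float)
    dead = max(1, int(round(p.dead_time_ms / 1000.0 * sampling_rate_hz)))
    trains: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(channel_ids):
        if sigma_n[ci] <= 0:
            trains[ch] = np.empty(0)
            continue
        thr = p.threshold_factor * sigma_n[ci]
        if p.polarity == "negative":
            over = x[:, ci] < -thr
        elif p.polarity == "positive":
            over = x[:, ci] > thr
        else:
            over = np.abs(x[:, ci]) > thr
        crossings = np.flatnonzero(over & ~np.r_[False, over[:-1]])
        times = []
        last = -np.inf
        for i in crossings:
            if i < last + dead:
                continue
            seg = x[i : min(i + dead, n), ci]
            if p.polarity == "positive":
                j = int(np.argmax(seg))
            elif p.polarity == "negative":
                j = int(np.argmin(seg))
            else:
                j = int(np.argmax(np.abs(seg)))
            times.append(i + j)
            last = i
        trains[ch] = t0_s + np.asarray(times, dtype=float) / sampling_rate_hz
    return SpikeTrainSet(trains=trains, t_start_s=t0_s, t_end_s=t0_s + n / sampling_rate_hz)


def detect_bursts(
    train: np.ndarray, p: BurstParams = BurstParams(), channel_id: str = ""
) -> list[Burst]:
    """Maximal runs of spikes with ISI <= max_isi and length >= min_spikes."""
    ts = np.asarray(train, dtype=float)
    if ts.size and (np.diff(ts) <= 0).any():
        raise ValidationError("train must be strictly increasing")
    max_isi = p.max_isi_ms / 1000.0
    bursts: list[Burst] = []
    i = 0
    while i < ts.size:
        j = i
        while j + 1 < ts.size and ts[j + 1] - ts[j] <= max_isi:
            j += 1
        if j - i + 1 >= p.min_spikes_per_burst:
            bursts.append(Burst(channel_id, float(ts[i]), float(ts[j]), j - i + 1))
        i = j + 1
    return bursts


def detect_bursts_all(spikes: SpikeTrainSet, p: BurstParams = BurstParams()) -> BurstList:
    out: list[Burst] = []
    for ch in spikes.channels:
        out.extend(detect_bursts(spikes.trains[ch], p, channel_id=ch))
    return BurstList(out)


def mean_firing_rate(
    spikes: SpikeTrainSet, window: tuple[float, float]
) -> tuple[pd.Series, float]:
    """Per-channel and network-mean firing rate in ``window`` (spike/s).

    The network value averages over all channels (silent ones included).
    """
    start, end = window
    if end <= start:
        raise ValidationError("zero-length window")
    counts = {
        ch: int(((ts >= start) & (ts < end)).sum()) for ch, ts in spikes.trains.items()
    }
    per_channel = pd.Series(counts, dtype=float) / (end - start)
    return per_channel, float(per_channel.mean()) if len(per_channel) else 0.0


def _in_burst_mask(ts: np.ndarray, bursts: list[Burst]) -> np.ndarray:
    mask = np.zeros(ts.size, dtype=bool)
    for b in bursts:
        mask |= (ts >= b.start_s) & (ts <= b.end_s)
    return mask


def inverse_burst_ratio(
    spikes: SpikeTrainSet, bursts: BurstList, window: tuple[float, float]
) -> float:
    """Percentage of spikes outside any burst of their channel, pooled.

    Returns NaN (undefined) when the window contains no spikes.
    """
    start, end = window
    total = 0
    outside = 0
    for ch in spikes.channels:
        ts = spikes.trains[ch]
        ts = ts[(ts >= start) & (ts < end)]
        if not ts.size:
            continue
        total += ts.size
        outside += int((~_in_burst_mask(ts, bursts.for_channel(ch))).sum())
    if total == 0:
        warnings.warn("IBR undefined: no spikes in window", stacklevel=2)
        return float("nan")
    return 100.0 * outside / total


def burstiness_index(
    spikes: SpikeTrainSet,
    window: tuple[float, float],
    bin_s: float = 1.0,
    top_fraction: float = 0.15,
) -> float:
    """Network burstiness index in [0, 1].

    All network spikes in the window are counted in ``bin_s`` bins aligned to
    the window start; ``f15`` is the fraction captured by the
    ``ceil(top_fraction * n_bins)`` most populated bins and
    ``BI = (f15 - top_fraction) / (1 - top_fraction)`` clipped to [0, 1].
    Returns NaN when the window holds no spikes.
    """
    start, end = window
    if end - start < bin_s:
        raise ValidationError("window shorter than one bin")
    n_bins = int(np.floor((end - start) / bin_s))
    pooled = spikes.pooled()
    pooled = pooled[(pooled >= start) & (pooled < start + n_bins * bin_s)]
    if pooled.size == 0:
        warnings.warn("BI undefined: no spikes in window", stacklevel=2)
        return float("nan")
    counts, _ = np.histogram(pooled, bins=n_bins, range=(start, start + n_bins * bin_s))
    k = int(np.ceil(top_fraction * n_bins))
    top = np.sort(counts)[::-1][:k]
    f15 = top.sum() / pooled.size
    bi = (f15 - top_fraction) / (1.0 - top_fraction)
    return float(np.clip(bi, 0.0, 1.0))


def percent_change(x_start: float, x_end: float) -> float:
    """``100 * (x_end - x_start) / x_start``; NaN (flagged) when x_start is 0."""
    if x_start == 0 or not np.isfinite(x_start):
        warnings.warn("percent change undefined for zero/non-finite start", stacklevel=2)
        return float("nan")
    return 100.0 * (x_end - x_start) / x_start


def compute_metrics(
    spikes: SpikeTrainSet,
    bursts: BurstList,
    windows: list[tuple[float, float]],
    bin_s: float = 1.0,
) -> pd.DataFrame:
    """Long-format metrics table (MFR, IBR, BI per window, network scope)."""
    rows = []
    for wi, (start, end) in enumerate(windows):
        _, mfr = mean_firing_rate(spikes, (start, end))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ibr = inverse_burst_ratio(spikes, bursts, (start, end))
            bi = burstiness_index(spikes, (start, end), bin_s=bin_s)
        for name, value in (("MFR", mfr), ("IBR", ibr), ("BI", bi)):
            rows.append((wi, start, end - start, "network", name, value, np.nan))
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def normalize_to_basal(metrics: pd.DataFrame, basal_window_indices: list[int]) -> pd.DataFrame:
    """Fill ``normalized_value = value / basal reference`` per scope+metric.

    The basal reference is the mean over the listed basal windows; a zero or
    undefined reference leaves the normalized value NaN (flagged missing,
    never silently zero).
    """
    out = metrics.copy()
    basal = out[out.window_index.isin(basal_window_indices)]
    refs = basal.groupby(["scope", "metric_name"]).value.mean()
    norm = []
    for r in out.itertuples():
        ref = refs.get((r.scope, r.metric_name), np.nan)
        if not np.isfinite(ref) or ref == 0:
            norm.append(np.nan)
        else:
            norm.append(r.value / ref)
    out["normalized_value"] = norm
    return out
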