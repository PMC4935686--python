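"""Local-field-potential branch: decimation, Welch PSD, band power.

The <300 Hz component of the raw signal reflects aggregate synaptic and
membrane currents near each electrode. The chain is: Hamming-window FIR
low-pass below 500 Hz (order 30, group delay compensated), decimation to
1 kHz, Welch power spectral density (5 s Hamming segments, 50% overlap,
zero-padded to 8192 DFT points, so df = 1000/8192 ~ 0.12 Hz and segment
advance dt = 8192/1000 ~ 8.19 s), and trapezoidal band integration over
delta (1-4 Hz), theta (4-11), beta (11-30) and gamma (30-55). Delta
dominance of the spectrum is the slow-wave, sleep-like signature; its
suppression marks the desynchronized state.

Band-limited traces are extracted with long linear-phase FIR filters
(20000/10000/10000/5000 taps for delta/theta/beta/gamma) whose delay is
compensated by shifting half the filter length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import RawRecording, ValidationError, BAND_POWER_COLUMNS

__all__ = [
    "WelchParams",
    "BandSpec",
    "BAND_EDGES",
    "band_specs",
    "Decimated",
    "BandTrace",
    "antialias_decimate",
    "welch_psd",
    "band_power",
    "band_filter",
    "psd_summary",
]

#: Frequency bands in Hz, half-open [lo, hi) except the top of gamma.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 11.0),
    "beta": (11.0, 30.0),
    "gamma": (30.0, 55.0),
}

_FIR_LENGTHS = {"delta": 20000, "theta": 10000, "beta": 10000, "gamma": 5000}


@dataclass(frozen=True)
class WelchParams:
    """Welch estimator configuration (Hamming taper, density scaling)."""

    window_s: float = 5.0
    overlap: float = 0.5
    dft_points: int = 8192
    target_fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValidationError("overlap must be in [0, 1)")
        if self.dft_points < self.nperseg:
            raise ValidationError("dft_points must be >= window samples")

    @property
    def nperseg(self) -> int:
        return int(round(self.window_s * self.target_fs_hz))

    @property
    def noverlap(self) -> int:
        return int(round(self.nperseg * self.overlap))

    @property
    def df_hz(self) -> float:
        """Frequency resolution of the zero-padded DFT grid."""
        return self.target_fs_hz / self.dft_points

    @property
    def dt_s(self) -> float:
        """Temporal resolution: one DFT length of signal."""
        return self.dft_points / self.target_fs_hz

    @property
    def config_id(self) -> str:
        return (
            f"w{self.window_s:g}s_o{int(self.overlap * 100)}"
            f"_n{self.dft_points}_fs{self.target_fs_hz:g}"
        )


@dataclass(frozen=True)
class BandSpec:
    name: str
    f_lo: float
    f_hi: float
    fir_length: int

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValidationError("band edges must satisfy 0 < f_lo < f_hi")


def band_specs(target_fs_hz: float = 1000.0) -> list[BandSpec]:
    """The four standard bands with their FIR trace-filter lengths."""
    out = []
    for name, (lo, hi) in BAND_EDGES.items():
        if hi >= target_fs_hz / 2:
            raise ValidationError(f"band {name} exceeds Nyquist")
        out.append(BandSpec(name, lo, hi, _FIR_LENGTHS[name]))
    return out


@dataclass
class Decimated:
    """Decimated LFP signal in microvolts, [n_samples x n_channels]."""

    data: np.ndarray
    sampling_rate_hz: float
    channel_ids: list[str]
    t0_s: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def antialias_decimate(rec: RawRecording, target_fs_hz: float = 1000.0) -> Decimated:
    """Low-pass below 500 Hz (Hamming FIR, order 30) and keep every k-th sample.

    The 31-tap filter's 15-sample group delay is compensated before
    decimation, so decimated timestamps stay aligned with the raw clock.
    The input rate must be an integer multiple of the target rate.
    """
    factor = rec.sampling_rate_hz / target_fs_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValidationError(
            f"sampling rate {rec.sampling_rate_hz} is not an integer multiple of {target_fs_hz}"
        )
    factor = int(round(factor))
    taps = sps.firwin(31, target_fs_hz / 2, window="hamming", fs=rec.sampling_rate_hz)
    x = rec.in_uV()
    # mode="same" with an odd-length symmetric FIR = group-delay-compensated output
    y = sps.fftconvolve(x, taps[:, None], mode="same", axes=0)
    return Decimated(
        data=y[::factor],
        sampling_rate_hz=target_fs_hz,
        channel_ids=list(rec.channel_ids),
        t0_s=rec.t0_s,
    )


def welch_psd(
    x: np.ndarray, p: WelchParams = WelchParams()
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of a single decimated channel, in uV^2/Hz.

    Hamming-tapered segments with the configured overlap are zero-padded to
    ``dft_points`` and averaged; density scaling includes the taper power
    correction, so the integral over frequency recovers the signal variance
    (Parseval). Each segment's mean is removed.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("welch_psd expects a single channel")
    if x.size < p.nperseg:
        raise ValidationError("signal shorter than one Welch window")
    freqs, psd = sps.welch(
        x,
        fs=p.target_fs_hz,
        window="hamming",
        nperseg=p.nperseg,
        noverlap=p.noverlap,
        nfft=p.dft_points,
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandSpec) -> float:
    """Trapezoidal integral of the PSD over ``[f_lo, f_hi)`` in uV^2."""
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


@dataclass
class BandTrace:
    """Band-limited trace with its valid (delay-compensated) region."""

    data: np.ndarray
    valid: np.ndarray  # boolean mask; False within half a filter length of the edges
    band: BandSpec


def band_filter(
    x: np.ndarray, band: BandSpec, sampling_rate_hz: float = 1000.0
) -> BandTrace:
    """Linear-phase band-pass FIR of the band's specified length.

    The output is shifted by half the filter length to cancel the group
    delay; the half-length stretches at both ends, where the convolution is
    incomplete, are marked invalid.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= band.fir_length:
        raise ValidationError("signal shorter than the band filter")
    taps = sps.firwin(
        band.fir_length,
        [band.f_lo, band.f_hi],
        pass_zero=False,
        window="hamming",
        fs=sampling_rate_hz,
    )
    full = sps.fftconvolve(x, taps, mode="full")
    delay = band.fir_length // 2
    out = full[delay : delay + x.size]
    valid = np.zeros(x.size, dtype=bool)
    half = band.fir_length // 2
    if x.size > 2 * half:
        valid[half : x.size - half] = True
    return BandTrace(data=out, valid=valid, band=band)


def psd_summary(
    dec: Decimated,
    windows: list[tuple[float, float]],
    p: WelchParams = WelchParams(),
    bands: list[BandSpec] | None = None,
) -> pd.DataFrame:
    """Per-window, per-band integrated power table.

    Windows are absolute times ``[start, end)``; each channel is analyzed
    separately and a ``"mean"`` row averages the band power over channels.
    """
    if bands is None:
        bands = band_specs(dec.sampling_rate_hz)
    rows = []
    for wi, (start, end) in enumerate(windows):
        i0 = int(round((start - dec.t0_s) * dec.sampling_rate_hz))
        i1 = int(round((end - dec.t0_s) * dec.sampling_rate_hz))
        if i0 < 0 or i1 > dec.n_samples or i1 <= i0:
            raise ValidationError(f"window {wi} outside the decimated signal")
        per_band: dict[str, list[float]] = {b.name: [] for b in bands}
        for ci, ch in enumerate(dec.channel_ids):
            freqs, psd = welch_psd(dec.data[i0:i1, ci], p)
            for b in bands:
                power = band_power(freqs, psd, b)
                per_band[b.name].append(power)
                rows.append((wi, ch, b.name, power, p.config_id))
        for b in bands:
            rows.append((wi, "mean", b.name, float(np.mean(per_band[b.name])), p.config_id))
    return pd.DataFrame(rows, columns=BAND_POWER_COLUMNS)
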