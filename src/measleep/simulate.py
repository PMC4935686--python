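"""Synthetic MEA-like spike trains and raw signals.

Cortical cultures on planar MEAs spontaneously produce a slow-wave,
"sleep-like" regime: brief (50-100 ms) network-wide bursts recurring at
0.16-3 Hz, separated by near-quiescence. Cholinergic activation (carbachol)
desynchronizes the network: bursts fragment, channel participation drops,
isolated (tonic) spikes multiply, and low-frequency LFP power collapses with
a slow partial recovery over hours. The generators here emulate exactly that
phenomenology with homogeneous Poisson building blocks — no biophysics —
which is enough to exercise every analysis stage quantitatively.

All randomness is driven by an explicit integer seed; identical
``(params, seed)`` produce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np

from .io import RawRecording, SpikeTrainSet, ValidationError, mea_60_layout

__all__ = [
    "RegimeParams",
    "ProtocolSpec",
    "sleep_like",
    "cch_like",
    "SLEEP_LFP_COMPONENTS",
    "CCH_LFP_COMPONENTS",
    "generate_spikes",
    "generate_spikes_with_bursts",
    "generate_raw",
    "generate_experiment",
    "ExperimentResult",
    "default_channel_ids",
]

#: Per-channel absolute refractory period enforced by thinning (seconds).
REFRACTORY_S = 0.002


@dataclass(frozen=True)
class RegimeParams:
    """Parameters of one firing regime.

    Rates are per channel; `participation` is the probability that a channel
    is recruited into a given network burst; `jitter_ms` jitters each
    recruited channel's burst onset (Gaussian SD).
    """

    network_burst_rate_hz: float = 0.2
    burst_duration_ms: float = 75.0
    in_burst_rate_hz: float = 150.0
    tonic_rate_hz: float = 0.05
    participation: float = 0.9
    jitter_ms: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "network_burst_rate_hz",
            "burst_duration_ms",
            "in_burst_rate_hz",
            "tonic_rate_hz",
            "jitter_ms",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.participation <= 1.0:
            raise ValidationError("participation must be in [0, 1]")


def sleep_like() -> RegimeParams:
    """Synchronized slow-bursting regime (basal / slow-wave-like)."""
    return RegimeParams()


def cch_like() -> RegimeParams:
    """Desynchronized regime: fragmented bursts, many isolated spikes."""
    return RegimeParams(
        network_burst_rate_hz=0.2,
        burst_duration_ms=75.0,
        in_burst_rate_hz=50.0,
        tonic_rate_hz=1.5,
        participation=0.25,
        jitter_ms=10.0,
    )


# LFP oscillation components (band_name, center_freq_hz, amplitude_uV).
# Amplitudes follow A = sqrt(2 P) from typical per-band mean powers of
# slow-wave-dominant cultures (~8.9/4.2/2.0/1.5 uV^2) and of cholinergically
# desynchronized ones (~3.3/1.2/1.0/0.9 uV^2).
SLEEP_LFP_COMPONENTS: list[tuple[str, float, float]] = [
    ("delta", 2.5, 4.21),
    ("theta", 7.5, 2.88),
    ("beta", 20.0, 2.01),
    ("gamma", 42.0, 1.75),
]
CCH_LFP_COMPONENTS: list[tuple[str, float, float]] = [
    ("delta", 2.5, 2.56),
    ("theta", 7.5, 1.56),
    ("beta", 20.0, 1.41),
    ("gamma", 42.0, 1.32),
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Recording protocol: basal phase followed by a treatment phase.

    ``desync_depth`` is the initial fraction of full desynchronization at
    treatment onset; the regime relaxes back toward basal with time constant
    ``recovery_tau_s`` (infinite = no recovery). The first
    ``discard_after_treatment_s`` seconds of the treatment phase are excluded
    from analysis windows (pipetting artifact in the emulated experiments).
    """

    basal_duration_s: float = 7 * 3600.0
    treatment_duration_s: float = 24 * 3600.0
    discard_after_treatment_s: float = 600.0
    desync_depth: float = 1.0
    recovery_tau_s: float = math.inf

    def __post_init__(self) -> None:
        if self.basal_duration_s <= 0 or self.treatment_duration_s <= 0:
            raise ValidationError("phase durations must be positive")
        if not 0 <= self.discard_after_treatment_s < self.treatment_duration_s:
            raise ValidationError("discard must be shorter than the treatment phase")
        if not 0 <= self.desync_depth <= 1:
            raise ValidationError("desync_depth must be in [0, 1]")
        if self.recovery_tau_s <= 0:
            raise ValidationError("recovery_tau_s must be positive")


def default_channel_ids(n_channels: int) -> list[str]:
    """First `n_channels` labels of the 59-site MEA layout (row-major)."""
    layout = mea_60_layout()
    labels = sorted(layout, key=lambda k: layout[k])
    if n_channels > len(labels):
        labels = labels + [f"x{i}" for i in range(n_channels - len(labels))]
    return labels[:n_channels]


def _thin_refractory(ts: np.ndarray, refractory_s: float = REFRACTORY_S) -> np.ndarray:
    """Greedy thinning: keep each spike only if >= refractory after the last kept."""
    if ts.size < 2:
        return ts
    kept = [ts[0]]
    last = ts[0]
    for t in ts[1:]:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def generate_spikes_with_bursts(
    params: RegimeParams,
    n_channels: int,
    duration_s: float,
    seed: int,
    t0_s: float = 0.0,
    channel_ids: Sequence[str] | None = None,
) -> tuple[SpikeTrainSet, np.ndarray]:
    """Draw one realization of the regime; also return network-burst event times.

    Network-burst event times are homogeneous Poisson at
    ``network_burst_rate_hz``; each burst recruits every channel
    independently with probability ``participation``; a recruited channel
    fires an in-burst Poisson barrage of ``burst_duration_ms`` starting at a
    jittered onset. Independent tonic Poisson spikes are superimposed. A 2 ms
    per-channel refractory period is enforced by thinning.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    if channel_ids is None:
        channel_ids = default_channel_ids(n_channels)
    if len(channel_ids) != n_channels:
        raise ValidationError("channel_ids length must equal n_channels")
    rng = np.random.default_rng(seed)
    t_end = t0_s + duration_s
    burst_dur = params.burst_duration_ms / 1000.0
    jitter = params.jitter_ms / 1000.0

    n_bursts = rng.poisson(params.network_burst_rate_hz * duration_s)
    burst_times = np.sort(rng.uniform(t0_s, t_end, size=n_bursts))

    trains: dict[str, np.ndarray] = {}
    per_channel: list[list[np.ndarray]] = [[] for _ in range(n_channels)]
    for tb in burst_times:
        recruited = np.flatnonzero(rng.random(n_channels) < params.participation)
        for ci in recruited:
            onset = tb + rng.normal(0.0, jitter)
            k = rng.poisson(params.in_burst_rate_hz * burst_dur)
            if k:
                per_channel[ci].append(onset + rng.uniform(0.0, burst_dur, size=k))
    for ci, ch in enumerate(channel_ids):
        k = rng.poisson(params.tonic_rate_hz * duration_s)
        if k:
            per_channel[ci].append(rng.uniform(t0_s, t_end, size=k))
        if per_channel[ci]:
            ts = np.sort(np.concatenate(per_channel[ci]))
            ts = ts[(ts >= t0_s) & (ts < t_end)]
            ts = _thin_refractory(ts)
        else:
            ts = np.empty(0)
        trains[ch] = ts
    return SpikeTrainSet(trains=trains, t_start_s=t0_s, t_end_s=t_end), burst_times


def generate_spikes(
    params: RegimeParams,
    n_channels: int,
    duration_s: float,
    seed: int,
    t0_s: float = 0.0,
    channel_ids: Sequence[str] | None = None,
) -> SpikeTrainSet:
    """Draw one realization of the regime as a spike-train set."""
    spikes, _ = generate_spikes_with_bursts(
        params, n_channels, duration_s, seed, t0_s=t0_s, channel_ids=channel_ids
    )
    return spikes


def _spike_template(sampling_rate_hz: float, amplitude_uV: float) -> np.ndarray:
    """Biphasic ~1 ms extracellular waveform, negative peak at `amplitude_uV`."""
    t = np.arange(0.0, 0.001, 1.0 / sampling_rate_hz)
    w = -np.exp(-((t - 0.30e-3) ** 2) / (2 * (0.10e-3) ** 2)) + 0.35 * np.exp(
        -((t - 0.65e-3) ** 2) / (2 * (0.15e-3) ** 2)
    )
    return w * (amplitude_uV / abs(w.min()))


def _burst_envelope(
    times: np.ndarray, burst_times: np.ndarray, width_s: float = 0.15, floor: float = 0.2
) -> np.ndarray:
    """Smooth gate tracking network bursts, normalized to unit RMS."""
    env = np.full(times.size, floor)
    for tb in burst_times:
        env += np.exp(-((times - tb) ** 2) / (2 * width_s**2))
    rms = math.sqrt(float(np.mean(env**2)))
    return env / rms if rms > 0 else env


def generate_raw(
    spikes: SpikeTrainSet,
    lfp_spec: Sequence[tuple[str, float, float]],
    noise_sigma_uV: float,
    seed: int,
    sampling_rate_hz: float = 10000.0,
    lsb_uV: float = 0.1,
    spike_amplitude_uV: float = 50.0,
    envelope_times: np.ndarray | None = None,
    envelope_bands: frozenset[str] = frozenset({"delta"}),
) -> RawRecording:
    """Render spike trains as a raw wide-band recording.

    The signal per channel is Gaussian noise (SD `noise_sigma_uV`) plus a
    biphasic ~1 ms waveform (negative peak ``-spike_amplitude_uV``) at each
    spike time plus the sum of the `lfp_spec` sinusoid components
    ``(band_name, center_freq_hz, amplitude_uV)``. When `envelope_times`
    (network-burst event times) is given, components whose band is in
    `envelope_bands` are amplitude-modulated by a smooth burst-locked gate —
    the slow-wave delta rhythm rides on the bursting. Output is quantized at
    `lsb_uV`.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spikes.span_s * sampling_rate_hz))
    channels = spikes.channels
    t = spikes.t_start_s + np.arange(n) / sampling_rate_hz

    lfp = np.zeros(n)
    env = None
    if envelope_times is not None and len(envelope_times):
        env = _burst_envelope(t, np.asarray(envelope_times))
    for band, freq, amp in lfp_spec:
        comp = amp * np.sin(2 * np.pi * freq * (t - spikes.t_start_s))
        if env is not None and band in envelope_bands:
            comp = comp * env
        lfp += comp

    template = _spike_template(sampling_rate_hz, spike_amplitude_uV)
    data = np.empty((n, len(channels)), dtype=np.float64)
    for ci, ch in enumerate(channels):
        x = rng.normal(0.0, noise_sigma_uV, size=n) + lfp
        ts = spikes.trains[ch]
        if ts.size:
            idx = np.round((ts - spikes.t_start_s) * sampling_rate_hz).astype(int)
            if (idx < 0).any() or (idx >= n).any():
                raise ValidationError(f"channel {ch}: spike time outside raw duration")
            for i in idx:
                stop = min(i + template.size, n)
                x[i:stop] += template[: stop - i]
        data[:, ci] = x
    counts = np.rint(data / lsb_uV)
    counts = np.clip(counts, -32768, 32767).astype(np.int16)
    return RawRecording(
        samples=counts,
        channel_ids=list(channels),
        lsb_uV=lsb_uV,
        sampling_rate_hz=sampling_rate_hz,
        t0_s=spikes.t_start_s,
    )


def _interp_params(basal: RegimeParams, treated: RegimeParams, mix: float) -> RegimeParams:
    """Linear interpolation basal->treated at mixing fraction `mix`."""
    fields = asdict(basal)
    out = {
        k: (1.0 - mix) * fields[k] + mix * getattr(treated, k) for k in fields
    }
    return RegimeParams(**out)


@dataclass
class ExperimentResult:
    basal: SpikeTrainSet
    treatment: SpikeTrainSet
    manifest: dict

    def combined(self) -> SpikeTrainSet:
        """Basal and treatment phases merged over the full protocol span."""
        trains: dict[str, np.ndarray] = {}
        for ch in self.basal.channels:
            trains[ch] = np.concatenate([self.basal.trains[ch], self.treatment.trains[ch]])
        return SpikeTrainSet(
            trains=trains, t_start_s=self.basal.t_start_s, t_end_s=self.treatment.t_end_s
        )


def generate_experiment(
    protocol: ProtocolSpec,
    basal: RegimeParams,
    treated: RegimeParams,
    seed: int,
    n_channels: int = 59,
    segment_s: float = 60.0,
) -> ExperimentResult:
    """Simulate the full basal + treatment protocol.

    The treatment phase interpolates from `treated` (scaled by
    ``protocol.desync_depth`` at onset) back toward `basal` with
    ``protocol.recovery_tau_s``: the mixing fraction at time ``u`` after
    treatment onset is ``desync_depth * exp(-u / tau)``. The phase is
    generated piecewise in `segment_s` segments with the regime frozen at
    each segment midpoint. The manifest records phase boundaries, per-segment
    seeds and parameters.
    """
    rng = np.random.default_rng(seed)
    basal_seed = int(rng.integers(2**31))
    channel_ids = default_channel_ids(n_channels)
    basal_set = generate_spikes(
        basal, n_channels, protocol.basal_duration_s, basal_seed, t0_s=0.0,
        channel_ids=channel_ids,
    )

    t_treat0 = protocol.basal_duration_s
    n_seg = max(1, int(math.ceil(protocol.treatment_duration_s / segment_s)))
    seg_edges = np.linspace(0.0, protocol.treatment_duration_s, n_seg + 1)
    seg_trains: dict[str, list[np.ndarray]] = {ch: [] for ch in channel_ids}
    segments_meta = []
    for i in range(n_seg):
        u_mid = 0.5 * (seg_edges[i] + seg_edges[i + 1])
        if math.isinf(protocol.recovery_tau_s):
            mix = protocol.desync_depth
        else:
            mix = protocol.desync_depth * math.exp(-u_mid / protocol.recovery_tau_s)
        params_i = _interp_params(basal, treated, mix)
        seg_seed = int(rng.integers(2**31))
        seg = generate_spikes(
            params_i,
            n_channels,
            seg_edges[i + 1] - seg_edges[i],
            seg_seed,
            t0_s=t_treat0 + seg_edges[i],
            channel_ids=channel_ids,
        )
        for ch in channel_ids:
            seg_trains[ch].append(seg.trains[ch])
        segments_meta.append(
            {"start_s": float(t_treat0 + seg_edges[i]), "mix": mix, "seed": seg_seed,
             "params": asdict(params_i)}
        )
    treat_trains = {}
    for ch in channel_ids:
        ts = np.concatenate(seg_trains[ch]) if seg_trains[ch] else np.empty(0)
        treat_trains[ch] = _thin_refractory(ts)
    treatment_set = SpikeTrainSet(
        trains=treat_trains,
        t_start_s=t_treat0,
        t_end_s=t_treat0 + protocol.treatment_duration_s,
    )
    manifest = {
        "seed": seed,
        "basal_seed": basal_seed,
        "n_channels": n_channels,
        "phase_boundaries_s": [
            protocol.basal_duration_s,
            protocol.basal_duration_s + protocol.treatment_duration_s,
        ],
        "protocol": asdict(protocol),
        "basal_params": asdict(basal),
        "treated_params": asdict(treated),
        "segments": segments_meta,
    }
    return ExperimentResult(basal=basal_set, treatment=treatment_set, manifest=manifest)
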