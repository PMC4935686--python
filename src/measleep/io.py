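"""On-disk formats and the in-memory data model.

Raw recordings are stored as flat little-endian int16, channel-interleaved,
with a JSON sidecar (same stem, ``.json``) holding the sampling metadata.
Spike trains, bursts, metrics, edges and band powers are plain CSV so that
every fixture stays human-inspectable. All intervals are half-open
``[start, end)``; spike timestamps are seconds, printed with 9 decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CorruptionError",
    "ValidationError",
    "RawRecording",
    "SpikeTrainSet",
    "Burst",
    "BurstList",
    "read_raw_recording",
    "write_raw_recording",
    "read_spike_trains",
    "write_spike_trains",
    "read_bursts",
    "write_bursts",
    "write_metrics",
    "read_metrics",
    "write_band_powers",
    "read_band_powers",
    "mea_60_layout",
]

METRICS_COLUMNS = [
    "window_index",
    "window_start_s",
    "window_len_s",
    "scope",
    "metric_name",
    "value",
    "normalized_value",
]

BAND_POWER_COLUMNS = [
    "window_index",
    "channel_id",
    "band_name",
    "power_uV2",
    "welch_config_id",
]


class FormatError(ValueError):
    """A file does not follow the expected on-disk format."""


class CorruptionError(ValueError):
    """A file is structurally inconsistent (e.g. truncated payload)."""


class ValidationError(ValueError):
    """In-memory data violates a model invariant."""


@dataclass
class RawRecording:
    """Multi-channel continuous extracellular signal in ADC counts.

    Parameters
    ----------
    samples
        Integer matrix of shape ``(n_samples, n_channels)``. The physical
        value of a sample ``s`` is ``s * lsb_uV`` microvolts.
    channel_ids
        Unique electrode labels, one per column of `samples`.
    lsb_uV
        Scale factor in microvolts per ADC count.
    sampling_rate_hz
        Acquisition rate; the systems emulated here sample at 10 kHz.
    t0_s
        Absolute recording start time in seconds.
    """

    samples: np.ndarray
    channel_ids: list[str]
    lsb_uV: float
    sampling_rate_hz: float = 10000.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D [n_samples x n_channels] matrix")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if self.samples.shape[1] != len(self.channel_ids):
            raise ValidationError(
                f"{self.samples.shape[1]} sample columns but {len(self.channel_ids)} channel ids"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("channel_ids must be unique")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if not self.lsb_uV > 0:
            raise ValidationError("lsb_uV must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def in_uV(self) -> np.ndarray:
        """Samples converted to microvolts (float64)."""
        return self.samples.astype(np.float64) * self.lsb_uV

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz


def write_raw_recording(rec: RawRecording, path: str | Path) -> None:
    """Write ``<stem>.bin`` (int16 LE, channel-interleaved) plus JSON sidecar."""
    path = Path(path)
    if path.suffix != ".bin":
        path = path.with_suffix(".bin")
    data = np.ascontiguousarray(rec.samples, dtype="<i2")
    data.tofile(path)
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_ids": rec.channel_ids,
        "lsb_uV": rec.lsb_uV,
        "t0_s": rec.t0_s,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_raw_recording(path: str | Path) -> RawRecording:
    """Read a raw recording written by :func:`write_raw_recording`.

    Raises
    ------
    FormatError
        If the JSON sidecar is missing or lacks required keys.
    CorruptionError
        If the payload size is not a whole number of frames.
    """
    path = Path(path)
    if path.suffix != ".bin":
        path = path.with_suffix(".bin")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate_hz", "channel_ids", "lsb_uV", "t0_s"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path} missing key {key!r}")
    n_channels = len(meta["channel_ids"])
    frame_bytes = 2 * n_channels
    n_bytes = path.stat().st_size
    if n_bytes % frame_bytes != 0:
        raise CorruptionError(
            f"{path}: {n_bytes} bytes is not a multiple of the {frame_bytes}-byte frame"
        )
    samples = np.fromfile(path, dtype="<i2").reshape(-1, n_channels)
    return RawRecording(
        samples=samples,
        channel_ids=list(meta["channel_ids"]),
        lsb_uV=float(meta["lsb_uV"]),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        t0_s=float(meta["t0_s"]),
    )


@dataclass
class SpikeTrainSet:
    """Per-channel sorted spike timestamps over ``[t_start_s, t_end_s)``."""

    trains: dict[str, np.ndarray]
    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if not self.t_end_s > self.t_start_s:
            raise ValidationError("span must satisfy t_end_s > t_start_s")
        clean: dict[str, np.ndarray] = {}
        for ch, ts in self.trains.items():
            ts = np.asarray(ts, dtype=np.float64)
            if ts.size and (np.diff(ts) <= 0).any():
                raise ValidationError(
                    f"channel {ch}: timestamps must be strictly increasing (duplicates rejected)"
                )
            if ts.size and (ts[0] < self.t_start_s or ts[-1] >= self.t_end_s):
                raise ValidationError(
                    f"channel {ch}: timestamps outside span [{self.t_start_s}, {self.t_end_s})"
                )
            clean[str(ch)] = ts
        self.trains = clean

    @property
    def channels(self) -> list[str]:
        return list(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(ts.size for ts in self.trains.values()))

    @property
    def span_s(self) -> float:
        return self.t_end_s - self.t_start_s

    def window(self, start_s: float, end_s: float) -> "SpikeTrainSet":
        """Restrict to spikes in ``[start_s, end_s)``."""
        trains = {
            ch: ts[(ts >= start_s) & (ts < end_s)] for ch, ts in self.trains.items()
        }
        return SpikeTrainSet(trains=trains, t_start_s=start_s, t_end_s=end_s)

    def pooled(self) -> np.ndarray:
        """All spikes of the network, time-sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate([ts for ts in self.trains.values()]))


def write_spike_trains(spikes: SpikeTrainSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# span_s,{spikes.t_start_s:.9f},{spikes.t_end_s:.9f}\n")
        fh.write("channel_id,timestamp_s\n")
        for ch in spikes.channels:
            for t in spikes.trains[ch]:
                fh.write(f"{ch},{t:.9f}\n")


def read_spike_trains(
    path: str | Path, span: tuple[float, float] | None = None
) -> SpikeTrainSet:
    """Read a spike-train CSV; `span` overrides the ``# span_s`` header row."""
    path = Path(path)
    file_span: tuple[float, float] | None = None
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("# span_s,"):
        parts = first.strip().split(",")
        file_span = (float(parts[1]), float(parts[2]))
    df = pd.read_csv(path, comment="#", dtype={"channel_id": str})
    if list(df.columns) != ["channel_id", "timestamp_s"]:
        raise FormatError(f"{path}: expected header channel_id,timestamp_s")
    if span is None:
        span = file_span
    if span is None:
        if len(df):
            span = (min(0.0, df.timestamp_s.min()), np.nextafter(df.timestamp_s.max(), np.inf))
        else:
            raise FormatError(f"{path}: empty file with no span metadata")
    trains: dict[str, np.ndarray] = {}
    for ch, grp in df.groupby("channel_id", sort=True):
        ts = np.sort(grp.timestamp_s.to_numpy(dtype=np.float64))
        if ts.size and (np.diff(ts) == 0).any():
            raise ValidationError(f"{path}: duplicate timestamp on channel {ch}")
        trains[str(ch)] = ts
    return SpikeTrainSet(trains=trains, t_start_s=span[0], t_end_s=span[1])


@dataclass(frozen=True)
class Burst:
    channel_id: str
    start_s: float
    end_s: float
    n_spikes: int


@dataclass
class BurstList:
    """Per-channel bursts: non-overlapping, time-ordered intervals."""

    bursts: list[Burst] = field(default_factory=list)

    def __post_init__(self) -> None:
        per_channel: dict[str, list[Burst]] = {}
        for b in self.bursts:
            if b.end_s < b.start_s:
                raise ValidationError(f"burst on {b.channel_id}: end before start")
            if b.n_spikes < 1:
                raise ValidationError(f"burst on {b.channel_id}: n_spikes < 1")
            per_channel.setdefault(b.channel_id, []).append(b)
        for ch, items in per_channel.items():
            for prev, cur in zip(items, items[1:]):
                if cur.start_s <= prev.end_s:
                    raise ValidationError(f"channel {ch}: bursts overlap or out of order")

    def for_channel(self, channel_id: str) -> list[Burst]:
        return [b for b in self.bursts if b.channel_id == channel_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.channel_id, b.start_s, b.end_s, b.n_spikes) for b in self.bursts],
            columns=["channel_id", "start_s", "end_s", "n_spikes"],
        )

    def __len__(self) -> int:
        return len(self.bursts)


def write_bursts(bursts: BurstList, path: str | Path) -> None:
    df = bursts.to_frame()
    df.to_csv(path, index=False, float_format="%.9f")


def read_bursts(path: str | Path) -> BurstList:
    df = pd.read_csv(path, dtype={"channel_id": str})
    if list(df.columns) != ["channel_id", "start_s", "end_s", "n_spikes"]:
        raise FormatError(f"{path}: expected header channel_id,start_s,end_s,n_spikes")
    return BurstList(
        [
            Burst(str(r.channel_id), float(r.start_s), float(r.end_s), int(r.n_spikes))
            for r in df.itertuples()
        ]
    )


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in METRICS_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValidationError(f"metrics table missing columns {missing}")
    metrics[METRICS_COLUMNS].to_csv(path, index=False, float_format="%.9g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != METRICS_COLUMNS:
        raise FormatError(f"{path}: unexpected metrics header")
    return df


def write_band_powers(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in BAND_POWER_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"band-power table missing columns {missing}")
    table[BAND_POWER_COLUMNS].to_csv(path, index=False, float_format="%.9g")


def read_band_powers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != BAND_POWER_COLUMNS:
        raise FormatError(f"{path}: unexpected band-power header")
    return df


def mea_60_layout(reference: str = "15") -> dict[str, tuple[int, int]]:
    """Standard 8x8 planar MEA layout minus the four corners.

    Labels follow the column-row convention (``"12"`` = column 1, row 2).
    The four corner positions do not carry electrodes and `reference`
    names the electrode replaced by the ground, leaving 59 recording sites.
    Returned mapping: label -> (row, col), both 1-based.
    """
    layout: dict[str, tuple[int, int]] = {}
    for col in range(1, 9):
        for row in range(1, 9):
            if (col, row) in {(1, 1), (1, 8), (8, 1), (8, 8)}:
                continue
            label = f"{col}{row}"
            if label == reference:
                continue
            layout[label] = (row, col)
    return layout
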