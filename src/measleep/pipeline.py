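"""End-to-end orchestration of the basal + treatment protocol.

Windows tile each phase hourly (or a scaled-down length), skipping the
post-treatment discard interval; named key windows (start / middle / end of
each phase) drive the summary comparisons. `run_experiment` runs the full
chain — simulate or load spikes, burst detection, MFR/IBR/BI metrics with
basal normalization, hourly STTC edge tracking, optional LFP band powers —
and writes deterministic CSV tables plus a JSON manifest of every parameter.

Group comparison follows the conventional decision rule: Kolmogorov-Smirnov
normality on each sample, two-sample t-test when both pass, Mann-Whitney
otherwise; significance is reported at alpha = 0.05 but not decided for the
caller.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .io import (
    SpikeTrainSet,
    ValidationError,
    read_raw_recording,
    read_spike_trains,
    write_metrics,
    write_spike_trains,
    write_band_powers,
)
from .simulate import (
    CCH_LFP_COMPONENTS,
    SLEEP_LFP_COMPONENTS,
    ExperimentResult,
    ProtocolSpec,
    RegimeParams,
    cch_like,
    generate_experiment,
    generate_raw,
    sleep_like,
)
from . import mua
from . import connectivity as conn
from . import lfp as lfp_mod

__all__ = [
    "AnalysisWindows",
    "make_windows",
    "GroupComparison",
    "compare_groups",
    "PipelineError",
    "default_config",
    "run_experiment",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisWindows:
    """Hourly tiling of both phases plus named key windows.

    ``basal`` and ``treatment`` are lists of absolute ``(start, end)``
    intervals; window indices are global (basal first, then treatment).
    ``key`` maps phase -> {"start" | "middle" | "end"} -> global index, the
    middle being the window containing the phase midpoint.
    """

    basal: list[tuple[float, float]]
    treatment: list[tuple[float, float]]
    key: dict[str, dict[str, int]]
    window_len_s: float

    @property
    def all(self) -> list[tuple[float, float]]:
        return self.basal + self.treatment

    @property
    def basal_indices(self) -> list[int]:
        return list(range(len(self.basal)))

    @property
    def treatment_indices(self) -> list[int]:
        return list(range(len(self.basal), len(self.basal) + len(self.treatment)))


def make_windows(protocol: ProtocolSpec, window_len_s: float = 3600.0) -> AnalysisWindows:
    """Tile both phases with contiguous windows of ``window_len_s``.

    Basal windows start at 0; treatment windows start after the discard
    interval. Partial trailing windows are dropped. Each phase must fit at
    least one full window.
    """
    if protocol.basal_duration_s < window_len_s:
        raise ValidationError("basal phase shorter than one window")
    usable_treatment = protocol.treatment_duration_s - protocol.discard_after_treatment_s
    if usable_treatment < window_len_s:
        raise ValidationError("treatment phase (after discard) shorter than one window")

    n_basal = int(math.floor(protocol.basal_duration_s / window_len_s))
    basal = [(i * window_len_s, (i + 1) * window_len_s) for i in range(n_basal)]
    t0 = protocol.basal_duration_s + protocol.discard_after_treatment_s
    n_treat = int(math.floor(usable_treatment / window_len_s))
    treatment = [(t0 + i * window_len_s, t0 + (i + 1) * window_len_s) for i in range(n_treat)]

    def _mid_index(wins: list[tuple[float, float]], midpoint: float, offset: int) -> int:
        for i, (s, e) in enumerate(wins):
            if s <= midpoint < e:
                return offset + i
        # midpoint falls in the discard interval or past the tiling: nearest window
        dists = [min(abs(midpoint - s), abs(midpoint - e)) for s, e in wins]
        return offset + int(np.argmin(dists))

    key = {
        "basal": {
            "start": 0,
            "middle": _mid_index(basal, protocol.basal_duration_s / 2, 0),
            "end": n_basal - 1,
        },
        "treatment": {
            "start": n_basal,
            "middle": _mid_index(
                treatment,
                protocol.basal_duration_s + protocol.treatment_duration_s / 2,
                n_basal,
            ),
            "end": n_basal + n_treat - 1,
        },
    }
    return AnalysisWindows(basal=basal, treatment=treatment, key=key, window_len_s=window_len_s)


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    normal_a: bool
    normal_b: bool
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _ks_normal(x: np.ndarray, alpha: float) -> bool:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return False
    _, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return p > alpha


def compare_groups(
    a: Any, b: Any, alpha: float = 0.05, test: str = "auto"
) -> GroupComparison:
    """KS-normality-gated two-sample comparison.

    Both samples need n >= 3. With ``test="auto"`` the t-test is used when
    both samples pass the KS normality check, otherwise a two-sided
    Mann-Whitney (exact for small tie-free samples, tie-corrected normal
    approximation above). ``test`` may force ``"mannwhitney"`` or
    ``"ttest"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValidationError("compare_groups needs n >= 3 per sample")
    normal_a = _ks_normal(a, alpha)
    normal_b = _ks_normal(b, alpha)
    if test == "ttest" or (test == "auto" and normal_a and normal_b):
        stat, p = stats.ttest_ind(a, b)
        name = "t-test"
    elif test in ("auto", "mannwhitney"):
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        if not has_ties and max(a.size, b.size) <= 8:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        else:
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=False
            )
        stat, p = res.statistic, res.pvalue
        name = "mann-whitney"
    else:
        raise ValidationError("test must be auto, mannwhitney or ttest")
    return GroupComparison(
        test_name=name,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        normal_a=normal_a,
        normal_b=normal_b,
        alpha=alpha,
    )


def default_config() -> dict:
    """Full-scale protocol configuration with every default parameter."""
    return {
        "seed": 0,
        "simulation": {
            "n_channels": 59,
            "arm": "treated",  # "treated" | "control"
            "protocol": asdict(ProtocolSpec()),
            "basal_regime": asdict(sleep_like()),
            "treated_regime": asdict(cch_like()),
            "segment_s": 60.0,
        },
        "windows": {"window_len_s": 3600.0},
        "bursts": {"max_isi_ms": 100.0, "min_spikes_per_burst": 3},
        "metrics": {"bi_bin_s": 1.0},
        "detection": {
            "hp_cutoff_hz": 300.0,
            "hp_order": 2,
            "threshold_factor": 5.0,
            "dead_time_ms": 2.0,
        },
        "sttc": {
            "dt_s": 0.05,
            "active_mfr_min": 0.01,
            "top_n": 100,
            "decrease_threshold_pct": 20.0,
        },
        "lfp": {
            "enabled": False,
            "seconds_per_window": 30.0,
            "n_channels": 4,
            "noise_sigma_uV": 5.0,
            "welch": {"window_s": 5.0, "overlap": 0.5, "dft_points": 8192,
                      "target_fs_hz": 1000.0},
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def _network_burst_times(spikes: SpikeTrainSet) -> np.ndarray:
    """Crude network-burst event times from pooled spikes (25 ms ISI runs)."""
    pooled = spikes.pooled()
    events = []
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and pooled[j + 1] - pooled[j] <= 0.025:
            j += 1
        if j - i + 1 >= 5:
            events.append(0.5 * (pooled[i] + pooled[j]))
        i = j + 1
    return np.asarray(events)


def _mixed_components(mix: float) -> list[tuple[str, float, float]]:
    out = []
    for (band, freq, a_sleep), (_, _, a_cch) in zip(
        SLEEP_LFP_COMPONENTS, CCH_LFP_COMPONENTS
    ):
        out.append((band, freq, (1.0 - mix) * a_sleep + mix * a_cch))
    return out


def run_experiment(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the full analysis workflow and write its result tables.

    ``config`` is a dict (or a YAML file path) overriding
    :func:`default_config`. Outputs in ``out_dir``: ``spikes.csv``,
    ``metrics.csv``, ``edges.csv``, optionally ``psd.csv``, and
    ``manifest.json``. Identical config produces byte-identical tables.
    Returns a summary dict (windows, STTC threshold, key comparisons).
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge(default_config(), config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    with _stage("simulate"):
        sim = cfg["simulation"]
        protocol = ProtocolSpec(**sim["protocol"])
        basal_params = RegimeParams(**sim["basal_regime"])
        treated_params = RegimeParams(**sim["treated_regime"])
        if sim["arm"] == "control":
            protocol = ProtocolSpec(**{**asdict(protocol), "desync_depth": 0.0})
        elif sim["arm"] != "treated":
            raise ValidationError("simulation.arm must be 'treated' or 'control'")
        result: ExperimentResult = generate_experiment(
            protocol,
            basal_params,
            treated_params,
            seed,
            n_channels=int(sim["n_channels"]),
            segment_s=float(sim["segment_s"]),
        )
        spikes = result.combined()
        write_spike_trains(spikes, out_dir / "spikes.csv")

    with _stage("windows"):
        windows = make_windows(protocol, float(cfg["windows"]["window_len_s"]))

    with _stage("metrics"):
        bparams = mua.BurstParams(
            max_isi_ms=float(cfg["bursts"]["max_isi_ms"]),
            min_spikes_per_burst=int(cfg["bursts"]["min_spikes_per_burst"]),
        )
        bursts = mua.detect_bursts_all(spikes, bparams)
        metrics = mua.compute_metrics(
            spikes, bursts, windows.all, bin_s=float(cfg["metrics"]["bi_bin_s"])
        )
        metrics = mua.normalize_to_basal(metrics, windows.basal_indices)
        write_metrics(metrics, out_dir / "metrics.csv")

    with _stage("sttc"):
        sttc_params = conn.SttcParams(
            dt_s=float(cfg["sttc"]["dt_s"]),
            active_mfr_min=float(cfg["sttc"]["active_mfr_min"]),
            window_len_s=float(cfg["windows"]["window_len_s"]),
            top_n=int(cfg["sttc"]["top_n"]),
            decrease_threshold_pct=float(cfg["sttc"]["decrease_threshold_pct"]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrices = [
                conn.sttc_matrix(spikes, sttc_params, w) for w in windows.all
            ]
            edge_set = conn.select_top_edges(
                [matrices[i] for i in windows.basal_indices], sttc_params.top_n
            )
            for wi, m in enumerate(matrices):
                conn.attach_window(edge_set, wi, m)
            basal_thr, thr_fallback = conn.basal_variation_threshold(
                edge_set, windows.basal_indices, sttc_params.decrease_threshold_pct
            )
        decreases = {}
        for wi in windows.treatment_indices:
            frac, _ = conn.edge_decreases(
                edge_set, wi, sttc_params.decrease_threshold_pct
            )
            decreases[wi] = frac
        deleted_fraction = conn.deleted_edges(edge_set, windows.treatment_indices)
        edge_set.to_frame().to_csv(
            out_dir / "edges.csv", index=False, float_format="%.9g", na_rep=""
        )

    psd_table = None
    if cfg["lfp"]["enabled"]:
        with _stage("lfp"):
            lcfg = cfg["lfp"]
            welch = lfp_mod.WelchParams(**lcfg["welch"])
            seg_s = float(lcfg["seconds_per_window"])
            lfp_channels = spikes.channels[: int(lcfg["n_channels"])]
            rng = np.random.default_rng(seed + 1)
            tables = []
            key_windows = sorted(
                {idx for phase in windows.key.values() for idx in phase.values()}
            )
            t_treat0 = protocol.basal_duration_s
            for wi in key_windows:
                start, end = windows.all[wi]
                seg_end = min(start + seg_s, end)
                seg = spikes.window(start, seg_end)
                seg = SpikeTrainSet(
                    trains={ch: seg.trains[ch] for ch in lfp_channels},
                    t_start_s=seg.t_start_s,
                    t_end_s=seg.t_end_s,
                )
                u = start - t_treat0
                if u < 0 or math.isinf(protocol.recovery_tau_s):
                    mix = 0.0 if u < 0 else protocol.desync_depth
                else:
                    mix = protocol.desync_depth * math.exp(-u / protocol.recovery_tau_s)
                raw = generate_raw(
                    seg,
                    _mixed_components(mix),
                    noise_sigma_uV=float(lcfg["noise_sigma_uV"]),
                    seed=int(rng.integers(2**31)),
                    envelope_times=_network_burst_times(seg),
                )
                dec = lfp_mod.antialias_decimate(raw, welch.target_fs_hz)
                table = lfp_mod.psd_summary(dec, [(start, seg_end)], welch)
                table["window_index"] = wi
                tables.append(table)
            psd_table = pd.concat(tables, ignore_index=True)
            write_band_powers(psd_table, out_dir / "psd.csv")

    with _stage("report"):
        manifest = {
            "version": __version__,
            "config": cfg,
            "generator_manifest": result.manifest,
            "windows": {
                "basal": windows.basal,
                "treatment": windows.treatment,
                "key": windows.key,
            },
            "sttc_basal_variation_threshold_pct": basal_thr,
            "sttc_threshold_fallback": thr_fallback,
            "sttc_decrease_fraction_per_window": decreases,
            "sttc_deleted_fraction": deleted_fraction,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))

    return {
        "windows": windows,
        "spikes": spikes,
        "metrics": metrics,
        "edge_set": edge_set,
        "decreases": decreases,
        "deleted_fraction": deleted_fraction,
        "basal_variation_threshold_pct": basal_thr,
        "psd": psd_table,
        "manifest": manifest,
    }


def load_spikes_input(path: str | Path, detection: mua.DetectionParams | None = None,
                      span: tuple[float, float] | None = None) -> SpikeTrainSet:
    """Load analysis input: a spike CSV directly, or a raw ``.bin`` to detect on."""
    path = Path(path)
    if path.suffix == ".csv":
        return read_spike_trains(path, span=span)
    rec = read_raw_recording(path)
    p = detection or mua.DetectionParams()
    filtered = mua.highpass_filter(rec, p)
    sigma = mua.estimate_noise_sigma(filtered)
    return mua.detect_spikes(
        filtered, p, rec.sampling_rate_hz, rec.channel_ids, rec.t0_s, sigma
    )
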