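import numpy as np
import pytest
from scipy import signal as sps

from oracles import bursts_bruteforce
from measleep import mua
from measleep.io import Burst, BurstList, RawRecording, SpikeTrainSet, ValidationError


def make_rec(x, fs=10000.0, lsb=0.01):
    counts = np.rint(np.atleast_2d(x.T).T / lsb).astype(np.int16)
    return RawRecording(counts, [f"c{i}" for i in range(counts.shape[1])],
                        lsb_uV=lsb, sampling_rate_hz=fs)


class TestHighpassFilter:
    def test_dc_rejection(self):
        rec = make_rec(np.full(20000, 100.0), lsb=0.1)
        out = mua.highpass_filter(rec)
        assert np.abs(out[5000:-5000, 0]).max() < 1e-6

    @pytest.mark.parametrize(
        "freq", [10.0, 500.0],
        ids=["deep-stopband", "near-passband"],
    )
    def test_single_pass_magnitude_matches_closed_form(self, freq):
        # order-2 Butterworth high-pass: |H| = (f/fc)^2 / sqrt(1 + (f/fc)^4)
        p = mua.DetectionParams()
        sos = sps.butter(p.hp_order, p.hp_cutoff_hz, btype="highpass",
                         fs=10000.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=10000.0)
        ratio = (freq / p.hp_cutoff_hz) ** 2
        expected = ratio / np.sqrt(1.0 + ratio**2)
        assert abs(abs(h[0]) - expected) / expected < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_rec(np.zeros(1000), fs=500.0)
        with pytest.raises(ValidationError):
            mua.highpass_filter(rec)


class TestNoiseSigma:
    def test_gaussian_recovery(self, rng):
        x = rng.normal(0.0, 4.0, size=(100000, 1))
        est = mua.estimate_noise_sigma(x)[0]
        assert abs(est - 4.0) / 4.0 < 0.03

    def test_robust_to_sparse_spikes(self, rng):
        x = rng.normal(0.0, 4.0, size=100000)
        # 1 Hz of -50 uV deflections over 10 s at 10 kHz: ~10 contaminated points
        idx = rng.choice(100000, size=10, replace=False)
        x[idx] = -50.0
        est = mua.estimate_noise_sigma(x.reshape(-1, 1))[0]
        assert abs(est - 4.0) / 4.0 < 0.05

    def test_all_zero_flagged(self):
        with pytest.warns(UserWarning):
            est = mua.estimate_noise_sigma(np.zeros((1000, 1)))
        assert est[0] == 0.0


class TestDetectSpikes:
    def test_threshold_is_k_sigma(self):
        # sigma 4, k 5: a -21 uV dip crosses the -20 uV threshold, -19 does not
        fs = 10000.0
        x = np.zeros((2000, 1))
        x[500, 0] = -21.0
        x[1500, 0] = -19.0
        p = mua.DetectionParams()
        out = mua.detect_spikes(x, p, fs, ["c0"], sigma_n=np.array([4.0]))
        np.testing.assert_allclose(out.trains["c0"], [0.05])

    def test_all_zero_signal_no_spikes(self):
        out = mua.detect_spikes(
            np.zeros((1000, 1)), mua.DetectionParams(), 10000.0, ["c0"],
            sigma_n=np.array([1.0]),
        )
        assert out.n_spikes == 0

    def test_dead_time_suppresses_retrigger(self):
        fs = 10000.0
        x = np.zeros((1000, 1))
        x[100, 0] = -30.0
        x[110, 0] = -40.0  # within 2 ms dead time of the first crossing
        x[200, 0] = -30.0  # beyond dead time
        p = mua.DetectionParams()
        out = mua.detect_spikes(x, p, fs, ["c0"], sigma_n=np.array([4.0]))
        # timestamp of the first spike sits at the extremum within the dead time
        np.testing.assert_allclose(out.trains["c0"], [0.011, 0.020])

    def test_false_positive_rate_on_pure_noise(self, rng):
        x = rng.normal(0.0, 5.0, size=(100000, 1))  # 10 s at 10 kHz
        p = mua.DetectionParams()
        out = mua.detect_spikes(x, p, 10000.0, ["c0"],
                                sigma_n=mua.estimate_noise_sigma(x))
        assert out.n_spikes <= 2  # <= 0.2 false positives per second


class TestDetectBursts:
    def test_two_bursts(self):
        train = np.array([0.0, 0.05, 0.10, 0.15, 1.0, 1.05, 1.10])
        bursts = mua.detect_bursts(train, mua.BurstParams(), "e1")
        assert [(b.start_s, b.end_s, b.n_spikes) for b in bursts] == [
            (0.0, 0.15, 4),
            (1.0, 1.10, 3),
        ]

    def test_sparse_spikes_no_bursts(self):
        train = np.arange(0.0, 5.0, 0.5)
        assert mua.detect_bursts(train, mua.BurstParams()) == []

    def test_short_run_rejected(self):
        assert mua.detect_bursts(np.array([0.0, 0.05]), mua.BurstParams()) == []

    @pytest.mark.parametrize("max_isi_ms", [50.0, 100.0, 200.0])
    @pytest.mark.parametrize("min_spikes", [2, 3, 5])
    def test_matches_bruteforce_oracle(self, rng, max_isi_ms, min_spikes):
        p = mua.BurstParams(max_isi_ms=max_isi_ms, min_spikes_per_burst=min_spikes)
        for _ in range(60):
            n = int(rng.integers(0, 51))
            ts = np.sort(rng.uniform(0, 5, size=n))
            ts = ts[np.r_[True, np.diff(ts) > 1e-6]] if n else ts
            got = [(b.start_s, b.end_s, b.n_spikes)
                   for b in mua.detect_bursts(ts, p)]
            expected = [(float(s), float(e), int(n))
                        for s, e, n in bursts_bruteforce(ts, max_isi_ms / 1000.0,
                                                         min_spikes)]
            assert got == expected


class TestMetrics:
    def test_mfr_basic(self):
        sts = SpikeTrainSet({"a": np.linspace(0.05, 9.05, 10),
                             "b": np.linspace(0.02, 9.72, 30)}, 0.0, 10.0)
        per_ch, net = mua.mean_firing_rate(sts, (0.0, 10.0))
        assert per_ch["a"] == 1.0
        assert per_ch["b"] == 3.0
        assert net == 2.0

    def test_mfr_empty_train_zero(self):
        sts = SpikeTrainSet({"a": np.empty(0)}, 0.0, 10.0)
        per_ch, net = mua.mean_firing_rate(sts, (0.0, 10.0))
        assert per_ch["a"] == 0.0 and net == 0.0

    def test_mfr_zero_length_window(self, small_spikes):
        with pytest.raises(ValidationError):
            mua.mean_firing_rate(small_spikes, (1.0, 1.0))

    def test_ibr_extremes_and_partial(self):
        ts = np.array([0.0, 0.05, 0.10, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        sts = SpikeTrainSet({"a": ts}, 0.0, 10.0)
        bursts = BurstList([Burst("a", 0.0, 0.10, 3)])
        assert mua.inverse_burst_ratio(sts, bursts, (0.0, 10.0)) == 70.0
        all_in = BurstList([Burst("a", 0.0, 7.0, 10)])
        assert mua.inverse_burst_ratio(sts, all_in, (0.0, 10.0)) == 0.0
        assert mua.inverse_burst_ratio(sts, BurstList([]), (0.0, 10.0)) == 100.0

    def test_ibr_no_spikes_is_nan(self):
        sts = SpikeTrainSet({"a": np.empty(0)}, 0.0, 10.0)
        with pytest.warns(UserWarning):
            assert np.isnan(mua.inverse_burst_ratio(sts, BurstList([]), (0.0, 10.0)))

    def test_ibr_complements_in_burst_percentage(self, rng):
        ts = np.sort(rng.uniform(0, 60, 500))
        ts = ts[np.r_[True, np.diff(ts) > 1e-6]]
        sts = SpikeTrainSet({"a": ts}, 0.0, 60.0)
        bursts = mua.detect_bursts_all(sts)
        ibr = mua.inverse_burst_ratio(sts, bursts, (0.0, 60.0))
        in_burst = sum(b.n_spikes for b in bursts.bursts)
        assert ibr + 100.0 * in_burst / ts.size == pytest.approx(100.0)

    def test_bi_all_in_one_bin(self):
        ts = 5.0 + np.linspace(0.0, 0.5, 40)
        sts = SpikeTrainSet({"a": ts}, 0.0, 100.0)
        assert mua.burstiness_index(sts, (0.0, 100.0)) == 1.0

    def test_bi_uniform_zero(self):
        # one spike per bin: every bin equally populated -> f15 = 0.15 -> BI 0
        ts = np.arange(100) + 0.5
        sts = SpikeTrainSet({"a": ts}, 0.0, 100.0)
        assert mua.burstiness_index(sts, (0.0, 100.0)) == 0.0

    def test_bi_ten_bins_single_loaded_bin(self):
        # counts [10,0,...,0]: top ceil(1.5)=2 bins hold everything -> BI = 1
        ts = 0.05 + np.arange(10) * 0.01
        sts = SpikeTrainSet({"a": ts}, 0.0, 10.0)
        assert mua.burstiness_index(sts, (0.0, 10.0)) == 1.0

    def test_bi_translation_invariance_aligned_bins(self, rng):
        ts = np.sort(rng.uniform(0, 50, 300))
        ts = ts[np.r_[True, np.diff(ts) > 1e-6]]
        a = SpikeTrainSet({"x": ts}, 0.0, 60.0)
        b = SpikeTrainSet({"x": ts + 7.0}, 7.0, 67.0)
        bi_a = mua.burstiness_index(a, (0.0, 60.0))
        bi_b = mua.burstiness_index(b, (7.0, 67.0))
        assert bi_a == pytest.approx(bi_b)

    def test_bi_no_spikes_nan(self):
        sts = SpikeTrainSet({"a": np.empty(0)}, 0.0, 10.0)
        with pytest.warns(UserWarning):
            assert np.isnan(mua.burstiness_index(sts, (0.0, 10.0)))


class TestPercentChangeAndNormalization:
    @pytest.mark.parametrize("start,end,expected", [(2, 3, 50.0), (4, 1, -75.0),
                                                    (7.3, 7.3, 0.0)])
    def test_percent_change(self, start, end, expected):
        assert mua.percent_change(start, end) == pytest.approx(expected)

    def test_percent_change_zero_start_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(mua.percent_change(0.0, 1.0))

    def test_normalize_to_basal(self):
        import pandas as pd

        rows = [
            (0, 0.0, 10.0, "network", "MFR", 2.0, np.nan),
            (1, 10.0, 10.0, "network", "MFR", 3.0, np.nan),
            (0, 0.0, 10.0, "network", "BI", 0.0, np.nan),
            (1, 10.0, 10.0, "network", "BI", 0.4, np.nan),
        ]
        from measleep.io import METRICS_COLUMNS

        metrics = pd.DataFrame(rows, columns=METRICS_COLUMNS)
        out = mua.normalize_to_basal(metrics, [0])
        mfr = out[out.metric_name == "MFR"].normalized_value.to_numpy()
        np.testing.assert_allclose(mfr, [1.0, 1.5])
        # zero basal reference: flagged missing, never silently zero
        bi = out[out.metric_name == "BI"].normalized_value.to_numpy()
        assert np.isnan(bi).all()
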