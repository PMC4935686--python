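import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import sttc_bruteforce, tiling_coverage_grid
from measleep import connectivity as conn
from measleep.connectivity import (
    EdgeSet,
    SttcParams,
    attach_window,
    basal_variation_threshold,
    deleted_edges,
    edge_decreases,
    select_top_edges,
    sttc,
    sttc_matrix,
)
from measleep.io import SpikeTrainSet, ValidationError
from conftest import random_train


class TestSttc:
    def test_identical_trains_give_one(self):
        a = np.array([1.0, 2.0, 3.0, 7.5])
        assert sttc(a, a, 0.05, (0.0, 10.0)) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # A={1}, B={5}, span 10 s, dt=0.1: P=0, T=0.02 -> STTC = -0.02
        v = sttc(np.array([1.0]), np.array([5.0]), 0.1, (0.0, 10.0))
        assert v == pytest.approx(-0.02, abs=1e-12)
        assert v == pytest.approx(sttc_bruteforce([1.0], [5.0], 0.1, (0, 10)))

    def test_empty_train_undefined(self):
        assert np.isnan(sttc(np.empty(0), np.array([1.0]), 0.05, (0.0, 10.0)))

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(200):
            a = random_train(rng)
            b = random_train(rng)
            dt = float(rng.uniform(0.005, 0.5))
            got = sttc(a, b, dt, (0.0, 10.0))
            expected = sttc_bruteforce(a, b, dt, (0.0, 10.0))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_tiling_union_matches_grid_estimate(self, rng):
        from measleep.connectivity import _tiling_fraction

        for _ in range(20):
            ts = random_train(rng)
            dt = float(rng.uniform(0.01, 1.0))
            analytic = _tiling_fraction(ts, dt, 0.0, 10.0)
            grid = tiling_coverage_grid(ts, dt, (0.0, 10.0))
            assert abs(analytic - grid) < 1e-4  # grid resolution 5e-5 s

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_symmetry_and_range(self, data):
        span = (0.0, 10.0)
        strat = st.lists(
            st.floats(0.0, 9.99, allow_nan=False), min_size=1, max_size=25, unique=True
        )
        a = np.sort(np.array(data.draw(strat)))
        b = np.sort(np.array(data.draw(strat)))
        dt = data.draw(st.floats(1e-3, 1.0))
        ab = sttc(a, b, dt, span)
        ba = sttc(b, a, dt, span)
        assert ab == ba
        assert -1.0 <= ab <= 1.0


class TestSttcMatrix:
    def make_set(self):
        return SpikeTrainSet(
            trains={
                "a": np.linspace(0.1, 9.9, 50),
                "b": np.linspace(0.11, 9.91, 50),
                "c": np.linspace(0.5, 9.5, 20),
                "sparse": np.array([5.0]),  # 0.1 spike/s: still active
            },
            t_start_s=0.0,
            t_end_s=10.0,
        )

    def test_pair_count_and_symmetry(self):
        sts = self.make_set()
        mat = sttc_matrix(sts, SttcParams(), (0.0, 10.0))
        defined = np.isfinite(mat.to_numpy())
        # 4 active channels -> C(4,2)=6 pairs, stored symmetrically
        assert defined.sum() == 12
        assert mat.equals(mat.T)

    def test_exact_threshold_excluded(self):
        # a channel at exactly 0.01 spike/s is NOT active (strict >)
        sts = SpikeTrainSet(
            trains={
                "edge": np.array([50.0]),  # 1 spike / 100 s = 0.01
                "a": np.linspace(1, 99, 200),
                "b": np.linspace(1.01, 99.01, 200),
            },
            t_start_s=0.0,
            t_end_s=100.0,
        )
        mat = sttc_matrix(sts, SttcParams(), (0.0, 100.0))
        assert np.isnan(mat.loc["edge"]).all()
        assert np.isfinite(mat.loc["a", "b"])

    def test_fewer_than_two_active_warns_empty(self):
        sts = SpikeTrainSet(trains={"a": np.array([5.0]), "b": np.array([6.0])},
                            t_start_s=0.0, t_end_s=1000.0)
        with pytest.warns(UserWarning):
            mat = sttc_matrix(sts, SttcParams(), (0.0, 1000.0))
        assert np.isnan(mat.to_numpy()).all()


def matrix_from(edges: dict[tuple[str, str], float], channels) -> pd.DataFrame:
    mat = pd.DataFrame(np.nan, index=channels, columns=channels, dtype=float)
    for (a, b), v in edges.items():
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return mat


class TestEdgeSelection:
    channels = ["a", "b", "c", "d"]

    def test_top_n_selection(self):
        mat = matrix_from(
            {("a", "b"): 0.9, ("a", "c"): 0.5, ("a", "d"): 0.8,
             ("b", "c"): 0.3, ("b", "d"): 0.1}, self.channels
        )
        es = select_top_edges([mat], top_n=3)
        assert es.edges == [("a", "b"), ("a", "d"), ("a", "c")]

    def test_fewer_edges_than_top_n(self):
        mat = matrix_from({("a", "b"): 0.9, ("c", "d"): 0.5}, self.channels)
        es = select_top_edges([mat], top_n=100)
        assert len(es.edges) == 2

    def test_tie_break_lexicographic(self):
        mat = matrix_from(
            {("a", "b"): 0.9, ("c", "d"): 0.5, ("b", "c"): 0.5}, self.channels
        )
        es = select_top_edges([mat], top_n=2)
        assert es.edges == [("a", "b"), ("b", "c")]

    def test_reference_is_mean_over_basal_windows(self):
        m1 = matrix_from({("a", "b"): 0.4}, self.channels)
        m2 = matrix_from({("a", "b"): 0.8}, self.channels)
        es = select_top_edges([m1, m2], top_n=10)
        assert es.basal_reference[("a", "b")] == pytest.approx(0.6)

    def test_no_defined_edges_errors(self):
        mat = matrix_from({}, self.channels)
        with pytest.raises(ValidationError):
            select_top_edges([mat], top_n=10)


def tracked_edge_set():
    ref = pd.Series(
        {("a", "b"): 0.5, ("a", "c"): 0.4, ("b", "c"): 0.2},
    )
    ref.index = pd.MultiIndex.from_tuples(ref.index)
    return EdgeSet(basal_reference=ref)


class TestEdgeTracking:
    def test_basal_variation_threshold_zero_sd(self):
        es = tracked_edge_set()
        # every edge drops exactly 5% per basal step: threshold 5 + 3*0 = 5
        es.values[0] = [0.5, 0.4, 0.2]
        es.values[1] = [0.475, 0.38, 0.19]
        thr, fallback = basal_variation_threshold(es, [0, 1])
        assert thr == pytest.approx(5.0)
        assert not fallback

    def test_basal_variation_threshold_direct(self):
        # pooled decreases {2,4,6}%: mean 4, sample SD 2 -> threshold 10
        es = tracked_edge_set()
        es.values[0] = [1.0, 1.0, 1.0]
        es.values[1] = [0.98, 0.96, 0.94]
        thr, fallback = basal_variation_threshold(es, [0, 1])
        assert thr == pytest.approx(10.0)
        assert not fallback

    def test_identical_basal_windows_fall_back(self):
        es = tracked_edge_set()
        es.values[0] = [0.5, 0.4, 0.2]
        es.values[1] = [0.5, 0.4, 0.2]
        thr, fallback = basal_variation_threshold(es, [0, 1])
        assert thr == 20.0 and fallback

    def test_single_basal_window_falls_back(self):
        es = tracked_edge_set()
        es.values[0] = [0.5, 0.4, 0.2]
        with pytest.warns(UserWarning):
            thr, fallback = basal_variation_threshold(es, [0])
        assert thr == 20.0 and fallback

    def test_edge_decreases(self):
        es = tracked_edge_set()
        # basal 0.5 -> 0.3 is a 40% drop (flagged); 0.4 -> 0.36 is 10% (not)
        es.values[0] = [0.3, 0.36, 0.2]
        frac, flagged = edge_decreases(es, 0, threshold_pct=20.0)
        assert flagged == [("a", "b")]
        assert frac == pytest.approx(1 / 3)

    def test_constructed_98_of_100(self, rng):
        pairs = [(f"e{i:03d}", f"f{i:03d}") for i in range(100)]
        ref = pd.Series(0.5, index=pd.MultiIndex.from_tuples(pairs))
        es = EdgeSet(basal_reference=ref)
        vals = np.full(100, 0.3)  # 40% drop
        vals[:2] = 0.49  # 2% drop
        es.values[0] = vals
        frac, flagged = edge_decreases(es, 0, threshold_pct=20.0)
        assert frac == pytest.approx(0.98)
        assert len(flagged) == 98

    def test_deleted_edges(self):
        es = tracked_edge_set()
        es.values[0] = [0.3, np.nan, np.nan]
        es.values[1] = [0.3, 0.2, np.nan]
        # ("b","c") missing in every window -> permanently deleted
        assert deleted_edges(es, [0, 1]) == pytest.approx(1 / 3)
        # all defined in window 1 except one
        es2 = tracked_edge_set()
        es2.values[0] = [0.1, 0.2, 0.3]
        assert deleted_edges(es2, [0]) == 0.0


class TestExport:
    def test_csv_rows_and_determinism(self, tmp_path):
        es = tracked_edge_set()
        es.values[0] = [0.3, np.nan, 0.2]
        grid = {"a": (1, 1), "b": (1, 2), "c": (2, 1)}
        conn.export_connectivity_map(es, 0, grid, tmp_path / "m1.csv",
                                     tmp_path / "m1.png")
        conn.export_connectivity_map(es, 0, grid, tmp_path / "m2.csv")
        c1 = (tmp_path / "m1.csv").read_bytes()
        c2 = (tmp_path / "m2.csv").read_bytes()
        assert c1 == c2
        lines = c1.decode().strip().splitlines()
        assert len(lines) == 4  # header + 3 edges, missing one as empty value
        assert lines[2].endswith(",")
        assert (tmp_path / "m1.png").exists()

    def test_missing_grid_warns_csv_only(self, tmp_path):
        es = tracked_edge_set()
        es.values[0] = [0.3, 0.1, 0.2]
        with pytest.warns(UserWarning):
            conn.export_connectivity_map(es, 0, None, tmp_path / "m.csv",
                                         tmp_path / "m.png")
        assert (tmp_path / "m.csv").exists()
        assert not (tmp_path / "m.png").exists()
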