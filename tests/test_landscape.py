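"""Window grid, QC filters, desert detection and the randomization test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from canroh import landscape
from canroh.landscape import (cohort_frequencies, desert_randomization_test,
                              filter_windows, find_deserts, make_windows,
                              window_indicators)


def seg(*triples, cols=("chrom", "start", "end")):
    return pd.DataFrame(list(triples), columns=list(cols))


class TestMakeWindows:
    def test_truncated_last_window(self):
        g = make_windows({"chr1": 1_200_000}, 500_000)
        assert len(g) == 3
        assert g.loc[2, "end"] - g.loc[2, "start"] == 200_000

    def test_exact_fit(self):
        assert len(make_windows({"chr1": 500_000}, 500_000)) == 1

    def test_length_conservation(self):
        lengths = {"chr1": 1_234_567, "chr2": 765_432}
        g = make_windows(lengths, 500_000)
        assert (g["end"] - g["start"]).sum() == sum(lengths.values())


class TestFilterWindows:
    def test_hand_example(self):
        """Depths [1]*9 + [30]: mean 3.9, sd ~9.17, so only the spike is
        outside mean +- 2 SD."""
        g = make_windows({"chr1": 5_000_000}, 500_000)
        depths = np.array([1.0] * 9 + [30.0])
        out = filter_windows(g, depths)
        assert out["included"].sum() == 9
        assert not out.loc[9, "included"]

    def test_constant_depths_all_included(self):
        g = make_windows({"chr1": 5_000_000}, 500_000)
        out = filter_windows(g, np.full(10, 3.0))
        assert out["included"].all()

    def test_cnv_mask_overrides_depth(self):
        g = make_windows({"chr1": 5_000_000}, 500_000)
        mask = seg(("chr1", 0, 500_000))
        out = filter_windows(g, np.full(10, 3.0), cnv_mask=mask)
        assert not out.loc[0, "included"] and out["included"].sum() == 9

    def test_partial_cnv_overlap_threshold(self):
        g = make_windows({"chr1": 5_000_000}, 500_000)
        mask = seg(("chr1", 0, 100_000))  # 20% of window 0
        out = filter_windows(g, np.full(10, 3.0), cnv_mask=mask)
        assert out.loc[0, "included"]

    def test_all_excluded_rejected(self):
        g = make_windows({"chr1": 1_000_000}, 500_000)
        mask = seg(("chr1", 0, 1_000_000))
        with pytest.raises(ValueError):
            filter_windows(g, np.full(2, 3.0), cnv_mask=mask)


class TestWindowIndicators:
    def test_exact_and_boundary_spanning_segments(self):
        g = make_windows({"chr1": 2_000_000}, 500_000)
        sets = {"a": seg(("chr1", 500_000, 1_000_000)),
                "b": seg(("chr1", 400_000, 600_000))}
        ind = window_indicators(sets, g)
        assert ind.loc["a"].tolist() == [False, True, False, False]
        assert ind.loc["b"].tolist() == [True, True, False, False]

    def test_unknown_chromosome_rejected(self):
        g = make_windows({"chr1": 1_000_000}, 500_000)
        with pytest.raises(ValueError):
            window_indicators({"a": seg(("chrX", 0, 100))}, g)

    def test_no_roh_gives_zero_frequencies(self):
        g = make_windows({"chr1": 1_000_000}, 500_000)
        empty = seg()
        ind = window_indicators({"a": empty, "b": empty}, g)
        labels = pd.DataFrame({"sample": ["a", "b"],
                               "group": ["ancient", "modern"]})
        freqs = cohort_frequencies(ind, labels)
        assert (freqs.to_numpy() == 0).all()


class TestFindDeserts:
    def grid(self):
        g = make_windows({"chr1": 2_000_000}, 500_000)
        g["included"] = True
        return g

    def test_strict_cutoff_boundary(self):
        g = self.grid()
        freqs = pd.DataFrame({
            "freq_ancient": [0.04, 0.05, 0.04, 0.2],
            "freq_modern": [0.049, 0.01, 0.06, 0.2]})
        out = find_deserts(g, freqs, cutoff=0.05)
        assert out["desert"].tolist() == [True, False, False, False]

    def test_excluded_windows_never_deserts(self):
        g = self.grid()
        g.loc[0, "included"] = False
        freqs = pd.DataFrame({"freq_ancient": [0.0] * 4,
                              "freq_modern": [0.0] * 4})
        out = find_deserts(g, freqs)
        assert not out.loc[0, "desert"] and out["desert"].sum() == 3


class TestRandomizationTest:
    def test_p_floor(self):
        """Observed count above every null count: p = 1/(n_perm + 1)."""
        rng = np.random.default_rng(1)
        n_win = 60
        # both cohorts leave the last 30 windows empty -> strong sharing
        occ_a = np.zeros((10, n_win), bool)
        occ_b = np.zeros((10, n_win), bool)
        occ_a[:, :30] = rng.random((10, 30)) < 0.5
        occ_b[:, :30] = rng.random((10, 30)) < 0.5
        res = desert_randomization_test(occ_a, occ_b, n_perm=999, seed=2)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_determinism_and_order_invariance(self):
        rng = np.random.default_rng(3)
        occ_a = rng.random((6, 40)) < 0.2
        occ_b = rng.random((6, 40)) < 0.2
        r1 = desert_randomization_test(occ_a, occ_b, n_perm=99, seed=5)
        r2 = desert_randomization_test(occ_a, occ_b, n_perm=99, seed=5)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)
        shuffled = desert_randomization_test(occ_a[::-1], occ_b, n_perm=99,
                                             seed=5)
        assert shuffled.observed_desert_count == r1.observed_desert_count

    def test_toy_case_matches_exhaustive_enumeration(self):
        """3 windows, 2 samples per cohort, 1 occupied window each: the
        permutation tail probability matches enumeration over all 3^4
        equally likely placements."""
        occ_a = np.array([[1, 0, 0], [1, 0, 0]], bool)
        occ_b = np.array([[1, 0, 0], [0, 1, 0]], bool)
        cutoff = 0.05

        def count(placements):
            fa = np.zeros(3)
            fb = np.zeros(3)
            fa[placements[0]] += 0.5
            fa[placements[1]] += 0.5
            fb[placements[2]] += 0.5
            fb[placements[3]] += 0.5
            return int(((fa < cutoff) & (fb < cutoff)).sum())

        observed = count((0, 0, 0, 1))
        tail = sum(count(p) >= observed
                   for p in itertools.product(range(3), repeat=4))
        exact_p = tail / 3**4
        res = desert_randomization_test(occ_a, occ_b, cutoff=cutoff,
                                        n_perm=100_000, seed=7)
        assert res.observed_desert_count == observed
        assert res.p_value == pytest.approx(exact_p, abs=0.005)

    def test_invalid_inputs_rejected(self):
        occ = np.ones((2, 3), bool)
        with pytest.raises(ValueError):
            desert_randomization_test(occ, occ, n_perm=0)
        with pytest.raises(ValueError):
            desert_randomization_test(occ, np.ones((2, 4), bool), n_perm=9)

    def test_circular_shift_preserves_counts(self):
        rng = np.random.default_rng(9)
        occ = rng.random((5, 30)) < 0.3
        shifted = landscape.circular_shift_null(occ, rng)
        np.testing.assert_array_equal(occ.sum(axis=1), shifted.sum(axis=1))
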