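"""ROH caller: degenerate cases, a naive-scan oracle, and F_ROH arithmetic."""

import numpy as np
import pandas as pd
import pytest

from canroh import roh
from canroh.roh import ROHParams, call_roh, froh, summarize_roh
from canroh.simulate import (SimConfig, simulate_panel,
                             simulate_truth_individual)


def naive_scan(genotypes, positions, params):
    """Independent brute-force reimplementation of the sliding-window scan."""
    m = len(positions)
    W = params.window_snp
    eligible = []
    for j in range(m):
        n_win = n_hit = 0
        for i in range(max(0, j - W + 1), min(j, m - W) + 1):
            win = genotypes[i:i + W]
            het = int(np.sum(win == 1))
            mis = int(np.sum(win == -1))
            n_win += 1
            if het <= params.window_het and mis <= params.window_missing:
                n_hit += 1
        eligible.append(n_win > 0 and n_hit >= params.hit_threshold * n_win)
    segments = []
    j = 0
    while j < m:
        if not eligible[j]:
            j += 1
            continue
        k = j
        while (k + 1 < m and eligible[k + 1]
               and positions[k + 1] - positions[k] <= params.max_gap * 1000):
            k += 1
        n_snps = k - j + 1
        length = positions[k] - positions[j] + 1
        if (n_snps >= params.min_snp and length >= params.min_kb * 1000
                and length / n_snps <= params.min_density * 1000):
            segments.append((int(positions[j]), int(positions[k]) + 1,
                             n_snps))
        j = k + 1
    return segments


def sites_for(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions,
                                                           dtype=np.int64)})


class TestCallRoh:
    def test_all_het_yields_nothing(self):
        pos = np.arange(5000) * 1000
        segs = call_roh(np.ones(5000, dtype=np.int8), sites_for(pos))
        assert len(segs) == 0

    def test_fully_homozygous_chromosome_is_one_segment(self):
        """5 Mb of evenly spaced homozygous SNPs: one segment from first
        to last SNP."""
        pos = np.arange(5000) * 1000
        segs = call_roh(np.zeros(5000, dtype=np.int8), sites_for(pos))
        assert len(segs) == 1
        assert segs.loc[0, "start"] == 0
        assert segs.loc[0, "end"] == pos[-1] + 1
        assert segs.loc[0, "n_snps"] == 5000

    def test_unsorted_input_rejected(self):
        pos = np.array([100, 50, 200])
        with pytest.raises(ValueError):
            call_roh(np.zeros(3, dtype=np.int8), sites_for(pos))

    def test_planted_tract_recovered_within_window_span(self):
        """A 3 Mb autozygous tract in 20 Mb is called with endpoints within
        one window-span of truth."""
        cfg = SimConfig(n_chromosomes=1, chromosome_length=20_000_000,
                        n_sites=20_000, seed=41)
        sites, _ = simulate_panel(cfg)

        def tract(rng):
            return 3_000_000

        tr = simulate_truth_individual(sites, 3 / 20, cfg,
                                       tract_length_sampler=tract)
        assert len(tr.truth_roh) == 1
        segs = call_roh(tr.genotypes, sites)
        assert len(segs) >= 1
        true_s = tr.truth_roh.loc[0, "start"]
        true_e = tr.truth_roh.loc[0, "end"]
        # window span ~ window_snp / SNP density
        span = 50 / (len(sites) / cfg.chromosome_length)
        best = segs.iloc[((segs["start"] - true_s).abs()).argmin()]
        assert abs(best["start"] - true_s) <= span
        assert abs(best["end"] - true_e) <= span

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_naive_scan(self, trial):
        """Exact equality with the brute-force scan on random chromosomes."""
        rng = np.random.default_rng(100 + trial)
        m = 200
        pos = np.sort(rng.choice(2_000_000, m, replace=False))
        geno = rng.choice([0, 1, 2, -1], size=m,
                          p=[0.55, 0.15, 0.25, 0.05]).astype(np.int8)
        params = ROHParams(window_snp=10, window_het=1, window_missing=2,
                           hit_threshold=0.05, min_snp=10, min_kb=10,
                           min_density=100, max_gap=200)
        got = call_roh(geno, sites_for(pos), params)
        expected = naive_scan(geno, pos, params)
        assert [(s, e, n) for s, e, n in
                got[["start", "end", "n_snps"]].to_numpy()] == expected

    def test_chromosome_processing_order_invariance(self):
        rng = np.random.default_rng(43)
        pos = np.sort(rng.choice(5_000_000, 500, replace=False))
        geno = rng.choice([0, 1, 2], size=500,
                          p=[0.6, 0.1, 0.3]).astype(np.int8)
        params = ROHParams(window_snp=10, min_snp=10, min_kb=10,
                           min_density=100, max_gap=500)
        a = call_roh(geno, sites_for(pos, "chr1"), params)
        b = call_roh(geno, sites_for(pos, "chr2"), params)
        both = call_roh(np.concatenate([geno, geno]),
                        pd.concat([sites_for(pos, "chr1"),
                                   sites_for(pos, "chr2")],
                                  ignore_index=True), params)
        assert len(both) == len(a) + len(b)
        np.testing.assert_array_equal(
            both[both["chrom"] == "chr1"][["start", "end"]].to_numpy(),
            a[["start", "end"]].to_numpy())


class TestFroh:
    def test_empty_set_is_zero(self):
        assert froh(pd.DataFrame(columns=["chrom", "start", "end"]),
                    100) == 0.0

    def test_class_arithmetic(self):
        segs = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "start": [0, 2_000_000],
                             "end": [1_000_000, 2_500_000]})
        genome = 100_000_000
        assert froh(segs, genome) == pytest.approx(0.015)
        assert froh(segs, genome, "short") == pytest.approx(0.015)
        assert froh(segs, genome, "long") == 0.0

    def test_partition_identity(self, rng):
        lengths = rng.integers(100_000, 5_000_000, 30)
        starts = np.cumsum(lengths + 50_000)
        segs = pd.DataFrame({"chrom": "chr1", "start": starts,
                             "end": starts + lengths})
        g = 500_000_000
        assert froh(segs, g) == pytest.approx(
            froh(segs, g, "short") + froh(segs, g, "long"))

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            froh(pd.DataFrame(columns=["chrom", "start", "end"]), 0)


class TestSummarize:
    def test_empty(self):
        out = summarize_roh(pd.DataFrame(columns=["chrom", "start", "end"]))
        assert (out["n_segments"], out["total_bp"], out["max_bp"]) == (0, 0, 0)

    def test_counts_and_high_inbreeding_flag(self):
        segs = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "start": [0, 5_000_000],
                             "end": [2_000_000, 8_000_000]})
        out = summarize_roh(segs, autosome_length_total=100_000_000)
        assert out["n_segments"] == 2
        assert out["total_bp"] == 5_000_000
        assert out["max_bp"] == 3_000_000
        assert not out["highly_inbred"]
        # a sample with 26% of its genome in ROH is flagged (threshold 0.1)
        out26 = summarize_roh(segs, autosome_length_total=19_000_000)
        assert out26["froh_all"] > 0.1 and out26["highly_inbred"]
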