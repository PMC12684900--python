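"""Synthetic-data generators: determinism, stated distributions, ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from canroh import landscape, roh
from canroh.simulate import (SimConfig, error_probability,
                             simulate_cohorts, simulate_imputed_calls,
                             simulate_panel, simulate_pseudohaploid,
                             simulate_truth_individual,
                             simulate_window_depths)
from canroh.variant_io import MISSING


class TestPanel:
    def test_determinism(self):
        cfg = SimConfig(n_sites=1000, seed=1)
        s1, g1 = simulate_panel(cfg)
        s2, g2 = simulate_panel(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        np.testing.assert_array_equal(g1, g2)

    def test_maf_range_and_sorting(self):
        cfg = SimConfig(n_sites=1000, seed=2)
        sites, geno = simulate_panel(cfg)
        assert len(sites) == 1000
        assert ((sites["maf"] > 0) & (sites["maf"] <= 0.5)).all()
        for _, sub in sites.groupby("chrom"):
            assert (np.diff(sub["pos"]) > 0).all()
        assert geno.shape == (cfg.n_ref, 1000)
        assert set(np.unique(geno)) <= {0, 1, 2}

    def test_transversion_fraction(self):
        """With 2/3 transitions, observed transversion fraction is
        ~1/3 +- 3% at 1e5 sites (binomial)."""
        cfg = SimConfig(n_sites=100_000, n_chromosomes=4,
                        chromosome_length=50_000_000, seed=3)
        sites, _ = simulate_panel(cfg)
        assert sites["transversion"].mean() == pytest.approx(1 / 3, abs=0.03)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimConfig(error_base=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_sites=0)


class TestTruthIndividual:
    def test_f_zero_is_outbred(self, small_config, small_panel):
        sites, _ = small_panel
        tr = simulate_truth_individual(sites, 0.0, small_config)
        assert len(tr.truth_roh) == 0
        het = (tr.genotypes == 1).mean()
        p = sites["alt_af"].to_numpy()
        assert het == pytest.approx((2 * p * (1 - p)).mean(), abs=0.02)

    def test_tract_total_near_target(self):
        """f=0.14 on a 100 Mb genome: tract total within 14 Mb +- 1.4 Mb."""
        cfg = SimConfig(n_chromosomes=2, chromosome_length=50_000_000,
                        n_sites=5000, seed=5)
        tr = simulate_truth_individual(simulate_panel(cfg)[0], 0.14, cfg)
        total = (tr.truth_roh["end"] - tr.truth_roh["start"]).sum()
        assert abs(total - 14e6) <= 1.4e6

    def test_tracts_are_homozygous_sorted_disjoint(self, small_config,
                                                   small_panel, small_truth):
        sites, _ = small_panel
        tr = small_truth
        pos = sites["pos"].to_numpy()
        chrom = sites["chrom"].to_numpy()
        in_tract = np.zeros(len(sites), dtype=bool)
        for c, s, e in tr.truth_roh[["chrom", "start", "end"]] \
                .itertuples(index=False):
            in_tract |= (chrom == c) & (pos >= s) & (pos < e)
        assert not np.any(tr.genotypes[in_tract] == 1)
        for _, sub in tr.truth_roh.groupby("chrom"):
            starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()
        assert (tr.truth_roh["end"]
                <= small_config.chromosome_length).all()

    def test_f_out_of_range(self, small_config, small_panel):
        with pytest.raises(ValueError):
            simulate_truth_individual(small_panel[0], 1.0, small_config)


class TestImputedCalls:
    def test_zero_error_is_exact(self, small_panel):
        cfg = SimConfig(n_sites=4_000, n_chromosomes=2,
                        chromosome_length=20_000_000, n_ref=40,
                        error_base=0.0, seed=11)
        sites, _ = simulate_panel(cfg)
        tr = simulate_truth_individual(sites, 0.1, cfg)
        cs = simulate_imputed_calls(tr, sites, cfg)
        np.testing.assert_array_equal(cs.genotypes[0], tr.genotypes)
        assert np.all(cs.info == 1.0)

    def test_gp_rows_sum_to_one_and_dosage_consistent(self, small_config,
                                                      small_panel,
                                                      small_truth):
        sites, _ = small_panel
        cs = simulate_imputed_calls(small_truth, sites, small_config)
        np.testing.assert_allclose(cs.gp.sum(axis=2), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            cs.dosage, cs.gp[:, :, 1] + 2 * cs.gp[:, :, 2], atol=1e-9)
        assert np.all((cs.dosage >= 0) & (cs.dosage <= 2))
        # argmax of GP equals the reported genotype
        np.testing.assert_array_equal(cs.gp[0].argmax(axis=1),
                                      cs.genotypes[0])

    def test_error_monotone_in_coverage(self):
        """Mean genotype error strictly lower at 2x than 0.1x, same seeds."""
        cfg = SimConfig(n_sites=100_000, n_chromosomes=4,
                        chromosome_length=50_000_000,
                        error_base=0.1, coverage_scale=0.5, seed=6)
        sites, _ = simulate_panel(cfg)
        tr = simulate_truth_individual(sites, 0.1, cfg)
        errs = {}
        for cov in (0.1, 2.0):
            cs = simulate_imputed_calls(
                tr, sites, dataclasses.replace(cfg, coverage=cov))
            errs[cov] = (cs.genotypes[0] != tr.genotypes).mean()
        assert errs[2.0] < errs[0.1]

    def test_rare_sites_err_more(self):
        cfg = SimConfig(n_sites=100_000, n_chromosomes=4,
                        chromosome_length=50_000_000,
                        rare_penalty=1.0, coverage=0.5, seed=7)
        sites, _ = simulate_panel(cfg)
        tr = simulate_truth_individual(sites, 0.0, cfg)
        cs = simulate_imputed_calls(tr, sites, cfg)
        err = cs.genotypes[0] != tr.genotypes
        rare = sites["maf"].to_numpy() < 0.05
        assert err[rare].mean() > err[~rare].mean()

    def test_error_probability_shape(self):
        cfg = SimConfig(error_base=0.1, coverage_scale=0.5,
                        rare_penalty=2.0, coverage=0.5)
        maf = np.array([0.01, 0.3])
        eps = error_probability(cfg, maf)
        assert eps[0] > eps[1]
        assert np.all((eps >= 0) & (eps <= 0.45))


class TestPseudohaploid:
    def test_missing_fraction_closed_form(self, small_config, small_panel,
                                          small_truth):
        """At coverage 0.05, the no-read probability is e^-0.05 ~ 0.951."""
        cfg = SimConfig(n_sites=100_000, n_chromosomes=4,
                        chromosome_length=50_000_000, seed=8)
        sites, _ = simulate_panel(cfg)
        tr = simulate_truth_individual(sites, 0.0, cfg)
        cs = simulate_pseudohaploid(tr, sites, 0.05, cfg.seed)
        missing = (cs.genotypes[0] == MISSING).mean()
        assert missing == pytest.approx(np.exp(-0.05), abs=0.01)

    def test_het_sites_split_evenly(self):
        cfg = SimConfig(n_sites=100_000, n_chromosomes=4,
                        chromosome_length=50_000_000, seed=9)
        sites, _ = simulate_panel(cfg)
        tr = simulate_truth_individual(sites, 0.0, cfg)
        c = 1.0
        cs = simulate_pseudohaploid(tr, sites, c, cfg.seed)
        het = tr.genotypes == 1
        calls = cs.genotypes[0][het]
        p_each = (1 - np.exp(-c)) / 2
        assert (calls == 0).mean() == pytest.approx(p_each, abs=0.01)
        assert (calls == 2).mean() == pytest.approx(p_each, abs=0.01)
        assert set(np.unique(calls)) <= {MISSING, 0, 2}

    def test_high_coverage_recovers_homozygotes(self, small_panel):
        cfg = SimConfig(n_sites=4_000, n_chromosomes=2,
                        chromosome_length=20_000_000, n_ref=40, seed=11)
        sites, _ = simulate_panel(cfg)
        tr = simulate_truth_individual(sites, 0.0, cfg)
        cs = simulate_pseudohaploid(tr, sites, 50.0, cfg.seed)
        hom = tr.genotypes != 1
        np.testing.assert_array_equal(cs.genotypes[0][hom],
                                      tr.genotypes[hom])


class TestCohorts:
    def setup_grid(self):
        return landscape.make_windows({"chr1": 25_000_000,
                                       "chr2": 25_000_000}, 500_000)

    def test_desert_windows_stay_empty(self):
        grid = self.setup_grid()
        deserts = [10, 11, 60, 61]
        segs, labels = simulate_cohorts(8, 8, 0.05, 0.25, grid,
                                        desert_windows=deserts, seed=12)
        ind = landscape.window_indicators(roh.roh_by_sample(segs), grid)
        assert not ind.to_numpy()[:, deserts].any()

    def test_modern_more_inbred_than_ancient(self):
        grid = self.setup_grid()
        segs, labels = simulate_cohorts(8, 8, 0.05, 0.30, grid, seed=13)
        genome = 50_000_000
        froh = {g: np.mean([roh.froh(s, genome) for name, s
                            in roh.roh_by_sample(segs).items()
                            if name.startswith(g)])
                for g in ("ancient", "modern")}
        assert froh["modern"] > froh["ancient"]

    def test_overlapping_designations_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohorts(2, 2, 0.05, 0.1, self.setup_grid(),
                             hotspot_windows=[1], desert_windows=[1])

    def test_infeasible_desert_coverage_rejected(self):
        grid = self.setup_grid()
        with pytest.raises(ValueError):
            simulate_cohorts(2, 2, 0.3, 0.4, grid,
                             desert_windows=list(range(len(grid) - 2)))

    def test_uniform_occupancy_matches_closed_form(self):
        """One fixed-length tract per sample, no hotspots/deserts: a given
        interior window is occupied with probability (w + t) / (L - t)."""
        L, w, t = 50_000_000, 500_000, 3_000_000
        grid = landscape.make_windows({"chr1": L}, w)
        segs, _ = simulate_cohorts(
            400, 0, t / L, 0.0, grid, seed=14,
            tract_length_sampler=lambda rng: t)
        ind = landscape.window_indicators(roh.roh_by_sample(segs), grid)
        # interior windows only (edge windows have clipped ranges)
        interior = slice(10, len(grid) - 10)
        occ = ind.to_numpy()[:, interior].mean()
        expected = (w + t) / (L - t)
        assert occ == pytest.approx(expected, rel=0.15)


class TestWindowDepths:
    def test_determinism_and_baseline(self):
        grid = landscape.make_windows({"chr1": 50_000_000}, 500_000)
        d1 = simulate_window_depths(grid, 0.0, seed=15)
        d2 = simulate_window_depths(grid, 0.0, seed=15)
        np.testing.assert_array_equal(d1, d2)
        # Normal tail mass: ~95.4% of draws within mean +- 2 sd
        inside = np.abs(d1 - 5.0) <= 2.0
        assert inside.mean() > 0.85

    def test_spikes_flagged_by_qc(self):
        """8x-mean spikes are caught by the mean +- 2 SD filter in >= 95%
        of replicates."""
        grid = landscape.make_windows({"chr1": 50_000_000}, 500_000)
        caught = total = 0
        for seed in range(20):
            d = simulate_window_depths(grid, 0.0, mean_depth=5.0,
                                       sd_depth=1.0, seed=seed)
            spiked = np.random.default_rng(seed).choice(len(d), 3,
                                                        replace=False)
            d[spiked] = 8 * 5.0
            qc = landscape.filter_windows(grid, d)
            caught += (~qc["included"].to_numpy()[spiked]).sum()
            total += len(spiked)
        assert caught / total >= 0.95
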