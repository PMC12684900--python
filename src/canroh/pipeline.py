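"""End-to-end orchestration of the synthetic benchmark and landscape runs.

Two entry points mirror the study's two analysis arms:

* :func:`run_benchmark` — simulate a panel and a truth genome, produce
  imputation-like and pseudohaploid versions over a coverage grid, and
  score them: concordance (r² by MAF bin and INFO cutoff, error rates,
  NRD), ROH recovery against the planted tracts, and weighted PC distance
  to the truth projection.
* :func:`run_landscape` — simulate two cohorts with shared ROH hotspots
  and deserts, apply window QC, estimate windowed prevalence, detect
  deserts, run the randomization significance test, and compare cohort
  F_ROH distributions by rank-sum tests.

Every run is a pure function of (config, seed); outputs are TSV/JSON plus
a manifest recording the package version, seed and a hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

import canroh
from canroh import (cohort_stats, concordance, landscape, pca, roh,
                    roh_benchmark, simulate)
from canroh.simulate import COVERAGE_GRID, SimConfig

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Unknown keys in ``from_dict`` input are rejected so that typos in
    config files fail loudly instead of silently using defaults.
    """

    seed: int = 0
    out_dir: str = "results/run"
    # benchmark arm
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    coverages: tuple = COVERAGE_GRID
    truth_autozygosity: float = 0.15
    info_cutoffs: tuple = concordance.DEFAULT_INFO_CUTOFFS
    n_pcs: int = 6
    roh_params: roh.ROHParams = dataclasses.field(default_factory=roh.ROHParams)
    # landscape arm
    n_ancient: int = 30
    n_modern: int = 30
    froh_ancient: float = 0.05
    froh_modern: float = 0.30
    window_bp: int = landscape.DEFAULT_WINDOW_BP
    n_desert_windows: int = 20
    n_hotspot_windows: int = 20
    desert_cutoff: float = landscape.DEFAULT_DESERT_CUTOFF
    n_perm: int = 999
    depth_outlier_fraction: float = 0.02

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        nested = {"sim": SimConfig, "roh_params": roh.ROHParams}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub_cls in nested.items():
            if key in d and isinstance(d[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(d[key]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown {key} keys: {sorted(sub_unknown)}")
                d[key] = sub_cls(**d[key])
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # output location is not an analysis parameter
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(config: RunConfig, out: Path, stage: str) -> None:
    manifest = {"package": "canroh", "version": canroh.__version__,
                "stage": stage, "seed": config.seed,
                "config_hash": config.config_hash(),
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Benchmark arm
# ---------------------------------------------------------------------------

def benchmark_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Compute the benchmark's result tables in memory (no file output)."""
    base = config.sim
    sites, _panel = simulate.simulate_panel(base)
    truth = simulate.simulate_truth_individual(
        sites, config.truth_autozygosity, base)
    truth_cs = truth.callset(sites, base.chrom_lengths)
    genome = base.genome_length
    assayable = pd.DataFrame(
        [(c, 0, L) for c, L in base.chrom_lengths.items()],
        columns=["chrom", "start", "end"])

    conc_rows, roh_rows, pca_rows = [], [], []
    # PC space from the synthetic panel
    panel_cfg = dataclasses.replace(base, n_pops=2, fst=0.1)
    p_sites, p_geno = simulate.simulate_panel(panel_cfg)
    model, _scores = pca.fit_pca(p_geno, k=config.n_pcs)
    truth_proj = pca.project(truth.genotypes.astype(float), model)

    for ci, cov in enumerate(config.coverages):
        cfg = dataclasses.replace(base, coverage=cov)
        imputed = simulate.simulate_imputed_calls(truth, sites, cfg,
                                                  seed_key=ci)
        pseudo = simulate.simulate_pseudohaploid(
            truth, sites, cov, base.seed, seed_key=ci,
            chrom_lengths=base.chrom_lengths)

        rep = concordance.r2_by_bin(truth_cs, imputed,
                                    info_cutoffs=config.info_cutoffs)
        rep.insert(0, "coverage", cov)
        conc_rows.append(rep)

        for cutoff in config.info_cutoffs:
            if cutoff is None:
                cs = imputed
            else:
                from canroh.variant_io import filter_sites
                cs, _ = filter_sites(imputed, info_min=cutoff)
            called = roh.call_roh(cs.genotypes[0], cs.sites,
                                  config.roh_params)
            scores = roh_benchmark.score_sets(truth.truth_roh, called,
                                              assayable, basis="length")
            scores.update(coverage=cov,
                          info_cutoff=np.nan if cutoff is None else cutoff,
                          froh_called=roh.froh(called, genome),
                          froh_truth=roh.froh(truth.truth_roh, genome))
            roh_rows.append(scores)

        imp_proj = pca.project(
            np.where(imputed.genotypes[0] == -1, np.nan,
                     imputed.genotypes[0]).astype(float), model)
        ph_proj = pca.project(
            np.where(pseudo.genotypes[0] == -1, np.nan,
                     pseudo.genotypes[0]).astype(float), model)
        pca_rows.append({
            "coverage": cov,
            "dist_imputed": pca.weighted_pc_distance(
                imp_proj, truth_proj, model.eigenvalues, k=config.n_pcs),
            "dist_pseudohaploid": pca.weighted_pc_distance(
                ph_proj, truth_proj, model.eigenvalues, k=config.n_pcs),
        })
    return {"concordance": pd.concat(conc_rows, ignore_index=True),
            "roh_benchmark": pd.DataFrame(roh_rows),
            "pc_distance": pd.DataFrame(pca_rows)}


def run_benchmark(config: RunConfig) -> dict:
    """Run the benchmark arm and write TSV/JSON outputs under out_dir."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = benchmark_tables(config)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "coverages": list(config.coverages),
        "r2_overall": tables["concordance"]
        .groupby("coverage")["r2"].mean().to_dict(),
        "mean_nrd": tables["concordance"]
        .groupby("coverage")["nrd"].mean().to_dict(),
        "roh_f1": tables["roh_benchmark"]
        .groupby("coverage")["f1"].mean().to_dict(),
        "pc_distance": tables["pc_distance"]
        .set_index("coverage").to_dict(orient="index"),
    }
    (out / "benchmark_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    _write_manifest(config, out, "benchmark")
    logger.info("benchmark arm finished in %.1fs", time.time() - t0)
    return summary


# ---------------------------------------------------------------------------
# Landscape arm
# ---------------------------------------------------------------------------

def landscape_tables(config: RunConfig) -> dict:
    """Compute the landscape analysis in memory (no file output)."""
    base = config.sim
    grid = landscape.make_windows(base.chrom_lengths, config.window_bp)
    rng = np.random.default_rng(config.seed)
    qc_safe = grid.index.to_numpy()
    chosen = rng.choice(qc_safe,
                        size=config.n_desert_windows + config.n_hotspot_windows,
                        replace=False)
    desert_windows = np.sort(chosen[:config.n_desert_windows])
    hotspot_windows = np.sort(chosen[config.n_desert_windows:])

    segments, labels = simulate.simulate_cohorts(
        config.n_ancient, config.n_modern,
        config.froh_ancient, config.froh_modern,
        grid, hotspot_windows=hotspot_windows,
        desert_windows=desert_windows, seed=config.seed)

    depths = simulate.simulate_window_depths(
        grid, outlier_fraction=config.depth_outlier_fraction,
        seed=config.seed)
    qc = landscape.filter_windows(grid, depths)
    roh_sets = roh.roh_by_sample(segments)
    indicators = landscape.window_indicators(roh_sets, qc)
    freqs = landscape.cohort_frequencies(indicators, labels)
    deserts = landscape.find_deserts(qc, freqs, config.desert_cutoff)

    included = qc["included"].to_numpy()
    anc = labels.loc[labels["group"] == "ancient", "sample"]
    mod = labels.loc[labels["group"] == "modern", "sample"]
    occ_a = indicators.loc[anc].to_numpy()[:, included]
    occ_b = indicators.loc[mod].to_numpy()[:, included]
    test = landscape.desert_randomization_test(
        occ_a, occ_b, cutoff=config.desert_cutoff,
        n_perm=config.n_perm, seed=config.seed)

    genome = base.genome_length
    froh_rows = []
    for sample, segs in roh_sets.items():
        group = labels.set_index("sample").loc[sample, "group"]
        froh_rows.append({
            "sample": sample, "group": group,
            "froh_all": roh.froh(segs, genome),
            "froh_short": roh.froh(segs, genome, "short"),
            "froh_long": roh.froh(segs, genome, "long")})
    froh_table = pd.DataFrame(froh_rows)
    comparison = cohort_stats.compare_groups(
        froh_table, [("modern", "ancient")])
    return {"windows": deserts, "froh": froh_table,
            "comparison": comparison, "test": test,
            "designated_deserts": desert_windows,
            "labels": labels}


def run_landscape(config: RunConfig) -> dict:
    """Run the landscape arm and write TSV/JSON outputs under out_dir."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = landscape_tables(config)
    res["windows"].to_csv(out / "windows.tsv", sep="\t", index=False)
    res["froh"].to_csv(out / "froh.tsv", sep="\t", index=False)
    res["comparison"].to_csv(out / "froh_comparison.tsv", sep="\t",
                             index=False)
    test = res["test"]
    included = res["windows"]["included"]
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_windows": int(len(res["windows"])),
        "n_included": int(included.sum()),
        "n_deserts": int(res["windows"]["desert"].sum()),
        "desert_fraction_of_included":
            float(res["windows"]["desert"].sum() / included.sum()),
        "randomization_p": test.p_value,
        "observed_desert_count": test.observed_desert_count,
        "null_mean_desert_count": float(test.null_counts.mean()),
        "froh_comparison": res["comparison"].to_dict(orient="records"),
    }
    (out / "landscape_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    _write_manifest(config, out, "landscape")
    logger.info("landscape arm finished in %.1fs", time.time() - t0)
    return summary
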