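"""Generate the synthetic study inputs with known ground truth.

Writes, under results/data/: a reference-panel site table and panel
genotypes, one truth genome with planted autozygous tracts (VCF + truth
ROH BED), its imputation-like and pseudohaploid call sets at 0.5x (VCF),
and per-window depths (TSV). Everything downstream of this script reads
only these standard-format files or regenerates data in memory.

Run from the repository root:  python analysis/01_simulate_inputs.py
"""

import sys
from pathlib import Path

from canroh import intervals, landscape, simulate, variant_io
from canroh.roh import froh

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = simulate.SimConfig(n_chromosomes=4, chromosome_length=50_000_000,
                             n_sites=100_000, n_ref=60, coverage=0.5,
                             seed=SEED)
    sites, panel = simulate.simulate_panel(cfg)
    truth = simulate.simulate_truth_individual(sites, 0.14, cfg)
    imputed = simulate.simulate_imputed_calls(truth, sites, cfg)
    pseudo = simulate.simulate_pseudohaploid(
        truth, sites, cfg.coverage, cfg.seed,
        chrom_lengths=cfg.chrom_lengths)

    variant_io.write_vcf(truth.callset(sites, cfg.chrom_lengths),
                         OUT / "truth.vcf.gz")
    variant_io.write_vcf(imputed, OUT / "imputed_0.5x.vcf.gz")
    variant_io.write_vcf(pseudo, OUT / "pseudohaploid_0.5x.vcf.gz")
    intervals.write_bed(truth.truth_roh, OUT / "truth_roh.bed")
    sites.to_csv(OUT / "panel_sites.tsv", sep="\t", index=False)

    grid = landscape.make_windows(cfg.chrom_lengths, 500_000)
    depths = simulate.simulate_window_depths(grid, outlier_fraction=0.02,
                                             seed=SEED)
    grid.assign(depth=depths).to_csv(OUT / "window_depths.tsv", sep="\t",
                                     index=False)

    genome = cfg.genome_length
    print(f"genome: {cfg.n_chromosomes} x {cfg.chromosome_length/1e6:.0f} Mb, "
          f"{cfg.n_sites} sites, panel of {cfg.n_ref} diploids")
    print(f"truth genome: {len(truth.truth_roh)} planted tracts, "
          f"F_ROH = {froh(truth.truth_roh, genome):.3f} (target 0.14)")
    err = (imputed.genotypes[0] != truth.genotypes).mean()
    print(f"imputed 0.5x call set: genotype error {err:.3%}, "
          f"mean INFO {imputed.info.mean():.3f}")
    miss = (pseudo.genotypes[0] == variant_io.MISSING).mean()
    print(f"pseudohaploid 0.5x call set: {miss:.1%} missing")
    print(f"wrote inputs to {OUT}/")


if __name__ == "__main__":
    main()
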