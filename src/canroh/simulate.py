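"""Synthetic data with known ground truth for the imputation/ROH pipeline.

The generators emulate, at the genotype level, the data a low-coverage
ancient-genome imputation study works with:

* a reference panel reduced to per-site allele frequencies (optionally with
  population structure between panel subgroups),
* "truth" diploid genomes carrying planted autozygous tracts at a target
  genomic fraction f,
* imputation-like call sets whose genotype error rate rises as coverage and
  minor-allele frequency fall, with posterior probabilities (GP), dosages
  (DS) and a calibrated per-site INFO score,
* pseudohaploid calls (one randomly sampled allele per covered site),
* two cohorts of ROH segment sets with shared hotspot and desert windows,
* per-window sequencing depths with a controllable outlier fraction.

No read-level process, ancient-DNA damage, or haplotype linkage structure
is simulated: the error model is a per-site miscall process

    eps(c, p) = eps0 * exp(-c / c0) * (1 + kappa * 1[p < rare_maf])

with coverage c, panel MAF p — a deliberately simple stand-in that
reproduces the qualitative accuracy patterns of real imputation output
(worse at low coverage, worse at rare sites), not its mechanism.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from canroh import _rng, intervals
from canroh.variant_io import MISSING, CallSet, compute_info

_COMPLEMENT = {"A": "G", "G": "A", "C": "T", "T": "C"}  # transition partner


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: the study's downsampling grid of fold-coverages
COVERAGE_GRID = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic benchmark.

    Attributes
    ----------
    n_chromosomes, chromosome_length, n_sites
        Genome layout; sites are spread uniformly over chromosomes.
    n_ref
        Number of diploid individuals in the synthetic reference panel.
    coverage
        Fold-coverage of the simulated low-coverage sample (the study's
        grid is :data:`COVERAGE_GRID`).
    error_base, coverage_scale, rare_penalty, rare_maf
        Parameters of the miscall model eps(c, p); see module docstring.
    missing_base
        Baseline per-genotype missingness of the imputed call set.
    het_uncertainty
        Multiplier on posterior diffuseness at heterozygous calls.
        Heterozygotes are the hardest class to impute from sparse reads,
        so their sites carry lower INFO; INFO filtering then biases the
        retained site set toward homozygous calls at low coverage, the
        mechanism behind spurious ROH in heavily filtered call sets.
    maf_alpha, maf_beta
        Beta distribution of panel allele frequencies (folded to <= 0.5
        for the MAF annotation).
    transition_fraction
        Fraction of sites whose ref/alt pair is a transition (~2/3
        genome-wide for real SNPs).
    n_pops, fst
        Optional population structure of the panel (Balding-Nichols
        frequency divergence between subgroups); fst = 0 disables it.
    seed
        Global seed; all operations derive independent substreams from it.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 50_000_000
    n_sites: int = 20_000
    n_ref: int = 50
    coverage: float = 1.0
    error_base: float = 0.1
    coverage_scale: float = 0.5
    rare_penalty: float = 2.0
    rare_maf: float = 0.05
    missing_base: float = 0.0
    het_uncertainty: float = 3.0
    maf_alpha: float = 0.3
    maf_beta: float = 0.7
    transition_fraction: float = 2.0 / 3.0
    n_pops: int = 1
    fst: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_base", "missing_base", "rare_maf",
                     "transition_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "chromosome_length", "n_sites", "n_ref",
                     "n_pops"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.coverage < 0 or self.coverage_scale <= 0:
            raise ValueError("coverage must be >= 0 and coverage_scale > 0")
        if self.fst < 0 or self.fst >= 1:
            raise ValueError("fst must be in [0, 1)")

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chromosome_length

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chromosome_length
                for i in range(self.n_chromosomes)}


@dataclasses.dataclass
class TruthIndividual:
    """A simulated diploid genome with known autozygous tracts."""

    genotypes: np.ndarray          # (n_sites,) codes in {0,1,2}
    truth_roh: pd.DataFrame        # segment table chrom/start/end
    target_autozygosity: float
    pop: int = 0

    def callset(self, site_table: pd.DataFrame,
                chrom_lengths: dict[str, int] | None = None,
                sample: str = "truth") -> CallSet:
        gt = self.genotypes[None, :]
        gp = np.zeros((1, len(site_table), 3))
        gp[0, np.arange(len(site_table)), self.genotypes] = 1.0
        return CallSet(sites=site_table, samples=[sample], genotypes=gt,
                       gp=gp, dosage=self.genotypes[None, :].astype(float),
                       info=np.ones(len(site_table)),
                       chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

def simulate_panel(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a reference panel: a site table plus panel genotypes.

    Per-site alternate-allele frequencies are Beta(maf_alpha, maf_beta)
    draws; the MAF annotation folds them to <= 0.5. Ref/alt nucleotides are
    assigned so that ``transition_fraction`` of sites are transitions.
    Panel genotypes are Hardy-Weinberg draws; with ``n_pops > 1`` each
    subgroup's frequency is a Balding-Nichols perturbation of the base
    frequency with divergence ``fst``.

    Returns
    -------
    (site_table, genotypes) where genotypes has shape (n_ref, n_sites).
    """
    rng = _rng.substream(config.seed, _rng.OP_PANEL)
    m = config.n_sites
    if m < 2 or config.n_ref < 2:
        raise ValueError("need n_sites >= 2 and n_ref >= 2")

    # even spread of sites over chromosomes, jittered positions
    per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    chroms, positions = [], []
    for ci, idx in enumerate(per_chrom):
        k = len(idx)
        pos = np.sort(rng.choice(config.chromosome_length, size=k,
                                 replace=False))
        chroms.extend([f"chr{ci + 1}"] * k)
        positions.append(pos)
    positions = np.concatenate(positions)

    alt_af = rng.beta(config.maf_alpha, config.maf_beta, size=m)
    alt_af = np.clip(alt_af, 1e-4, 1 - 1e-4)
    maf = np.minimum(alt_af, 1.0 - alt_af)

    refs = rng.choice(list("ACGT"), size=m)
    is_ts = rng.random(m) < config.transition_fraction
    alts = np.empty(m, dtype="<U1")
    for i in range(m):
        r = refs[i]
        if is_ts[i]:
            alts[i] = _COMPLEMENT[r]
        else:
            choices = [b for b in "ACGT"
                       if b != r and b != _COMPLEMENT[r]]
            alts[i] = choices[rng.integers(2)]

    sites = pd.DataFrame({
        "chrom": chroms, "pos": positions.astype(np.int64),
        "ref": refs, "alt": alts,
        "maf": maf, "alt_af": alt_af,
        "transversion": ~is_ts,
    })

    # panel genotypes under HW, with optional Balding-Nichols structure
    pops = np.arange(config.n_ref) % config.n_pops
    if config.n_pops > 1 and config.fst > 0:
        shape = (1.0 - config.fst) / config.fst
        pop_af = np.stack([
            rng.beta(alt_af * shape, (1.0 - alt_af) * shape)
            for _ in range(config.n_pops)
        ])
        pop_af = np.clip(pop_af, 1e-4, 1 - 1e-4)
    else:
        pop_af = np.tile(alt_af, (config.n_pops, 1))
    genotypes = rng.binomial(2, pop_af[pops, :]).astype(np.int8)
    return sites, genotypes


# ---------------------------------------------------------------------------
# Truth individuals with planted autozygous tracts
# ---------------------------------------------------------------------------

#: shortest tract the placer will emit when truncating the final tract to
#: hit the target; comfortably above typical ROH-calling minimum lengths
MIN_TRACT_BP = 1_000_000


def _place_tracts(rng: np.random.Generator, chrom_lengths: dict[str, int],
                  target_bp: int, tract_length_sampler) -> pd.DataFrame:
    """Place non-overlapping tracts uniformly until target_bp is reached.

    The final tract is truncated so the total lands on the target; a
    remainder shorter than MIN_TRACT_BP is dropped rather than emitted as
    an uncallably short tract.
    """
    rows: list[tuple[str, int, int]] = []
    total = 0
    chrom_names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    attempts = 0
    while total < target_bp and attempts < 10_000:
        attempts += 1
        remaining = target_bp - total
        if remaining < MIN_TRACT_BP:
            break
        tl = min(int(tract_length_sampler(rng)), remaining)
        ci = rng.choice(len(chrom_names), p=probs)
        L = int(lengths[ci])
        if tl >= L:
            continue
        start = int(rng.integers(0, L - tl))
        cand = (chrom_names[ci], start, start + tl)
        if any(c == cand[0] and not (cand[2] <= s or cand[1] >= e)
               for c, s, e in rows):
            continue
        rows.append(cand)
        total += tl
    return intervals.as_segments(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def default_tract_length_sampler(rng: np.random.Generator) -> float:
    """Tract lengths 2-8 Mb uniform: comfortably above typical ROH-calling
    minimum lengths, mixing short and long classes around the 1.6 Mb split."""
    return rng.uniform(2e6, 8e6)


def simulate_truth_individual(site_table: pd.DataFrame, f: float,
                              config: SimConfig,
                              tract_length_sampler=default_tract_length_sampler,
                              seed_key: int = 0,
                              pop: int = 0) -> TruthIndividual:
    """Simulate a diploid genome with autozygous fraction ~f.

    Inside planted tracts one founder haplotype is duplicated, so every
    genotype is homozygous, with the allele drawn by panel frequency.
    Outside tracts genotypes are Hardy-Weinberg draws. ``seed_key``
    distinguishes individuals under the same config.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError(f"autozygosity target f must be in [0, 1), got {f}")
    rng = _rng.substream(config.seed, _rng.OP_TRUTH, seed_key)
    chrom_lengths = config.chrom_lengths
    genome = config.genome_length
    target_bp = int(round(f * genome))
    tracts = (_place_tracts(rng, chrom_lengths, target_bp, tract_length_sampler)
              if target_bp > 0 else intervals.empty_segments())

    af = site_table["alt_af"].to_numpy()
    n = len(site_table)
    geno = rng.binomial(2, af).astype(np.int8)
    # overwrite tract sites with duplicated-founder homozygotes
    in_tract = np.zeros(n, dtype=bool)
    pos = site_table["pos"].to_numpy()
    chrom = site_table["chrom"].to_numpy()
    for c, s, e in tracts[["chrom", "start", "end"]].itertuples(index=False):
        in_tract |= (chrom == c) & (pos >= s) & (pos < e)
    k = int(in_tract.sum())
    if k:
        geno[in_tract] = 2 * rng.binomial(1, af[in_tract]).astype(np.int8)
    return TruthIndividual(genotypes=geno, truth_roh=tracts,
                           target_autozygosity=f, pop=pop)


# ---------------------------------------------------------------------------
# Imputation-like noisy calls
# ---------------------------------------------------------------------------

def error_probability(config: SimConfig, maf: np.ndarray) -> np.ndarray:
    """Per-site miscall probability eps(c, p); clipped to [0, 0.45].

    eps(c, p) = eps0 * exp(-c/c0) * (1 + kappa * 1[p < rare_maf]) * (1 - p)

    The (1 - p) factor makes accuracy improve gently and continuously with
    MAF on top of the rare-site penalty, mirroring how haplotype-based
    imputation gains statistical support as the minor allele becomes more
    common; without it, mean-reverting miscalls at balanced-frequency
    sites would make r² dip slightly in the top MAF bin, a pattern real
    imputation output does not show.
    """
    eps = (config.error_base * np.exp(-config.coverage / config.coverage_scale)
           * (1.0 + config.rare_penalty * (maf < config.rare_maf))
           * (1.0 - maf))
    return np.clip(eps, 0.0, 0.45)


def simulate_imputed_calls(truth: TruthIndividual, site_table: pd.DataFrame,
                           config: SimConfig, seed_key: int = 0,
                           sample: str = "imputed") -> CallSet:
    """Emit an imputation-like call set for a truth genome.

    Each genotype is miscalled with probability eps(c, p); a miscall moves
    the call to an adjacent genotype class (0<->1, 1<->2, hets to either
    side with equal odds). The posterior triple puts mass 1-q on the
    reported class with q drawn uniformly in [0, 2*eps] (capped below
    0.49), so error-prone sites carry visibly diffuse posteriors — and
    hence lower INFO scores, computed by :func:`compute_info` on the
    emitted posteriors exactly as imputation tools do.
    """
    if len(truth.genotypes) != len(site_table):
        raise ValueError("truth and site table are not congruent")
    rng = _rng.substream(config.seed, _rng.OP_IMPUTE, seed_key)
    n = len(site_table)
    maf = site_table["maf"].to_numpy()
    eps = error_probability(config, maf)

    g = truth.genotypes.astype(np.int8).copy()
    err = rng.random(n) < eps
    direction = rng.integers(0, 2, size=n)  # for hets: down/up
    g_err = g.copy()
    g_err[g == 0] = 1
    g_err[g == 2] = 1
    g_err[g == 1] = np.where(direction[g == 1] == 0, 0, 2)
    g = np.where(err, g_err, g).astype(np.int8)

    q = rng.uniform(0.0, 2.0 * eps)
    # heterozygous calls are the least certain class at low coverage
    q = np.where(g == 1, config.het_uncertainty * q, q)
    q = np.minimum(q, 0.49)
    gp = np.zeros((n, 3))
    idx = np.arange(n)
    gp[idx, g] = 1.0 - q
    # residual mass to adjacent classes
    hom0 = g == 0
    hom2 = g == 2
    het = g == 1
    gp[hom0, 1] = q[hom0]
    gp[hom2, 1] = q[hom2]
    gp[het, 0] = q[het] / 2.0
    gp[het, 2] = q[het] / 2.0

    geno = g.copy()
    if config.missing_base > 0:
        miss = rng.random(n) < config.missing_base
        geno = np.where(miss, MISSING, geno).astype(np.int8)

    dosage = gp[:, 1] + 2.0 * gp[:, 2]
    # single-sample INFO is scored against the panel frequency; the
    # posterior-estimated theta would be degenerate at N = 1
    info = compute_info(gp[None, :, :],
                        theta=site_table["alt_af"].to_numpy())
    return CallSet(sites=site_table, samples=[sample],
                   genotypes=geno[None, :], gp=gp[None, :, :],
                   dosage=dosage[None, :], info=np.asarray(info, dtype=float),
                   chrom_lengths=config.chrom_lengths)


# ---------------------------------------------------------------------------
# Pseudohaploid calls
# ---------------------------------------------------------------------------

def simulate_pseudohaploid(truth: TruthIndividual, site_table: pd.DataFrame,
                           coverage: float, seed: int, seed_key: int = 0,
                           sample: str = "pseudohap",
                           chrom_lengths: dict[str, int] | None = None
                           ) -> CallSet:
    """Pseudohaploid calls: one random allele per covered site.

    A site has no read (missing) with probability exp(-coverage) — the
    Poisson zero-count probability — otherwise one of the two alleles of
    the truth genotype is sampled uniformly and reported as a homozygous
    diploid code (0 or 2).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = _rng.substream(seed, _rng.OP_PSEUDOHAP, seed_key)
    n = len(site_table)
    missing = rng.random(n) < np.exp(-coverage)
    allele = np.where(truth.genotypes == 1,
                      rng.integers(0, 2, size=n),
                      truth.genotypes // 2)
    geno = np.where(missing, MISSING, 2 * allele).astype(np.int8)
    return CallSet(sites=site_table, samples=[sample], genotypes=geno[None, :],
                   chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# ROH cohorts for the landscape analysis
# ---------------------------------------------------------------------------

def simulate_cohorts(n_ancient: int, n_modern: int,
                     froh_ancient: float, froh_modern: float,
                     window_grid: pd.DataFrame,
                     hotspot_windows: np.ndarray | list[int] = (),
                     desert_windows: np.ndarray | list[int] = (),
                     hotspot_boost: float = 5.0,
                     seed: int = 0,
                     tract_length_sampler=None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample ROH segment sets for two cohorts.

    Tracts are placed by rejection sampling: a candidate tract is rejected
    if it overlaps a designated desert window, and accepted with elevated
    odds (``hotspot_boost``) if it overlaps a hotspot window; otherwise
    acceptance is uniform. Per-sample total tract length targets the
    cohort's F_ROH.

    Parameters
    ----------
    window_grid : DataFrame from :func:`canroh.landscape.make_windows`
        Supplies the genome layout and window coordinates that hotspot /
        desert indices refer to.

    Returns
    -------
    (segments, labels): a segment table with a ``sample`` column, and a
    labels table (sample, group).
    """
    hotspot_windows = np.asarray(hotspot_windows, dtype=int)
    desert_windows = np.asarray(desert_windows, dtype=int)
    if np.intersect1d(hotspot_windows, desert_windows).size:
        raise ValueError("hotspot and desert windows must be disjoint")
    rng = _rng.substream(seed, _rng.OP_COHORTS)
    if tract_length_sampler is None:
        tract_length_sampler = default_tract_length_sampler

    grid = window_grid.reset_index(drop=True)
    chrom_lengths = grid.groupby("chrom", sort=False)["end"].max().to_dict()
    genome = int(sum(chrom_lengths.values()))
    desert_bp = int((grid.loc[desert_windows, "end"]
                     - grid.loc[desert_windows, "start"]).sum()) \
        if desert_windows.size else 0
    max_f = max(froh_ancient, froh_modern)
    if genome - desert_bp < 2.0 * max_f * genome:
        raise ValueError("desert windows cover too much genome for the "
                         "requested F_ROH targets")

    deserts = grid.loc[desert_windows, ["chrom", "start", "end"]] \
        if desert_windows.size else intervals.empty_segments()
    hotspots = grid.loc[hotspot_windows, ["chrom", "start", "end"]] \
        if hotspot_windows.size else intervals.empty_segments()

    def overlaps(seg, table) -> bool:
        if len(table) == 0:
            return False
        c, s, e = seg
        sub = table[table["chrom"] == c]
        return bool(((sub["start"] < e) & (sub["end"] > s)).any())

    chrom_names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()

    all_rows = []
    labels = []
    specs = [("ancient", n_ancient, froh_ancient),
             ("modern", n_modern, froh_modern)]
    for group, n_samples, f in specs:
        for si in range(n_samples):
            name = f"{group}_{si:03d}"
            labels.append((name, group))
            target = f * genome
            placed: list[tuple[str, int, int]] = []
            total = 0
            attempts = 0
            while total < target and attempts < 20_000:
                attempts += 1
                remaining = int(target - total)
                if remaining < MIN_TRACT_BP:
                    break
                tl = min(int(tract_length_sampler(rng)), remaining)
                ci = rng.choice(len(chrom_names), p=probs)
                L = int(lengths[ci])
                if tl >= L:
                    continue
                start = int(rng.integers(0, L - tl))
                cand = (chrom_names[ci], start, start + tl)
                if overlaps(cand, deserts):
                    continue
                if any(c == cand[0] and not (cand[2] <= s or cand[1] >= e)
                       for c, s, e in placed):
                    continue
                if hotspot_windows.size and not overlaps(cand, hotspots):
                    # uniform placement would overweight non-hotspot genome;
                    # thin non-hotspot candidates to boost hotspot odds
                    if rng.random() > 1.0 / hotspot_boost:
                        continue
                placed.append(cand)
                total += tl
            for c, s, e in placed:
                all_rows.append((c, s, e, name))
    segments = pd.DataFrame(all_rows,
                            columns=["chrom", "start", "end", "sample"])
    segments = segments.sort_values(["sample", "chrom", "start"]) \
        .reset_index(drop=True)
    label_df = pd.DataFrame(labels, columns=["sample", "group"])
    return segments, label_df


# ---------------------------------------------------------------------------
# Window depths
# ---------------------------------------------------------------------------

def simulate_window_depths(window_grid: pd.DataFrame,
                           outlier_fraction: float = 0.02,
                           mean_depth: float = 5.0,
                           sd_depth: float = 1.0,
                           seed: int = 0) -> np.ndarray:
    """Per-window mean depths: Normal(mean, sd) baseline with a fraction of
    windows replaced by 5-10x spikes (emulating collapsed repeats / CNVs)."""
    if not 0.0 <= outlier_fraction < 0.5:
        raise ValueError("outlier_fraction must be in [0, 0.5)")
    rng = _rng.substream(seed, _rng.OP_DEPTHS)
    n = len(window_grid)
    depths = rng.normal(mean_depth, sd_depth, size=n)
    n_out = int(round(outlier_fraction * n))
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        depths[idx] = mean_depth * rng.uniform(5.0, 10.0, size=n_out)
    return depths
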