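# Methods

This note documents the models, parameter choices and numerical
conventions behind `canroh`, and what the synthetic benchmark does and
does not establish about real data.

## The synthetic data model

The generator works at the *genotype* level. A reference panel is reduced
to per-site alternate-allele frequencies q ~ Beta(0.3, 0.7) (folded to a
MAF ≤ 0.5 annotation), a heavily zero-skewed shape typical of sequencing
panels; ref/alt nucleotides are assigned so two thirds of sites are
transitions, matching genome-wide SNP composition. Panel genotypes are
Hardy–Weinberg draws; optional population structure uses Balding–Nichols
frequency perturbation (`n_pops`, `fst`), which is what gives PCA a real
axis of variation to recover.

**Truth genomes.** Autozygous tracts are placed uniformly and without
overlap until a target fraction *f* of the genome is covered; the final
tract is truncated to land on the target (tracts shorter than 1 Mb are
never emitted, keeping every planted tract above typical ROH-calling
minimum lengths). Inside a tract one founder haplotype is duplicated
(homozygote by allele frequency); outside, genotypes are Hardy–Weinberg.
The default tract-length sampler is uniform on 2–8 Mb — long enough to be
unambiguous for the caller while straddling the 1.6 Mb short/long split.

**Imputation-like calls.** Each genotype is miscalled with probability

    eps(c, p) = eps0 · exp(−c / c0) · (1 + kappa · 1[p < 0.05]) · (1 − p)

with coverage c and panel MAF p; defaults eps0 = 0.1, c0 = 0.5,
kappa = 2. This is the package's own error model — imputation tools do
not publish one — built to reproduce the qualitative accuracy surface of
real benchmarks: error falls exponentially with coverage, rare sites are
penalized, and the continuous (1 − p) factor makes accuracy improve
gently with MAF throughout. The last factor matters: without it,
miscalls at balanced-frequency sites (hom→het, het→either side) are
mean-reverting and depress r² slightly in the top MAF bin, a dip real
imputation output does not show. A miscall moves the call to an adjacent
genotype class; posterior mass 1 − q stays on the reported class with
q ~ U(0, 2·eps), capped at 0.49 so the argmax always equals the reported
call. Heterozygous calls get q multiplied by `het_uncertainty` (default
3): hets are the hardest class to impute from sparse reads, and this is
the mechanism that reproduces the known low-coverage failure mode —
INFO-filtering preferentially removes het sites, the retained set becomes
homozygosity-biased, and spurious ROH appear (FDR highest at 0.05×,
falling with coverage, while sensitivity stays high).

**INFO scores.** Per-site INFO is the IMPUTE-style variance ratio
computed from the emitted posteriors. For a *single* sample the formula's
internal allele-frequency estimate θ = Σe/2N is degenerate (a slightly
diffuse hom-ref call would score ≈ 0), so the simulator supplies the
panel allele frequency as θ — effectively what imputation software uses
when scoring one sample against a panel. `compute_info` without an
external θ implements the estimated-θ form, which is the correct
"recalibration" over a merged cohort and is exposed as
`recalibrate_info`.

**Pseudohaploid calls.** A site is missing with probability e^(−c) (the
Poisson zero-read probability — the simplest coverage-faithful model);
otherwise one allele of the diploid truth genotype is sampled uniformly
and reported as a homozygous code. No reads, base qualities or
deamination damage are simulated.

**Cohorts and landscape fixtures.** Two cohorts of ROH segment sets are
placed by rejection sampling: candidates overlapping designated desert
windows are rejected, candidates missing hotspot windows are thinned by
1/`hotspot_boost` (default 5), and per-sample total length targets the
cohort F_ROH (defaults 0.05 ancient vs 0.30 modern, the contrast between
pre-breed-formation dogs and modern breeds). Window depths are
Normal(μ, σ) with a fraction of 5–10×μ spikes emulating collapsed
repeats/CNVs.

**Determinism.** One global seed expands to per-operation substreams via
`numpy.random.SeedSequence(seed, spawn_key=(op, key))`, so adding samples
or stages never perturbs earlier draws; identical (config, seed) gives
bit-identical output everywhere, including the permutation test.

## What the generator does *not* emulate

No linkage disequilibrium or haplotype mosaic structure (errors are
independent across sites given coverage and MAF), no read-level process,
no ancient-DNA damage, no actual imputation algorithm. Consequently the
benchmark validates the *measurement machinery* — that the statistics,
filters, caller and tests behave correctly on data with a known answer —
not the accuracy of any particular imputation tool on real ancient DNA.
Absolute values (r², NRD, FDR) are properties of the synthetic error
model, not predictions for real samples.

## Analysis conventions and numerical choices

- **MAF bins**: half-open [eᵢ, eᵢ₊₁), last bin closed; default edges
  0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5 cover the conventional filtering
  cutoffs. "MAF above 0.01" filters are implemented inclusively (≥ 0.01).
- **r²** uses imputed dosages when present (field practice), hard calls
  otherwise; sites missing in the truth are excluded, not counted as
  errors. Undefined statistics (empty class, zero variance) are NaN with
  a defined-flag — never silently 0, which would fake perfection in
  near-empty bins.
- **ROH scan defaults** are the reference tool's published defaults
  (window 50 SNPs / 1 het / 5 missing, hit threshold 0.05, min 100 SNPs,
  min 1000 kb, max 50 kb/SNP, gap split 1000 kb); the algorithm, not the
  constants, is the contract, and all are configurable. Segment
  coordinates run from first to last SNP of the run. The scan sees only
  the SNPs supplied, so site density bounds boundary resolution.
- **F_ROH denominator** is the full autosome length (configurable); the
  short/long boundary is 1.6 Mb, long ROH flagging recent inbreeding.
  Samples with F_ROH > 0.1 are flagged highly inbred.
- **Interval scoring** is exact in integer bp; tp+fp+tn+fn reconstructs
  the assayable length identically. Segment-basis "overlap" is ≥ 1 bp by
  default with an optional reciprocal-overlap fraction; segment-basis tn
  is undefined, with an off-by-default convention (truth gaps untouched
  by any test segment) for users who need a segment-basis nMCC.
- **Window QC** computes mean and sample SD (ddof = 1) genome-wide over
  all windows; a window is dropped outside mean ± 2 SD or when ≥ 50 % of
  its length overlaps the CNV mask (both configurable).
- **Desert test null**: every sample's occupied-window set is reassigned
  to a uniform random subset of QC-included windows of the same size,
  independently per sample and cohort — deliberately ignoring segment
  contiguity, because the null hypothesis is random, independent
  placement; a contiguity-preserving circular-shift null is provided for
  sensitivity analysis. One-sided p with the +1 correction. Being a
  discrete randomization test it is exactly valid but mildly conservative
  when the null count distribution has heavy ties; calibration is checked
  at a realistic granularity (1,000 windows).
- **PCA**: centering by per-site mean, scaling by √(p(1−p)), monomorphic
  sites dropped, SVD; loading signs fixed (largest-magnitude entry
  positive) for run-to-run reproducibility. Projection of incomplete
  samples is least squares on the observed, standardized sites. The PC
  distance is eigenvalue-proportion-weighted L1 over the top 10 PCs by
  default — the weighting is this package's definition (published work
  rarely prints one); squared and unweighted variants are flags.
- **Rank-sum W** follows R's `wilcox.test` convention (midranks, W =
  rank sum of x minus n_x(n_x+1)/2), exact p for n_x·n_y ≤ 400 without
  ties, tie-corrected normal otherwise; continuity correction off by
  default (configurable — published W/p pairs can depend on it). Pairwise
  cohort p-values are reported raw, without multiplicity adjustment.

## Problem sizes used in tests and the acceptance script

The shipped analyses run on a 4 × 50 Mb genome with 100,000 panel sites
(0.5 SNP/kb), 60-diploid panels, 30 + 30 cohorts, 400 × 500 kb windows
and 999 permutations; PCA examples use 3,000–5,000 sites and 60–80
reference samples. These sizes give stable statistics in seconds while
exercising every code path; all are configuration parameters, and nothing
in the implementation depends on them.

## Known limitations

- The error model is independent across sites; real imputation errors are
  locally correlated along haplotypes, so real ROH false positives are
  blockier than simulated ones.
- Cohort ROH sets are placed geometrically, not generated from genotypes,
  so the landscape arm tests windowing/QC/test logic rather than the
  caller; the benchmark arm covers the caller separately.
- The synthetic panel does not mirror any real panel's site-filtering
  history; transversion fractions and MAF spectra are stylized.
- Single-sample INFO depends on the supplied panel frequency; with very
  small panels that frequency is itself noisy, which is not modeled.
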