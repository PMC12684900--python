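"""Variant input/output, per-site annotation, and post-imputation filtering.

Conventions
-----------
Sites live in a "site table": a pandas DataFrame with one row per biallelic
SNP and columns

``chrom``        chromosome label (str)
``pos``          0-based position (converted to 1-based on VCF output)
``ref``, ``alt`` nucleotides
``maf``          minor allele frequency in the reference panel, in [0, 0.5]
``alt_af``       alternate-allele frequency in the panel (may exceed 0.5)
``transversion`` bool

Genotype call sets are :class:`CallSet` objects: genotype codes 0/1/2 count
alternate alleles, -1 marks missing. Optional per-genotype posteriors (GP),
dosages (DS) and a per-site imputation INFO score mirror what low-coverage
imputation tools emit.

The INFO score implemented here is the IMPUTE-style ratio of observed to
expected dosage variance computed from the posterior genotype probabilities;
recomputing it over a merged cohort is what "recalibration" means in this
package.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: default MAF bin edges; chosen to bracket the cutoffs 0.01/0.02/0.05
#: commonly used for post-imputation filtering
DEFAULT_MAF_EDGES = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_NUCS = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CallSet:
    """Per-sample × per-site genotype calls with optional posteriors.

    Attributes
    ----------
    sites : pandas.DataFrame
        Site table (see module docstring).
    samples : list of str
    genotypes : int8 array, shape (n_samples, n_sites)
        0/1/2 alternate-allele counts; -1 = missing.
    gp : float array, shape (n_samples, n_sites, 3), optional
        Posterior probabilities of genotype classes 0/1/2; rows sum to 1.
    dosage : float array, shape (n_samples, n_sites), optional
        Expected alternate-allele count, GP1 + 2*GP2, in [0, 2].
    info : float array, shape (n_sites,), optional
        Per-site imputation INFO score in [0, 1].
    chrom_lengths : dict, optional
        Chromosome label -> length in bp (needed to write VCF contigs).
    """

    sites: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray
    gp: np.ndarray | None = None
    dosage: np.ndarray | None = None
    info: np.ndarray | None = None
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("genotypes shape must be (n_samples, n_sites)")
        if self.gp is not None:
            self.gp = np.asarray(self.gp, dtype=float)
            sums = self.gp.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("GP rows must sum to 1")
        if self.dosage is not None:
            self.dosage = np.asarray(self.dosage, dtype=float)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, idx: np.ndarray) -> "CallSet":
        """Subset to the given site indices (positional)."""
        return CallSet(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            genotypes=self.genotypes[:, idx],
            gp=None if self.gp is None else self.gp[:, idx, :],
            dosage=None if self.dosage is None else self.dosage[:, idx],
            info=None if self.info is None else np.asarray(self.info)[idx],
            chrom_lengths=self.chrom_lengths,
        )

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)


# ---------------------------------------------------------------------------
# Per-site annotations
# ---------------------------------------------------------------------------

def is_transversion(ref: str, alt: str) -> bool:
    """True iff ref->alt is a purine<->pyrimidine change.

    Transitions (A<->G, C<->T) are the substitution classes that overlap
    post-mortem cytosine deamination damage in ancient DNA, hence the
    transversion-only analysis mode.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _NUCS or alt not in _NUCS:
        raise ValueError(f"non-nucleotide allele: {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref == alt is not a variant")
    return not ((ref in _PURINES) == (alt in _PURINES))


def assign_maf_bin(maf: float | np.ndarray,
                   edges: Sequence[float] = DEFAULT_MAF_EDGES) -> np.ndarray | int:
    """Bin index for a MAF under half-open binning [e_i, e_{i+1}).

    The last bin is closed on the right so maf = 0.5 belongs to it.
    """
    edges = np.asarray(edges, dtype=float)
    if edges[0] != 0.0 or edges[-1] != 0.5 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must increase strictly from 0 to 0.5")
    arr = np.asarray(maf, dtype=float)
    if np.any((arr < 0) | (arr > 0.5)):
        raise ValueError("maf outside [0, 0.5]")
    idx = np.searchsorted(edges, arr, side="right") - 1
    idx = np.minimum(idx, len(edges) - 2)  # maf == 0.5 -> last bin
    return idx if np.ndim(maf) else int(idx)


def compute_info(gp: np.ndarray,
                 theta: float | np.ndarray | None = None) -> float | np.ndarray:
    """IMPUTE-style INFO score from posterior genotype probabilities.

    With per-sample expected dosage e_i = GP_i1 + 2 GP_i2 and second moment
    f_i = GP_i1 + 4 GP_i2, and allele frequency theta:

        INFO = 1 - sum(f_i - e_i^2) / (2N * theta * (1 - theta))

    By default theta is estimated from the posteriors themselves,
    theta = sum(e_i) / 2N — the "recalibration" mode used after merging a
    cohort. For few samples that estimate is unstable (with one confident
    homozygous-reference sample it collapses to 0), so ``theta`` may be
    supplied externally, typically the reference-panel alternate-allele
    frequency — what imputation tools effectively use when scoring a
    single sample against a panel.

    INFO = 1 by convention when theta is 0 or 1 (monomorphic).
    Values are clipped to [0, 1].

    Parameters
    ----------
    gp : array, shape (N, 3) for one site or (N, n_sites, 3)
    theta : optional fixed allele frequency (scalar or per-site array)

    Returns
    -------
    float for a single site, else array of shape (n_sites,)
    """
    gp = np.asarray(gp, dtype=float)
    single = gp.ndim == 2
    if single:
        gp = gp[:, None, :]
    if gp.ndim != 3 or gp.shape[2] != 3:
        raise ValueError("gp must have shape (N, [n_sites,] 3)")
    sums = gp.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("malformed posterior: rows must sum to 1")
    n = gp.shape[0]
    e = gp[:, :, 1] + 2.0 * gp[:, :, 2]
    f = gp[:, :, 1] + 4.0 * gp[:, :, 2]
    if theta is None:
        theta = e.sum(axis=0) / (2.0 * n)
    else:
        theta = np.broadcast_to(np.asarray(theta, dtype=float),
                                (gp.shape[1],))
    denom = 2.0 * n * theta * (1.0 - theta)
    num = (f - e**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = 1.0 - num / denom
    info = np.where((theta <= 0.0) | (theta >= 1.0), 1.0, info)
    info = np.clip(info, 0.0, 1.0)
    return float(info[0]) if single else info


def recalibrate_info(callset: CallSet) -> CallSet:
    """Recompute per-site INFO over all samples currently in the call set.

    This is what "recalibrating" INFO means after merging cohorts imputed
    separately: the score is a function of the pooled posteriors.
    """
    if callset.gp is None:
        raise ValueError("call set has no posteriors to recalibrate from")
    info = compute_info(callset.gp)
    return dataclasses.replace(callset, info=np.asarray(info, dtype=float))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_sites(callset: CallSet,
                 info_min: float = 0.0,
                 maf_min: float = 0.0,
                 transversions_only: bool = False) -> tuple[CallSet, dict[str, int]]:
    """Apply post-imputation site filters.

    Retains sites with INFO >= info_min AND panel MAF >= maf_min AND
    (transversion, if requested). Returns the filtered call set and a dict
    of per-criterion removal counts (a site failing several criteria is
    counted under each).
    """
    sites = callset.sites
    n = len(sites)
    keep = np.ones(n, dtype=bool)
    removed = {}
    if info_min > 0:
        if callset.info is None:
            raise ValueError("info_min requested but call set has no INFO")
        ok = np.asarray(callset.info) >= info_min
        removed["info"] = int((~ok).sum())
        keep &= ok
    if maf_min > 0:
        ok = sites["maf"].to_numpy() >= maf_min
        removed["maf"] = int((~ok).sum())
        keep &= ok
    if transversions_only:
        ok = sites["transversion"].to_numpy().astype(bool)
        removed["transition"] = int((~ok).sum())
        keep &= ok
    removed["total"] = int((~keep).sum())
    return callset.take_sites(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# VCF input/output
# ---------------------------------------------------------------------------

INFO_KEY = "INFO_SCORE"


def write_vcf(callset: CallSet, path) -> None:
    """Write a call set as VCF 4.2 with GT, GP, DS and per-site INFO_SCORE.

    Positions are written 1-based; a ``.vcf.gz`` suffix produces a
    bgzip-compressed file.
    """
    import pysam

    path = str(path)
    header = pysam.VariantHeader()
    lengths = callset.chrom_lengths or {}
    chroms = list(dict.fromkeys(callset.sites["chrom"]))
    for chrom in chroms:
        header.contigs.add(str(chrom), length=int(lengths.get(chrom, 2**29)))
    header.info.add(INFO_KEY, 1, "Float", "Imputation INFO score")
    header.info.add("PANEL_MAF", 1, "Float", "Reference-panel minor allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GP", "G", "Float", "Genotype posterior probabilities")
    header.formats.add("DS", 1, "Float", "Alternate allele dosage")
    for s in callset.samples:
        header.add_sample(s)

    mode = "wz" if path.endswith(".gz") else "w"
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(path, mode, header=header) as out:
        for j, row in enumerate(callset.sites.itertuples(index=False)):
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos),
                stop=int(row.pos) + 1, alleles=(row.ref, row.alt))
            if callset.info is not None:
                rec.info[INFO_KEY] = float(callset.info[j])
            rec.info["PANEL_MAF"] = float(row.maf)
            for i, s in enumerate(callset.samples):
                rec.samples[s]["GT"] = gt_map[int(callset.genotypes[i, j])]
                if callset.gp is not None:
                    rec.samples[s]["GP"] = tuple(float(x) for x in callset.gp[i, j])
                if callset.dosage is not None:
                    rec.samples[s]["DS"] = float(callset.dosage[i, j])
            out.write(rec)
    if path.endswith(".gz"):
        pysam.tabix_index(path, preset="vcf", force=True)


def read_vcf(path, panel_maf: pd.DataFrame | None = None) -> CallSet:
    """Read a biallelic-SNP VCF into a :class:`CallSet`.

    Multiallelic and non-SNP records are skipped (counted in the log).
    Panel MAF is taken from the ``PANEL_MAF`` INFO key when present, else
    from an optional ``panel_maf`` site table keyed by (chrom, pos), else
    left as NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, gts, gps, dss, infos = [], [], [], [], []
    n_skipped = 0
    has_gp = has_ds = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1 \
                or var.REF not in _NUCS or var.ALT[0] not in _NUCS:
            n_skipped += 1
            continue
        maf = var.INFO.get("PANEL_MAF")
        rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0],
                     np.nan if maf is None else float(maf)))
        # gts012: 0/1/2 = alt count, 3 = missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        try:
            gp = var.format("GP")
        except KeyError:
            gp = None
        if gp is None:
            has_gp = False
        else:
            gps.append(np.asarray(gp, dtype=float))
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is None:
            has_ds = False
        else:
            dss.append(np.asarray(ds, dtype=float).ravel())
        score = var.INFO.get(INFO_KEY)
        infos.append(np.nan if score is None else float(score))
    if n_skipped:
        logger.warning("skipped %d multiallelic/non-SNP records in %s",
                       n_skipped, path)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"])
    if panel_maf is not None:
        key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
        lut = panel_maf.set_index(["chrom", "pos"])["maf"]
        sites["maf"] = lut.reindex(key).to_numpy()
    sites["alt_af"] = sites["maf"]
    sites["transversion"] = [is_transversion(r, a)
                             for r, a in zip(sites["ref"], sites["alt"])]
    info_arr = np.asarray(infos, dtype=float)
    cs = CallSet(
        sites=sites,
        samples=samples,
        genotypes=np.asarray(gts, dtype=np.int8).T if gts else
        np.zeros((len(samples), 0), dtype=np.int8),
        gp=np.transpose(np.asarray(gps), (1, 0, 2)) if (has_gp and gps) else None,
        dosage=np.asarray(dss).T if (has_ds and dss) else None,
        info=None if np.all(np.isnan(info_arr)) else info_arr,
        chrom_lengths={c: l for c, l in zip(vcf.seqnames, vcf.seqlens)}
        if vcf.seqlens is not None else None,
    )
    cs.skipped_records = n_skipped
    return cs
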