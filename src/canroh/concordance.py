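"""Genotype concordance between a truth and an imputed call set.

Implements the standard accuracy panel for imputation benchmarking:

* a 3x3 genotype confusion matrix (truth class x imputed class),
* per-class error rates for homozygous-reference, heterozygous and
  homozygous-alternate truth genotypes,
* non-reference discordance (NRD), the error rate whose denominator
  excludes concordant homozygous-reference calls — so it weights the sites
  carrying the alternate allele, not the hom-ref majority,
* squared Pearson correlation r² between truth genotype codes and imputed
  dosages, stratified by panel-MAF bin and INFO-score cutoff.

Statistics whose denominator is empty or whose inputs have zero variance
are reported as *undefined* (NaN plus a defined=False flag), never as 0:
a silently perfect score in a near-empty bin would be misleading.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from canroh.variant_io import (DEFAULT_MAF_EDGES, MISSING, CallSet,
                               assign_maf_bin)

#: INFO cutoffs examined in the benchmark; None = no cutoff
DEFAULT_INFO_CUTOFFS = (None, 0.8, 0.9, 0.95)


@dataclasses.dataclass
class ConfusionMatrix:
    """3x3 genotype confusion counts; n[t][i] = truth class t called as i."""

    counts: np.ndarray
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def genotype_confusion(truth: np.ndarray, imputed: np.ndarray,
                       site_mask: np.ndarray | None = None) -> ConfusionMatrix:
    """Tally the genotype confusion matrix for one sample.

    Sites missing in either vector are counted in ``n_missing`` and
    excluded from the matrix. ``site_mask`` optionally restricts the
    comparison to a boolean subset of sites.
    """
    truth = np.asarray(truth).ravel()
    imputed = np.asarray(imputed).ravel()
    if truth.shape != imputed.shape:
        raise ValueError("truth and imputed vectors differ in length")
    if site_mask is not None:
        mask = np.asarray(site_mask, dtype=bool)
        truth, imputed = truth[mask], imputed[mask]
    ok = (truth != MISSING) & (imputed != MISSING)
    n_missing = int((~ok).sum())
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (truth[ok], imputed[ok]), 1)
    return ConfusionMatrix(counts=counts, n_missing=n_missing)


def error_rates(confusion: ConfusionMatrix) -> tuple[float, float, float]:
    """Per-truth-class error rates (hom-ref, het, hom-alt).

    error_t = sum_{i != t} n[t][i] / sum_i n[t][i]; NaN when the class is
    absent (undefined, not zero).
    """
    c = confusion.counts
    out = []
    for t in range(3):
        row = c[t].sum()
        out.append(float(c[t].sum() - c[t, t]) / row if row > 0 else np.nan)
    return tuple(out)


def nrd(confusion: ConfusionMatrix) -> float:
    """Non-reference discordance rate.

    NRD = (e_RR + e_RA + e_AA) / (e_RR + e_RA + e_AA + m_RA + m_AA), with
    e_t the off-diagonal (discordant) count of truth class t and m the
    concordant het / hom-alt counts. Concordant hom-ref calls do not enter
    the denominator, so NRD is invariant to adding any number of them.
    NaN when the denominator is zero.
    """
    c = confusion.counts
    errors = int(c.sum() - np.trace(c))
    matches_nonref = int(c[1, 1] + c[2, 2])
    denom = errors + matches_nonref
    return float(errors) / denom if denom > 0 else np.nan


def r2(truth: np.ndarray, imputed_values: np.ndarray) -> float:
    """Squared Pearson correlation; NaN if either vector is constant or
    fewer than two sites are compared."""
    t = np.asarray(truth, dtype=float)
    v = np.asarray(imputed_values, dtype=float)
    if t.size < 2 or np.ptp(t) == 0 or np.ptp(v) == 0:
        return np.nan
    r = np.corrcoef(t, v)[0, 1]
    return float(r * r)


def r2_by_bin(truth: CallSet, imputed: CallSet,
              edges: Sequence[float] = DEFAULT_MAF_EDGES,
              info_cutoffs: Sequence[float | None] = DEFAULT_INFO_CUTOFFS,
              transversions_only: bool = False,
              sample: str | None = None) -> pd.DataFrame:
    """Concordance report per (MAF bin x INFO cutoff).

    r² correlates truth genotype codes with imputed dosages when the
    imputed call set carries DS, falling back to hard genotype codes
    otherwise. Error rates and NRD are computed from hard calls. Sites
    missing in the truth are excluded throughout (the truth is the set of
    confidently called genotypes, not an error-free oracle of the whole
    genome).

    Returns a tidy DataFrame with one row per (bin, cutoff).
    """
    si = 0 if sample is None else truth.sample_index(sample)
    sj = 0 if sample is None else imputed.sample_index(sample)
    if len(truth.sites) != len(imputed.sites):
        raise ValueError("truth and imputed site tables are not congruent")

    t_gt = truth.genotypes[si]
    i_gt = imputed.genotypes[sj]
    values = (imputed.dosage[sj] if imputed.dosage is not None
              else i_gt.astype(float))
    maf = imputed.sites["maf"].to_numpy()
    bins = assign_maf_bin(maf, edges)
    info = (np.asarray(imputed.info) if imputed.info is not None
            else np.ones(len(maf)))
    base_ok = (t_gt != MISSING) & (i_gt != MISSING)
    if transversions_only:
        base_ok &= imputed.sites["transversion"].to_numpy().astype(bool)

    rows = []
    edges = np.asarray(edges, dtype=float)
    for cutoff in info_cutoffs:
        ok_cut = base_ok if cutoff is None else base_ok & (info >= cutoff)
        for b in range(len(edges) - 1):
            mask = ok_cut & (bins == b)
            n = int(mask.sum())
            conf = genotype_confusion(t_gt, i_gt, site_mask=mask)
            e0, e1, e2 = error_rates(conf)
            r2_val = r2(t_gt[mask], values[mask]) if n >= 2 else np.nan
            rows.append({
                "maf_lo": edges[b], "maf_hi": edges[b + 1],
                "info_cutoff": np.nan if cutoff is None else cutoff,
                "r2": r2_val, "r2_defined": bool(np.isfinite(r2_val)),
                "error_homref": e0, "error_het": e1, "error_homalt": e2,
                "nrd": nrd(conf), "n_sites": n,
            })
    return pd.DataFrame(rows)
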