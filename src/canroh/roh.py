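"""Runs-of-homozygosity calling and F_ROH estimation.

The caller is a sliding-window scan in the style of PLINK ``--homozyg``:

1. slide a window of ``window_snp`` consecutive SNPs along each chromosome;
   a window is a *hit* when it contains at most ``window_het`` heterozygous
   and at most ``window_missing`` missing calls;
2. each SNP's hit proportion is the fraction of hits among the windows that
   cover it; the SNP is homozygous-eligible when that proportion reaches
   ``hit_threshold``;
3. maximal runs of eligible SNPs, split wherever adjacent SNPs are more
   than ``max_gap`` bp apart, become segments if they contain at least
   ``min_snp`` SNPs, span at least ``min_kb`` kb, and are dense enough
   (at most ``min_density`` bp per SNP).

Segment coordinates run from the first to the last SNP of the run, the
convention of the reference tool. The scan sees only the SNPs it is given:
genotyping density directly bounds the resolution of segment boundaries.

F_ROH is the fraction of the autosomal genome covered by ROH; the short /
long partition at 1.6 Mb separates background relatedness (short, older
coalescence) from recent inbreeding (long).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from canroh import intervals
from canroh.variant_io import MISSING

#: boundary between short and long ROH, bp
LENGTH_CLASS_SPLIT = 1_600_000

#: F_ROH above this marks a sample as highly inbred
HIGH_INBREEDING_THRESHOLD = 0.1


@dataclasses.dataclass
class ROHParams:
    """Scan parameters; defaults are the reference tool's published defaults.

    min_kb and max_gap are in kilobases, min_density in kb per SNP,
    mirroring the conventions users know from PLINK.
    """

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    hit_threshold: float = 0.05
    min_snp: int = 100
    min_kb: float = 1000.0
    min_density: float = 50.0
    max_gap: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must be in (0, 1]")
        for name in ("window_snp", "window_het", "window_missing", "min_snp",
                     "min_kb", "min_density", "max_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _eligible_snps(genotypes: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean homozygous-eligibility per SNP on one chromosome."""
    m = len(genotypes)
    W = params.window_snp
    if m < W:
        return np.zeros(m, dtype=bool)
    het = (genotypes == 1).astype(np.int64)
    mis = (genotypes == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - W + 1
    het_in = chet[W:] - chet[:-W]
    mis_in = cmis[W:] - cmis[:-W]
    hit = ((het_in <= params.window_het)
           & (mis_in <= params.window_missing)).astype(np.int64)
    chit = np.concatenate([[0], np.cumsum(hit)])
    j = np.arange(m)
    lo = np.maximum(0, j - W + 1)
    hi = np.minimum(j, n_win - 1)
    covering = hi - lo + 1
    hits = chit[hi + 1] - chit[lo]
    return hits >= params.hit_threshold * covering


def call_roh(genotypes: np.ndarray, site_table: pd.DataFrame,
             params: ROHParams | None = None) -> pd.DataFrame:
    """Call ROH segments for one sample.

    Parameters
    ----------
    genotypes : array of shape (n_sites,), codes 0/1/2 and -1 for missing
    site_table : DataFrame with chrom and pos, sorted within chromosome
    params : ROHParams

    Returns
    -------
    Segment table (chrom, start, end, n_snps), 0-based half-open, end at
    last SNP position + 1.
    """
    params = params or ROHParams()
    genotypes = np.asarray(genotypes).ravel()
    if len(genotypes) != len(site_table):
        raise ValueError("genotypes and site table differ in length")
    site_table = site_table.reset_index(drop=True)
    min_bp = params.min_kb * 1000.0
    max_gap_bp = params.max_gap * 1000.0
    density_bp = params.min_density * 1000.0

    rows = []
    for chrom, sub in site_table.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"sites on {chrom} are not sorted by position")
        g = genotypes[sub.index.to_numpy()]
        eligible = _eligible_snps(g, params)
        # maximal runs of eligible SNPs, split at large gaps
        j = 0
        m = len(pos)
        while j < m:
            if not eligible[j]:
                j += 1
                continue
            k = j
            while (k + 1 < m and eligible[k + 1]
                   and pos[k + 1] - pos[k] <= max_gap_bp):
                k += 1
            n_snps = k - j + 1
            length = pos[k] - pos[j] + 1
            if (n_snps >= params.min_snp and length >= min_bp
                    and length / n_snps <= density_bp):
                rows.append((chrom, int(pos[j]), int(pos[k]) + 1, n_snps))
            j = k + 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def froh(roh_set: pd.DataFrame, autosome_length_total: int,
         length_class: str = "all") -> float:
    """Genomic inbreeding coefficient F_ROH.

    F_ROH = total length of ROH segments in the class / autosome length.
    length_class: "all", "short" (< 1.6 Mb) or "long" (>= 1.6 Mb).
    """
    if autosome_length_total <= 0:
        raise ValueError("autosome_length_total must be > 0")
    if len(roh_set) == 0:
        return 0.0
    lengths = (roh_set["end"] - roh_set["start"]).to_numpy(dtype=np.int64)
    if length_class == "all":
        sel = np.ones(len(lengths), dtype=bool)
    elif length_class == "short":
        sel = lengths < LENGTH_CLASS_SPLIT
    elif length_class == "long":
        sel = lengths >= LENGTH_CLASS_SPLIT
    else:
        raise ValueError(f"unknown length class {length_class!r}")
    return float(lengths[sel].sum()) / float(autosome_length_total)


def summarize_roh(roh_set: pd.DataFrame,
                  autosome_length_total: int | None = None) -> dict:
    """Summary of a sample's ROH: counts, total and maximum length, and —
    when the autosome length is supplied — F_ROH by class plus a
    highly-inbred flag (F_ROH > 0.1)."""
    if len(roh_set) == 0:
        out = {"n_segments": 0, "total_bp": 0, "max_bp": 0}
    else:
        lengths = (roh_set["end"] - roh_set["start"]).to_numpy(dtype=np.int64)
        out = {"n_segments": int(len(lengths)),
               "total_bp": int(lengths.sum()),
               "max_bp": int(lengths.max())}
    if autosome_length_total is not None:
        out["froh_all"] = froh(roh_set, autosome_length_total, "all")
        out["froh_short"] = froh(roh_set, autosome_length_total, "short")
        out["froh_long"] = froh(roh_set, autosome_length_total, "long")
        out["highly_inbred"] = out["froh_all"] > HIGH_INBREEDING_THRESHOLD
    return out


def roh_by_sample(segments: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a multi-sample segment table (with a 'sample' column) into
    per-sample segment tables."""
    return {s: intervals.as_segments(sub)
            for s, sub in segments.groupby("sample", sort=True)}
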