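"""Exact integer interval arithmetic on genomic segment tables.

Segment tables are pandas DataFrames with columns ``chrom``, ``start``,
``end`` (0-based half-open, integer bp) and optionally per-segment payload
columns such as ``n_snps`` or ``sample``. All set operations here merge
their inputs first, so outputs are always sorted and non-overlapping, and
lengths are conserved exactly in integer base pairs — the ROH benchmark
relies on that exactness.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

SEGMENT_COLUMNS = ["chrom", "start", "end"]


def empty_segments() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series([], dtype=object),
                         "start": pd.Series([], dtype=np.int64),
                         "end": pd.Series([], dtype=np.int64)})


def as_segments(df: pd.DataFrame | None) -> pd.DataFrame:
    """Validate and normalize a segment table (sorted by chrom, start)."""
    if df is None or len(df) == 0:
        return empty_segments()
    out = df[SEGMENT_COLUMNS].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["end"] <= out["start"]).any():
        raise ValueError("segments must have end > start")
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def merge(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: sorted, non-overlapping (touching intervals fuse)."""
    df = as_segments(df)
    if len(df) == 0:
        return df
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def total_length(df: pd.DataFrame) -> int:
    """Total bp covered (input is merged first, so overlaps count once)."""
    m = merge(df)
    if len(m) == 0:
        return 0
    return int((m["end"] - m["start"]).sum())


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Set intersection of two interval sets."""
    a, b = merge(a), merge(b)
    rows = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        sa = a[a["chrom"] == chrom]
        sb = b[b["chrom"] == chrom]
        i = j = 0
        A = sa[["start", "end"]].to_numpy()
        B = sb[["start", "end"]].to_numpy()
        while i < len(A) and j < len(B):
            s = max(A[i, 0], B[j, 0])
            e = min(A[i, 1], B[j, 1])
            if s < e:
                rows.append((chrom, int(s), int(e)))
            if A[i, 1] <= B[j, 1]:
                i += 1
            else:
                j += 1
    if not rows:
        return empty_segments()
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def subtract(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intervals of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    rows = []
    for chrom, sa in a.groupby("chrom", sort=True):
        sb = b[b["chrom"] == chrom]
        B = sb[["start", "end"]].to_numpy()
        for s, e in sa[["start", "end"]].to_numpy():
            cur = int(s)
            for bs, be in B:
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    rows.append((chrom, cur, int(bs)))
                cur = max(cur, int(be))
                if cur >= e:
                    break
            if cur < e:
                rows.append((chrom, cur, int(e)))
    if not rows:
        return empty_segments()
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def clip_to(df: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Clip intervals to a region set (= intersection)."""
    return intersect(df, regions)


def concat(parts: Iterable[pd.DataFrame]) -> pd.DataFrame:
    parts = [p for p in parts if p is not None and len(p)]
    if not parts:
        return empty_segments()
    return as_segments(pd.concat(parts, ignore_index=True))


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open) into a segment table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=SEGMENT_COLUMNS,
                     dtype={"chrom": str})
    return as_segments(df)


def write_bed(df: pd.DataFrame, path) -> None:
    as_segments(df).to_csv(path, sep="\t", header=False, index=False)
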