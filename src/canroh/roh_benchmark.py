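"""Scoring a called ROH set against a truth ROH set.

Two confusion bases are supported:

* **length basis** — exact interval arithmetic in integer bp over an
  assayable-region set: tp = |truth ∩ test|, fp = |test \\ truth|,
  fn = |truth \\ test|, tn = the remaining assayable length. The four
  counts conserve the assayable length exactly.
* **segment basis** — a truth segment overlapped (>= 1 bp, or an optional
  reciprocal-overlap fraction) by any test segment is a tp, otherwise a
  fn; a test segment with no truth overlap is a fp. True negatives are
  undefined on this basis; an optional convention counts truth gaps with
  no test overlap, which is off by default and clearly marked.

From the confusion come F1, Matthews correlation (MCC), its normalized
form nMCC = (MCC + 1) / 2, sensitivity, specificity and FDR. Statistics
with empty denominators are NaN (undefined), never silently 0.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from canroh import intervals


@dataclasses.dataclass
class IntervalConfusion:
    """tp/fp/tn/fn in bp (basis='length') or segment counts ('segments').

    tn is NaN on the segment basis unless the gap convention is used.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    basis: str = "length"


def interval_confusion_bp(truth_set: pd.DataFrame, test_set: pd.DataFrame,
                          assayable_regions: pd.DataFrame) -> IntervalConfusion:
    """Length-basis confusion by exact interval arithmetic (integer bp)."""
    assayable = intervals.merge(assayable_regions)
    if len(assayable) == 0:
        raise ValueError("assayable regions are empty")
    truth = intervals.clip_to(truth_set, assayable)
    test = intervals.clip_to(test_set, assayable)
    tp = intervals.total_length(intervals.intersect(truth, test))
    fp = intervals.total_length(intervals.subtract(test, truth))
    fn = intervals.total_length(intervals.subtract(truth, test))
    tn = intervals.total_length(assayable) - tp - fp - fn
    return IntervalConfusion(tp=tp, fp=fp, tn=tn, fn=fn, basis="length")


def _overlap_hits(a: pd.DataFrame, b: pd.DataFrame,
                  min_reciprocal: float = 0.0) -> np.ndarray:
    """For each segment of ``a``: does any segment of ``b`` overlap it
    (by >= 1 bp, or by >= min_reciprocal of both lengths)?"""
    a = intervals.as_segments(a)
    b = intervals.as_segments(b)
    hits = np.zeros(len(a), dtype=bool)
    for i, (chrom, s, e) in enumerate(
            a[["chrom", "start", "end"]].itertuples(index=False)):
        sub = b[b["chrom"] == chrom]
        ov = np.minimum(sub["end"].to_numpy(), e) \
            - np.maximum(sub["start"].to_numpy(), s)
        if min_reciprocal > 0:
            la = e - s
            lb = (sub["end"] - sub["start"]).to_numpy()
            ok = (ov >= min_reciprocal * la) & (ov >= min_reciprocal * lb)
        else:
            ok = ov > 0
        hits[i] = bool(ok.any())
    return hits


def segment_confusion(truth_set: pd.DataFrame, test_set: pd.DataFrame,
                      min_reciprocal: float = 0.0,
                      tn_from_gaps: bool = False) -> IntervalConfusion:
    """Segment-basis confusion under the any-overlap rule.

    With ``tn_from_gaps`` the gaps between consecutive truth segments (per
    chromosome) that no test segment touches are counted as tn — an
    artifact convention enabling a segment-basis nMCC, not a standard
    definition; off by default.
    """
    truth = intervals.as_segments(truth_set)
    test = intervals.as_segments(test_set)
    truth_hit = _overlap_hits(truth, test, min_reciprocal)
    test_hit = _overlap_hits(test, truth, min_reciprocal)
    tp = int(truth_hit.sum())
    fn = int((~truth_hit).sum())
    fp = int((~test_hit).sum())
    tn: float = math.nan
    if tn_from_gaps:
        gaps = []
        for chrom, sub in truth.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            for gs, ge in zip(ends[:-1], starts[1:]):
                if ge > gs:
                    gaps.append((chrom, int(gs), int(ge)))
        if gaps:
            gap_df = pd.DataFrame(gaps, columns=["chrom", "start", "end"])
            tn = int((~_overlap_hits(gap_df, test)).sum())
        else:
            tn = 0
    return IntervalConfusion(tp=tp, fp=fp, tn=tn, fn=fn, basis="segments")


def overlap_scores(confusion: IntervalConfusion) -> dict[str, float]:
    """F1, MCC, nMCC, sensitivity, specificity and FDR from a confusion.

    Undefined statistics (zero denominator, or tn unavailable) are NaN.
    """
    tp, fp, tn, fn = (float(confusion.tp), float(confusion.fp),
                      float(confusion.tn), float(confusion.fn))

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    sensitivity = ratio(tp, tp + fn)
    fdr = ratio(fp, tp + fp)
    if math.isnan(tn):
        specificity = mcc = nmcc = math.nan
    else:
        specificity = ratio(tn, tn + fp)
        denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = (tp * tn - fp * fn) / denom if denom > 0 else math.nan
        nmcc = (mcc + 1.0) / 2.0 if not math.isnan(mcc) else math.nan
    return {"f1": f1, "mcc": mcc, "nmcc": nmcc,
            "sensitivity": sensitivity, "specificity": specificity,
            "fdr": fdr}


def score_sets(truth_set: pd.DataFrame, test_set: pd.DataFrame,
               assayable_regions: pd.DataFrame,
               basis: str = "length", **kwargs) -> dict[str, float]:
    """Convenience wrapper: confusion + scores on the chosen basis."""
    if basis == "length":
        conf = interval_confusion_bp(truth_set, test_set, assayable_regions)
    elif basis == "segments":
        conf = segment_confusion(truth_set, test_set, **kwargs)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    scores = overlap_scores(conf)
    scores.update(tp=conf.tp, fp=conf.fp, tn=conf.tn, fn=conf.fn,
                  basis=basis)
    return scores
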