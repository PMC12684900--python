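"""Windowed ROH landscape: prevalence, window QC, deserts, randomization.

The genome is tiled into fixed-width windows (default 500 kb). For each
sample a window is *occupied* when at least 1 bp of one of its ROH
segments overlaps the window. Cohort frequencies (ancient / modern) are
the fraction of samples occupying each window.

Window QC removes windows whose mean depth of coverage falls outside
mean ± k·SD (k = 2 by default, genome-wide sample SD) and windows
overlapping a copy-number-variant mask, since collapsed repeats and CNVs
produce artifactual homozygosity signals.

An *ROH desert* is an included window where both cohorts' frequencies are
strictly below a cutoff (default 5%). Whether the observed number of
shared deserts is surprising is assessed by a randomization test whose
null places every sample's occupied windows uniformly at random among the
included windows — preserving each sample's number of occupied windows,
independently across samples and cohorts. The one-sided p-value uses the
standard +1 correction: p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from canroh import _rng, intervals

DEFAULT_WINDOW_BP = 500_000
DEFAULT_DESERT_CUTOFF = 0.05


@dataclasses.dataclass
class DesertTestResult:
    observed_desert_count: int
    null_counts: np.ndarray
    p_value: float
    n_perm: int


def make_windows(chrom_lengths: dict[str, int],
                 width: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Tile each chromosome with fixed-width windows; last one truncated.

    Returns a DataFrame (chrom, start, end, window) where ``window`` is a
    global 0-based index.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    rows = []
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, L, width, dtype=np.int64)
        ends = np.minimum(starts + width, L)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": ends}))
    grid = pd.concat(rows, ignore_index=True)
    grid["window"] = np.arange(len(grid))
    return grid


def filter_windows(grid: pd.DataFrame, depths: np.ndarray,
                   cnv_mask: pd.DataFrame | None = None,
                   k_sd: float = 2.0,
                   cnv_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Flag windows passing depth and CNV QC.

    A window is included when its depth lies within mean ± k_sd·SD (mean
    and sample SD computed genome-wide over all windows) and it does not
    overlap the CNV mask by >= cnv_overlap_fraction of its length.

    Returns a copy of the grid with ``depth`` and ``included`` columns.
    """
    depths = np.asarray(depths, dtype=float)
    if len(depths) != len(grid):
        raise ValueError("depths are not aligned to the window grid")
    mean = depths.mean()
    sd = depths.std(ddof=1)
    ok = (depths >= mean - k_sd * sd) & (depths <= mean + k_sd * sd)
    if cnv_mask is not None and len(cnv_mask):
        mask = intervals.merge(cnv_mask)
        for i, (chrom, s, e) in enumerate(
                grid[["chrom", "start", "end"]].itertuples(index=False)):
            sub = mask[mask["chrom"] == chrom]
            ov = np.maximum(0, np.minimum(sub["end"].to_numpy(), e)
                            - np.maximum(sub["start"].to_numpy(), s)).sum()
            if ov >= cnv_overlap_fraction * (e - s):
                ok[i] = False
    if not ok.any():
        raise ValueError("window QC excluded every window")
    out = grid.copy()
    out["depth"] = depths
    out["included"] = ok
    return out


def window_indicators(roh_sets: dict[str, pd.DataFrame],
                      grid: pd.DataFrame) -> pd.DataFrame:
    """Sample × window occupancy matrix (>= 1 bp of ROH in the window).

    Returns a boolean DataFrame indexed by sample, columns = window index.
    """
    n_win = len(grid)
    out = {}
    chrom_groups = {c: sub for c, sub in grid.groupby("chrom", sort=False)}
    for sample, segs in roh_sets.items():
        ind = np.zeros(n_win, dtype=bool)
        segs = intervals.as_segments(segs)
        for chrom, s, e in segs[["chrom", "start", "end"]] \
                .itertuples(index=False):
            sub = chrom_groups.get(chrom)
            if sub is None:
                raise ValueError(f"segment on unknown chromosome {chrom!r}")
            hit = (sub["start"].to_numpy() < e) & (sub["end"].to_numpy() > s)
            ind[sub["window"].to_numpy()[hit]] = True
        out[sample] = ind
    return pd.DataFrame.from_dict(out, orient="index",
                                  columns=grid["window"].to_numpy())


def cohort_frequencies(indicators: pd.DataFrame,
                       labels: pd.DataFrame) -> pd.DataFrame:
    """Per-window occupancy frequency for each cohort in ``labels``
    (columns sample, group)."""
    freq = {}
    for group, sub in labels.groupby("group", sort=True):
        members = [s for s in sub["sample"] if s in indicators.index]
        if not members:
            raise ValueError(f"no indicator rows for group {group!r}")
        freq[f"freq_{group}"] = indicators.loc[members].mean(axis=0).to_numpy()
    return pd.DataFrame(freq)


def find_deserts(grid: pd.DataFrame, freqs: pd.DataFrame,
                 cutoff: float = DEFAULT_DESERT_CUTOFF) -> pd.DataFrame:
    """Desert windows: included, with every cohort frequency strictly below
    the cutoff. Returns the grid rows flagged, with a ``desert`` column."""
    if "included" not in grid.columns:
        raise ValueError("grid must carry an 'included' column (run QC first)")
    below = np.ones(len(grid), dtype=bool)
    for col in freqs.columns:
        below &= freqs[col].to_numpy() < cutoff
    out = grid.copy()
    for col in freqs.columns:
        out[col] = freqs[col].to_numpy()
    out["desert"] = below & grid["included"].to_numpy()
    return out


def _desert_count(occ_a: np.ndarray, occ_b: np.ndarray,
                  cutoff: float) -> int:
    """Count windows where both cohorts' frequencies are below cutoff.
    occ_* are (n_samples, n_windows) boolean matrices over included
    windows only."""
    fa = occ_a.mean(axis=0)
    fb = occ_b.mean(axis=0)
    return int(((fa < cutoff) & (fb < cutoff)).sum())


def desert_randomization_test(indicators_ancient: np.ndarray,
                              indicators_modern: np.ndarray,
                              cutoff: float = DEFAULT_DESERT_CUTOFF,
                              n_perm: int = 999,
                              seed: int = 0) -> DesertTestResult:
    """Randomization test for an excess of shared ROH-desert windows.

    The inputs are boolean occupancy matrices restricted to QC-included
    windows. Each permutation reassigns every sample's occupied windows to
    a uniform random subset (of the same size) of the included windows,
    independently per sample; the desert count is recomputed and compared
    one-sidedly against the observed count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    occ_a = np.asarray(indicators_ancient, dtype=bool)
    occ_b = np.asarray(indicators_modern, dtype=bool)
    if occ_a.ndim != 2 or occ_b.ndim != 2 or occ_a.shape[1] != occ_b.shape[1]:
        raise ValueError("indicator matrices must be 2D with equal window "
                         "dimension")
    n_win = occ_a.shape[1]
    counts_a = occ_a.sum(axis=1)
    counts_b = occ_b.sum(axis=1)
    if counts_a.max(initial=0) > n_win or counts_b.max(initial=0) > n_win:
        raise ValueError("per-sample occupied-window count exceeds the "
                         "number of included windows")
    observed = _desert_count(occ_a, occ_b, cutoff)

    rng = _rng.substream(seed, _rng.OP_PERMTEST)
    both = np.vstack([occ_a, occ_b])
    ks = both.sum(axis=1)
    n_a = occ_a.shape[0]
    null_counts = np.empty(n_perm, dtype=np.int64)
    first_k = np.arange(n_win)[None, :] < ks[:, None]
    perm = np.empty_like(both)
    for p in range(n_perm):
        # per-row uniform k-subset: mark the k smallest of iid uniforms
        order = rng.random(both.shape).argsort(axis=1)
        np.put_along_axis(perm, order, first_k, axis=1)
        null_counts[p] = _desert_count(perm[:n_a], perm[n_a:], cutoff)
    p_value = (1.0 + (null_counts >= observed).sum()) / (1.0 + n_perm)
    return DesertTestResult(observed_desert_count=observed,
                            null_counts=null_counts, p_value=p_value,
                            n_perm=n_perm)


def circular_shift_null(indicators: np.ndarray, rng: np.random.Generator
                        ) -> np.ndarray:
    """Contiguity-preserving alternative null: each sample's indicator
    vector is circularly shifted by an independent uniform offset. Offered
    for sensitivity analysis; the primary null ignores contiguity."""
    occ = np.asarray(indicators, dtype=bool)
    out = np.empty_like(occ)
    n_win = occ.shape[1]
    for i in range(occ.shape[0]):
        out[i] = np.roll(occ[i], int(rng.integers(n_win)))
    return out
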