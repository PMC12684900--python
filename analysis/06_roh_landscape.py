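"""Windowed ROH landscape, desert detection and the randomization test.

Tiles the genome into 500 kb windows, drops windows failing the
mean +- 2 SD depth QC, computes per-window ROH occupancy frequencies for
the two cohorts, flags deserts (< 5% occupancy in both cohorts), and asks
whether the number of shared desert windows exceeds what uniform,
independent placement of each sample's ROH windows would produce.
Writes results/landscape_windows.tsv and results/landscape_test.json.

Run from the repository root:  python analysis/06_roh_landscape.py
"""

import json
import sys
from pathlib import Path

import numpy as np

from canroh import landscape, roh, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    chrom_lengths = {f"chr{i+1}": 50_000_000 for i in range(4)}
    grid = landscape.make_windows(chrom_lengths, 500_000)

    # designate shared protected deserts and hotspots, then simulate
    rng = np.random.default_rng(SEED)
    chosen = rng.choice(len(grid), size=40, replace=False)
    desert_windows, hotspot_windows = np.sort(chosen[:20]), np.sort(chosen[20:])
    segments, labels = simulate.simulate_cohorts(
        n_ancient=30, n_modern=30, froh_ancient=0.05, froh_modern=0.30,
        window_grid=grid, hotspot_windows=hotspot_windows,
        desert_windows=desert_windows, seed=SEED)

    depths = simulate.simulate_window_depths(grid, outlier_fraction=0.02,
                                             seed=SEED)
    qc = landscape.filter_windows(grid, depths)
    indicators = landscape.window_indicators(roh.roh_by_sample(segments), qc)
    freqs = landscape.cohort_frequencies(indicators, labels)
    windows = landscape.find_deserts(qc, freqs)
    windows.to_csv(OUT / "landscape_windows.tsv", sep="\t", index=False)

    included = qc["included"].to_numpy()
    occ = {g: indicators.loc[labels.loc[labels["group"] == g, "sample"]]
           .to_numpy()[:, included] for g in ("ancient", "modern")}
    res = landscape.desert_randomization_test(occ["ancient"], occ["modern"],
                                              n_perm=999, seed=SEED)

    n_inc = int(included.sum())
    n_des = int(windows["desert"].sum())
    recovered = int(windows.loc[desert_windows, "desert"].sum())
    print(f"windows: {len(grid)} total, {n_inc} pass depth QC")
    print(f"deserts: {n_des} ({n_des / n_inc:.1%} of included windows); "
          f"{recovered}/{len(desert_windows)} designated deserts recovered")
    print(f"randomization test: observed {res.observed_desert_count} vs "
          f"null mean {res.null_counts.mean():.1f} -> "
          f"p = {res.p_value:.4g} ({res.n_perm} permutations)")
    (OUT / "landscape_test.json").write_text(json.dumps({
        "n_windows": len(grid), "n_included": n_inc, "n_deserts": n_des,
        "desert_fraction_of_included": n_des / n_inc,
        "observed_desert_count": res.observed_desert_count,
        "null_mean": float(res.null_counts.mean()),
        "p_value": res.p_value, "n_perm": res.n_perm}, indent=2))
    print(f"wrote {OUT}/landscape_windows.tsv and {OUT}/landscape_test.json")


if __name__ == "__main__":
    main()
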