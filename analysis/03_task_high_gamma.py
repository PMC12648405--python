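#!/usr/bin/env python
"""Task-related high-gamma enhancement across bipolar distances.

Simulates a recording in which stimulus intervals boost 50–200 Hz power
by 50% on a designated electrode subset, computes the stimulus-minus-
baseline contrast over frequency × distance with a cluster permutation
mask, and writes the per-bin high-gamma curve to results/task/.
"""
from pathlib import Path

import numpy as np

import bprr
from bprr.montage import bin_pairs_by_distance, enumerate_omnidirectional_pairs
from bprr.preprocess import notch_line_noise, parse_baseline_windows
from bprr.task import (cluster_permutation_map, condition_difference_map,
                       high_gamma_metric, restrict_pairs)

RESULTS = Path(__file__).resolve().parents[1] / "results" / "task"
SEED = 0


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    array = bprr.make_geometry("grid1x16")
    array.table["subset"] = 1  # the whole row plays the designated cortical subset
    config = bprr.reference_field_config(seed=SEED)
    rec = bprr.simulate_field(array, config, duration_s=120.0, fs=512.0)
    stim = [(10.0 + k * 20.0, 20.0 + k * 20.0) for k in range(5)]
    rec, ann = bprr.inject_task_modulation(rec, array.contact_ids, stim,
                                           gain_band=(50.0, 200.0), gain=1.5,
                                           seed=SEED + 1)
    rec = notch_line_noise(rec)
    windows = parse_baseline_windows(rec, ann)
    pairs = bin_pairs_by_distance(enumerate_omnidirectional_pairs(array))
    pairs = restrict_pairs(pairs, array.table, max_distance_mm=40.0)

    contrast = condition_difference_map(windows, pairs, zscore=False)
    result = cluster_permutation_map(contrast, n_perm=500, seed=SEED)
    hg = high_gamma_metric(contrast)

    contrast.diff_map.to_tsv(RESULTS / "task_diff_map.tsv")
    contrast.sig_mask.to_tsv(RESULTS / "task_sig_mask.tsv")
    occupied = ~np.isnan(hg)
    with open(RESULTS / "high_gamma_by_distance.tsv", "w") as fh:
        fh.write("bin_center_mm\thigh_gamma_log_diff\n")
        for c, v in zip(contrast.bin_centers_mm[occupied], hg[occupied]):
            fh.write(f"{c:g}\t{v:.6f}\n")

    n_stim = (windows.labels == "stimulus").sum()
    n_base = (windows.labels == "baseline").sum()
    print(f"{n_stim} stimulus vs {n_base} baseline windows, {len(pairs)} pairs <= 40 mm")
    print(f"high-gamma contrast positive at {np.sum(hg[occupied] > 0)}/{occupied.sum()} bins"
          f" (range {hg[occupied].min():.3f} .. {hg[occupied].max():.3f} log10 units)")
    print(f"significant clusters: {int(np.sum(result.cluster_pvalues <= 0.05))} "
          f"(smallest p = {result.min_pvalue:.3f})")


if __name__ == "__main__":
    main()
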