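#!/usr/bin/env python
"""Distance-frequency relation maps on the reference configuration.

Runs the full chain (simulate → filter/downsample/notch → omnidirectional
bipolar montage → multitaper spectra → maps) and writes the z-scored
√-power map and the percent-change map to results/maps/.  Prints the
crescent-shape summary: low frequencies attenuated at the 4 mm bin, all
frequencies enhanced from 16 mm outward.
"""
import shutil
from pathlib import Path

import numpy as np

from bprr.maps import DistanceFrequencyMap
from bprr.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "maps"
SEED = 0


def main() -> None:
    cfg = PipelineConfig(geometry="grid1x16", duration_s=120.0, sim_fs=3052.0, seed=SEED)
    # the run directory holds the bulky intermediates; only the maps are results
    run_dir = run_pipeline(cfg, ROOT / "scratch" / "maps_run")
    RESULTS.mkdir(parents=True, exist_ok=True)
    for name in ("map_percent_change.tsv", "map_zscored_sqrt_power.tsv",
                 "n_pairs_per_bin.tsv"):
        shutil.copy2(run_dir / name, RESULTS / name)
    pc = DistanceFrequencyMap.from_tsv(run_dir / "map_percent_change.tsv")
    f = pc.frequencies
    v4 = pc.values[:, 1]
    low = v4[(f >= 2) & (f <= 20)]
    high = v4[f > 30]
    far = pc.values[:, pc.bin_centers_mm >= 16]
    print(f"maps in {run_dir}")
    print(f"4 mm bin, 2-20 Hz:  percent change {low.min():.1f} .. {low.max():.1f} "
          f"(attenuation at short distance)")
    print(f"4 mm bin, >30 Hz:   percent change {high.min():.1f} .. {high.max():.1f} "
          f"(high frequencies already enhanced)")
    print(f"bins >= 16 mm:      minimum percent change {np.nanmin(far):.1f} "
          f"(enhancement at all frequencies)")


if __name__ == "__main__":
    main()
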