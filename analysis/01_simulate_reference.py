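#!/usr/bin/env python
"""Generate the reference synthetic dataset.

A 16-contact, 4 mm-pitch grid row records two minutes of the reference
field: traveling waves at 4–28 Hz (v = 0.72 m/s, partially coherent),
an aperiodic field above 30 Hz with 4 mm coherence length, and
common-mode line noise.  The raw recording (float32 binary + sidecar)
goes to scratch/reference_dataset/; the electrode and annotation tables
are small TSVs alongside it.
"""
from pathlib import Path

import bprr
from bprr.io import write_binary_recording

OUT = Path(__file__).resolve().parents[1] / "scratch" / "reference_dataset"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    array = bprr.make_geometry("grid1x16")
    config = bprr.reference_field_config(seed=SEED)
    rec = bprr.simulate_field(array, config, duration_s=120.0, fs=3052.0)
    array.to_tsv(OUT / "electrodes.tsv")
    write_binary_recording(rec, OUT / "referential.bin")
    print(f"simulated {rec.n_channels} channels x {rec.duration_s:.0f} s "
          f"at {rec.fs:.0f} Hz -> {OUT}")
    print(f"wave components: {[w.frequency_hz for w in config.waves]} Hz, "
          f"aperiodic {config.aperiodic.band_hz} Hz (l = {config.aperiodic.coherence_mm} mm)")


if __name__ == "__main__":
    main()
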