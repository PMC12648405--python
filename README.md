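# bprr — bipolar re-referencing distance effects on intracranial EEG

Bipolar re-referencing (BPRR) — subtracting one intracranial electrode's
referential trace from a neighbor's — is the default montage for clinical and
research iEEG, yet the inter-electrode distance it is built on is usually
whatever the manufacturer shipped. Distance is not neutral: BPRR approximates
the first spatial derivative of the cortical field, so its effect on measured
power depends jointly on frequency and electrode separation. This package
implements a systematic evaluation of that dependence: montage construction at
controlled distances, multitaper spectral analysis, distance–frequency relation
maps, task-contrast statistics, and line-length detection of interictal
epileptiform discharges (IEDs) — together with a synthetic multi-electrode
field generator whose bipolar/referential power ratios are known in closed
form, so the entire chain can be validated analytically.

It is intended for iEEG researchers choosing re-referencing distances for
spectral biomarkers, and for anyone who wants a tested, deterministic pipeline
from referential recordings (or simulations) to distance–frequency maps.

## The model

For a plane traveling wave of temporal frequency *f* and propagation speed
*v*, the spatial wavelength is λ(f) = v/f. Two electrodes separated by *d*
along the propagation axis see the wave with spatial phase offset 2πd/λ, so
the bipolar-to-referential power ratio is

    R(d) = 4 sin²(π d cosθ / λ),

with θ the angle between the pair axis and the propagation direction. R < 1
(attenuation) for d < λ/6, R = 1 at d = λ/6, and R rises to 4 at d = λ/2.
With v = 0.72 m/s this places the reversal at **8 mm** for λ = 48 mm, and for
a fixed 4 mm pair the attenuation→amplification crossing at **30 Hz** — the
two transition points the analysis is organized around. Spatially incoherent
(aperiodic) activity with correlation exp(−d/ℓ) instead gives
R(d) = 2(1 − e^(−d/ℓ)) → 2, so high frequencies are *enhanced* by BPRR at
every distance. The superposition of the two regimes produces the
characteristic crescent-shaped distance–frequency map: low frequencies
suppressed at short distances, everything enhanced far out.

## Worked example

```
$ python analysis/02_distance_frequency_maps.py
maps in .../scratch/maps_run
4 mm bin, 2-20 Hz:  percent change -37.9 .. -25.1 (attenuation at short distance)
4 mm bin, >30 Hz:   percent change 7.2 .. 13.8 (high frequencies already enhanced)
bins >= 16 mm:      minimum percent change 5.4 (enhancement at all frequencies)
```

This simulates two minutes of a 16-contact, 4 mm-pitch grid row under the
reference field configuration (traveling waves at 4–28 Hz, aperiodic activity
above 30 Hz with ℓ = 4 mm, common-mode line noise), runs
filter → downsample → notch → omnidirectional bipolar montage → multitaper
spectra, and bins percent power change by pair distance. The printed numbers
are the crescent shape: at the 4 mm bin every frequency up to 20 Hz loses
25–38% of √-power relative to the contributing referential electrodes, while
everything above 30 Hz already gains 7–14%; from 16 mm outward every frequency
is enhanced. The full maps (199 frequencies × 29 two-millimeter distance bins)
are written as TSV under `results/maps/`.

The other drivers follow the same pattern: `analysis/01_simulate_reference.py`
writes the raw synthetic dataset, `03_task_high_gamma.py` shows a simulated
stimulus-driven 50–200 Hz increase surviving at every bipolar distance up to
40 mm with a cluster-permutation mask, and `04_ied_density.py` compares
discharge detection between 4 mm ("high-density") and 8 mm ("low-density")
montages built from the same base electrodes.

A `bprr` command-line interface wraps the same pipeline
(`bprr simulate | map | task-compare | ied | all`); every run directory
contains a manifest with the exact configuration and seeds, and identical
configurations reproduce byte-identical outputs.

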