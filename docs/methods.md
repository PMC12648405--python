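# Methods

## Signal chain

Recordings are referential multi-channel time series in µV. The preprocessing
chain is: 4th-order Butterworth low-pass below 255 Hz applied zero-phase
(forward–backward), polyphase resampling at the exact rational ratio to
512 Hz, then zero-phase notch filters (2 Hz bandwidth) at 60, 120, 180 and
240 Hz. The source rate (3052 Hz by default) and the non-integer 3052→512
ratio are handled by `scipy.signal.resample_poly` after the anti-alias filter.
The original acquisition chain specifies only the cutoff and target rate; the
filter order and zero-phase application are this package's choices, made so
that window timing is unaffected by filtering.

Recordings are parsed into 1 s consecutive non-overlapping windows starting at
t = 0. Windows overlapping an annotated discharge or artifact interval are
dropped; surviving windows overlapping a stimulus interval are labeled
`stimulus`, the rest `baseline`. Discharge-centered windows take 0.5 s on each
side of the sample (within the annotated interval) maximizing the absolute
first difference across channels; ties break to the earliest sample, and
events too close to a recording edge are dropped with a warning.

## Montages

Two pairing schemes:

* **Linear ordinal** — along each linear run (a depth probe, a strip, or one
  grid row), pairs (i, i+s) for skip s, with distance s × manufactured pitch.
  This is the clinical convention and deliberately non-Euclidean.
* **Omnidirectional** — every unordered within-component pair, with 3D
  Euclidean distance. Cross-component pairs are never formed (different
  contact geometry and materials would confound the comparison).

Contacts flagged bad are excluded before enumeration; on ordinal lines they
still count as skipped positions. Pairs are canonically ordered (lower table
index as anode) so derived-channel signs are deterministic; all power analyses
are sign-invariant. Distance bins are half-open [lo, lo+w) with w = 2 mm over
[2, 60] mm (29 bins; a pair exactly at 60 mm falls in the last bin). The bin
edge convention is this package's choice — the analysis it follows never
states one.

## Spectra

Power spectral density is estimated per 1 s window with DPSS tapers
(time–bandwidth NW = 3, 5 tapers, ≈3 Hz half-bandwidth), windows demeaned
before tapering, on the 2–200 Hz grid in 1 Hz steps; averaging across windows
is the arithmetic mean of linear power. NW and the taper count are exposed in
the API — the source analysis names its toolbox but not its parameters, and
these defaults are common practice for 1 s iEEG windows. An independent
multitaper implementation (`mne`) is used as a cross-check in the test suite
only.

Rebasing, used for cross-subject comparison of spectra, converts curves to
log10 power and subtracts one per-subject scalar: the median over 2–10 Hz of
the electrode-averaged referential log-spectrum. The subtraction is performed
in log space — a median offset across decades of power is only meaningful
there — and preserves all between-curve power differences.

## Distance–frequency maps

* **z-scored √power** — per distance bin, the mean over contributing pairs of
  √power; each frequency row is then z-scored across non-empty bins with the
  population (ddof = 0) standard deviation. Bins are equally weighted
  regardless of pair count (a pair-count-weighted variant is a flag).
* **Percent change** — per pair, 100 × (B − R)/R, where B is the bipolar
  √-power spectrum and R the arithmetic mean of the two contributing
  referential √-power curves, averaged within bins. Positive means bipolar
  exceeds referential; a `legacy_sign` flag reproduces the opposite
  (referential-minus-bipolar) convention, and `scale="linear"` computes the
  change on raw power (on that scale the independent-noise limit is +100%,
  versus +41.4% = √2 − 1 on the default √ scale). Cells from bins with fewer
  than 5 pairs are reported as missing (NA), never as zero.

Band-level statistics aggregate band-mean power per subject (averaged across
electrodes or pairs), compare bipolar vs referential per band × ordinal
distance with paired two-sided Wilcoxon signed-rank tests (rank-biserial
effect size), and control the whole family with Benjamini–Hochberg FDR at
q = 0.05. A single subject suppresses inference and returns descriptives.

## Task contrast

Per-window bipolar spectra (restricted to a flagged electrode subset and pairs
≤ 40 mm) are log10-transformed, averaged within distance bins, and optionally
z-scored by frequency across bins per window. Note that this z-scoring removes
any effect that is uniform across distance bins — it isolates
*distance-dependent* structure by design. The contrast is the stimulus-mean
minus baseline-mean map. Significance uses a two-sided cluster-based
permutation test: cell-wise pooled-variance t, cluster-forming threshold at
two-sided α = 0.05, 4-connected clusters in the frequency × bin grid, cluster
mass = summed t, compared against the permutation distribution of the maximum
absolute cluster mass under full label exchange (1000 permutations by
default, seeded and bit-reproducible). The statistic, adjacency and
permutation count are field-standard defaults, all configurable. The
high-gamma summary is the 50–200 Hz row mean per distance bin.

## Discharge (IED) analysis

Line length is the moving sum of absolute first differences over a trailing
window (100/40/20 ms, centered alignment with partial windows at the edges)
or the instantaneous |first difference|. Detection compares line-length-
transformed IED-centered windows against (count-matched, randomly subsampled —
a flag uses all) baseline windows, per bipolar channel, with 1D temporal
clusters and the same permutation machinery; channel-level p-values (the
permutation p of each channel's largest cluster) are BH-FDR corrected across
channels within subject. Extent metrics: per-channel significant duration in
ms, the number of involved channels, and the mean width over involved
channels (a max-over-channels variant is a flag). Subjects enter the analysis
only with more than 50 IED windows.

High- and low-density montages are built from the same base electrodes (every
other contact of each line): high pairs each base with its first neighbor
(one pitch), low with its second (two pitches). Density conditions are
compared with paired Wilcoxon tests at a per-comparison threshold of
0.05/4 = 0.0125, Bonferroni-corrected for the four line-length window
conditions.

The BH step across channels implies an irreducible exact-recovery ceiling:
each truly null channel is falsely included with probability ≈ (k+1)q/m
(k true channels of m), independent of effect size — worth remembering when
interpreting "channels involved" counts.

## Synthetic field generator

The generator is one concrete instantiation of the spatial-wavelength account
of the distance–frequency pattern — a hypothesis, not an established
mechanism — built so that every analysis stage has an analytic oracle:

* **Traveling waves**: per contact at position r,
  A·cos(2πft − (2π/λ)u·r + φ) with λ = v/f. A colinear pair at separation d
  has bipolar/referential power ratio 4 sin²(πd cosθ/λ)
  (`analytic_pair_power_ratio`).
* **Partial coherence**: each wave component carries a `coherent_fraction` w;
  the remaining band power is a narrowband (±2 Hz) field with spatial
  correlation exp(−d/ℓ_w), ℓ_w = 12 mm by default. A fully coherent
  long-wavelength wave would be attenuated by bipolar derivation even at
  60 mm (4 sin²(πd/λ) < 1 for d < λ/6 ≈ 30 mm at 4 Hz), which contradicts
  the observed enhancement of all frequencies at large distances; real
  low-frequency iEEG is only partly a single plane wave. w ≈ 0.22–0.3 places
  both the short-distance attenuation and the long-distance enhancement in
  the analytically required regime.
* **Aperiodic field**: band-limited (30–250 Hz) Gaussian noise with
  cross-contact correlation exp(−d/ℓ), realized by Cholesky-factoring the
  distance covariance (ridge-regularized if jitter breaks positive
  definiteness). ℓ = 4 mm gives +26% bipolar power at 4 mm separation — a
  modeling choice inside the empirically reported high-frequency range, not
  a fit to any dataset.
* **Common mode**: 60/120/180/240 Hz tones plus two narrowband peaks above
  75 Hz (80 and 105 Hz), identical on all contacts; bipolar derivation
  removes them exactly, the notch stage handles the referential side.
* **Reference configuration** (`reference_field_config`): waves at
  {4, 8, 12, 20, 28} Hz, v = 0.72 m/s, 1/f amplitudes (the 28 Hz component
  kept small so its incoherent surround does not leak above 30 Hz),
  aperiodic std 12 µV. The default geometry for map runs is a single
  16-contact 4 mm grid row colinear with propagation, spanning 4–60 mm pair
  distances while keeping full runs fast.
* **IED transients**: a biphasic triangular spike (70 ms; piecewise-linear so
  the absolute slope is sustained across the spike, the signature line-length
  detection keys on) plus a 300 ms slow half-wave, scaled per contact by
  A·exp(−d²/2σ²) around a center contact, placed ≥1 s apart with jitter, with
  exact annotations emitted.
* **Task modulation**: independent band-limited noise with variance
  (gain − 1) × the contact's in-band variance added on subset contacts during
  stimulus intervals, multiplying expected 50–200 Hz power by `gain`.

All generator outputs are bit-reproducible given (config, seed).

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — distance-
dependent coherence, spectral shape, common-mode artifact, discharge
morphology and footprint, task-band power increases. It does not model
volume conduction, dipole geometry, gray/white-matter differences, cortical
folding, non-stationarity, or realistic artifact diversity. Passing tests
therefore demonstrate that the *pipeline* measures what it claims under
known ground truth, not that real cortex behaves like the model; the
traveling-wave dispersion λ(f) = v/f with a single speed is an idealization.

## Numerical choices and problem sizes

Zero-phase filtering throughout; multitaper tapers normalized to unit energy
so white noise integrates to its variance; percent-change cells with zero
referential power are excluded with a warning; z-scored rows with zero
variance are set to 0. Permutation engines draw from a single seeded
`numpy.random.Generator`; p-values use the (1 + exceedances)/(1 + permutations)
convention. Map runs in the analysis drivers and tests use a 16-contact row
and 120 s of signal; calibration suites use 200 null simulations with
250–500 permutations; discharge-recovery suites use 30 IED / 40 baseline
windows per run. These sizes were chosen to keep full runs comfortably
reproducible on a laptop while leaving Monte-Carlo noise well inside the
asserted margins.

## Known limitations

* EDF files are read (via `mne`) but not written; the native signal format is
  flat float32 binary with a JSON sidecar.
* The ordinal scheme treats curved arrays as ideal lines (distance =
  skip × pitch), faithful to clinical convention but not to 3D geometry.
* Cluster-based permutation inference is calibrated for the any-cluster
  family error per field; cluster *extents* are descriptive, as in all
  cluster-mass methods.
* The task z-scoring across bins removes distance-uniform effects (see
  above); use `zscore=False` to quantify absolute condition differences.
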