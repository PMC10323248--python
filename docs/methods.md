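# Methods

## The measurement model

Each embryo is filmed in short clips (default 30 s at 30 frames s⁻¹,
hourly) under dark-field illumination: a bright embryo on a dark
background. One bounding box per clip is found on the temporal-median
frame by global thresholding (Otsu by default), keeping the largest
connected component, inflating by a configurable margin and clamping to
the frame. The embryo is capsule-confined at this magnification, so a
single per-clip box is used rather than per-frame tracking — per-frame
boxes would modulate the measured mean with box jitter, i.e. inject
artefactual signal into the very quantity being analysed. Each frame is
then reduced to the arithmetic mean grey level over the whole box.
Coordinates are 0-based and half-open on the max edges throughout.

## The energy proxy trait

The per-clip brightness series x(t) is decomposed with Welch's method
(averaged periodograms of overlapping, detrended, tapered segments) into
a one-sided power spectral density, which is binned into 60 bands of
0.1 Hz covering (0, 6] Hz. Band k's energy is the rectangle-rule sum
density × grid spacing over grid frequencies f with 0.1 k ≤ f < 0.1 (k+1);
the f = 0 point is excluded (baseline brightness is illumination, not
physiology) and f ≥ 6 Hz is discarded. Because every retained grid point
belongs to exactly one band, the 60 band energies partition the
DC-excluded integrated PSD exactly, and **total energy** is their exact
sum. A grid frequency sitting on a band edge belongs to the upper band
(deterministic, testable tie-break).

### Welch defaults and why

* `segment_length = 10 s × fps` (300 frames at 30 fps, 480 at 48 fps).
  This makes the analysis grid spacing exactly 0.1 Hz, commensurate with
  the band edges at any acquisition rate. Shorter segments whose grid
  spacing exceeds 0.1 Hz would leave some bands with *no* grid frequency
  at all, silently zeroing them.
* `taper = boxcar` with per-segment **linear detrending** and 50% overlap.
  With the grid aligned to band edges, every periodic signal whose
  frequency is a multiple of 0.1 Hz completes an integer number of cycles
  per segment, so a rectangular taper concentrates its power in the single
  grid point that owns it; any smooth taper (Hann etc.) spreads an on-edge
  tone across two bands. Linear detrending removes illumination drift
  (which the rectangular taper would otherwise smear) without touching the
  in-band signal. Hann and arbitrary segment lengths remain available via
  `WelchConfig` for matching other software; the fine-resolution Hann
  configuration (`segment_length = full trace`) localises mid-band tones
  to better than 90% and is exercised in the tests.
* Density scaling (grey level² Hz⁻¹). The fps-invariance of the band
  energies (same continuous signal sampled at 30 vs 48 fps agrees within
  10% per occupied band) is tested explicitly, since studies mix
  acquisition rates across species.

## Developmental time and windows

Absolute clip times (hours post-4-cell) divide by each embryo's own hatch
time to give relative developmental time in [0, 1]. Clips after hatch are
excluded and logged. Each clip is labelled with the physiological window
opened by the most recent scored onset (ciliary rotation, heartbeat,
crawling, radula) at or before it, in *that embryo's own event order* —
physid-order embryos open the crawling window before the heart window,
lymnaeid-order embryos the reverse — so like-named windows are compared
across species despite heterochrony. Window means are arithmetic means of
the band vectors over an embryo's clips in the window; embryos without
clips in a window are omitted, never zero-filled.

For trajectory comparison, each embryo's total-energy series is linearly
interpolated onto an even n-point grid over [0, 1] (default n = 100).
Grid points outside the observed range are missing, with one deliberate
exception: an endpoint within one grid spacing of the nearest observation
takes that observation's value. The last pre-hatch clip sits ~1/hatch
(≲ 0.006) below rel-time 1.0 — far below the grid resolution of ~0.01 —
and holding its value there keeps the grid complete without extrapolating
any trend. Gaps longer than `max_gap_h` (default 3 h, i.e. three missed
hourly clips) are left missing rather than silently bridged.

## Statistics

* **Trajectory**: a two-level repeated-measures ANOVA with temperature as
  the within factor paired across the grid points of the two cohort-mean
  trajectories; with two levels the F statistic is the square of the
  paired t over grid points, df (1, n_grid − 1) — (1, 99) on the default
  complete grid, reduced pairwise when grid points are missing in either
  cohort mean. A per-embryo mixed construction was considered and
  deliberately not made the default: the paired-across-grid construction
  is the one whose df structure the reported statistic follows.
* **Post hoc**: at every grid point, Tukey's HSD between temperatures
  across embryos, computed through the studentized-range distribution so
  it generalises to more than two temperatures; with two groups it equals
  the pooled-variance two-sample comparison (q = √2·|t|), which the tests
  verify. Contiguous significant points (same direction) are reported as
  regions of relative developmental time with their direction and minimum p.
* **Band-wise**: the multivariate comparison is implemented as 60
  univariate Kruskal–Wallis tests (one per band) on per-embryo window
  means under a single Bonferroni family, per-test threshold α/60
  (0.05/60 ≈ 0.00083). Bonferroni (a FWER control) is used rather than a
  BH/FDR procedure — the threshold is what defines the family. Bands where
  all values tie give H = 0, p = 1. Direction is the sign of the median
  difference; contiguous significant bands are summarised as Hz ranges.
* **Event timings**: per-event Kruskal–Wallis on absolute timings with an
  accelerated/delayed/unchanged call from the median difference; events
  with fewer than two scored embryos in a group are skipped and logged.

## Ordination

PCA is fit on log10 band energies of per-embryo window means pooled
across temperatures and windows (per-group grand means would give a
trivial two-point PCA). The log floor defaults to the smallest positive
observed energy × 10⁻³, keeping empty bands finite without dominating the
variance; PCA is column-centred and unscaled by default (the log already
tames the dynamic range; unit-variance scaling is available). Components
carry a deterministic sign (largest-|loading| entry positive). Axis
attribution reports the standardised mean score difference between two
groups on a component and the bands whose |loading| is ≥ 50% of that
component's maximum, as Hz ranges.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not embryo optics. Per embryo it draws an **itinerary** from a species
preset — lymnaeid: rotation 40 h, heart 110 h, crawling 150 h, radula
190 h, hatch 240 h; physid: rotation 30 h, crawling 70 h, heart 95 h,
radula 120 h, hatch 160 h (values chosen once as realistic for pulmonate
development at 20 °C; the two presets encode the two heterochronic
orders). Per-embryo jitter multiplies the *increments* between
consecutive events by lognormal(σ = 0.05) factors, which keeps times
positive and provably never reorders events. A temperature effect scales
all event times (default warm treatment ×0.75, with optional per-event
overrides, e.g. rotation unchanged), scales component amplitudes
(default ×1.3, with per-component overrides) and can shift centre
frequencies.

Each clip's trace is baseline (100 grey levels) + slow sinusoidal drift
(0.02 Hz, 2 grey levels) + the physiological components whose onset has
passed + white noise (σ = 1). Default components: rotation = band-limited
noise 0.1–0.5 Hz (RMS 2), crawling/flexing = band-limited noise
0.4–1.0 Hz (RMS 2), heartbeat = 2.0-Hz sinusoid (peak 3, variance A²/2),
radula = 2.3-Hz Gaussian pulse train (RMS 1.5, pulse σ 0.06 s — wide
enough to be sampled consistently at both 30 and 48 fps). Frequencies sit
in distinct bands attributable to observable physiology (sub-1-Hz
rotation/flexing, ~2-Hz heartbeat), so band-level recovery is checkable;
amplitudes are free parameters of the generator, not estimates of any real
embryo. Random draws are consumed for every component whether or not it is
active, so cohorts sharing a seed differ only through the treatment
effect. All randomness flows through one SeedSequence tree: cohorts are
bit-reproducible, and a vectorised batch path produces traces
bit-identical to the per-clip path (asserted in the tests).

At frame fidelity, a trace is rendered as a statically textured bright
ellipse on a zero background in 8-bit frames, with texture weights
normalised so the mean grey level over the ellipse's true bounding box
reproduces the trace value to within quantisation (< 1 grey level).

What the generator does **not** model: egg-capsule optics, embryo growth
or shape change, rotation of the texture, multi-embryo frames,
heteroscedastic camera noise, illumination flicker. Passing tests
therefore demonstrate that the pipeline recovers known band-limited
structure and controls its error rates under these idealised conditions —
not that segmentation or the statistics are robust to real-world imaging
artefacts.

## Problem sizes used in the shipped studies

The effect study doubles the heartbeat amplitude in the warm cohort
(n = 20 embryos per cohort, lymnaeid preset, hourly clips): trajectory
power is estimated over 100 replicate experiments and band recovery on
one fixed-seed experiment. The null study uses identical generative
settings in both cohorts (n = 8 per cohort, physid preset, 2-hourly
clips) over 17 replicates = 1020 band tests. Event-timing recovery uses
timing factor 0.8 with n = 20 itineraries per cohort. These sizes are the
package's own choices for a desk-scale characterisation; all are
parameters of the corresponding functions.

## Known limitations

* The repeated-measures construction treats grid points of cohort means
  as repeated units; temporal autocorrelation along the trajectory is not
  modelled (no sphericity correction), matching the df structure it is
  designed to reproduce rather than a modern longitudinal model.
* Band-wise Kruskal–Wallis at very small n cannot reach the Bonferroni
  threshold (the minimum two-group p at n = 8 + 8 is ≈ 0.00078); with
  fewer embryos the family is effectively powerless, by construction.
* The boundary-hold at the grid endpoints assumes the trajectory is
  effectively constant over the final sub-grid-spacing interval before
  hatch.
* Segmentation assumes a single bright object; it has no notion of
  focus, debris or neighbouring embryos.
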