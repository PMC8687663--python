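# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `perwave`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Signal model and the synthetic generator

A PER2::LUC reporter rhythm is modeled as

    y(t) = mesor + drift·t + A · d^c(t) · cos(π·φ(t)) + I(t) + ε(t)

where `φ(t)` is a monotone phase function in half-cycle units (φ = 0 at the
first peak), `c = φ/2` the cycle index, `d ∈ (0, 1]` the multiplicative
per-cycle damping of the explant rhythm, `I(t)` an additive induction
transient, and `ε` white Gaussian noise.

The generator pins every extremum to an exact clock time and interpolates
phase between those knots with a **monotone cubic (PCHIP)**. Two properties
follow. First, programmed quantities are exact: a rising/falling warp
multiplies the knot spacing of that limb, a step phase shift displaces the
first post-stimulus peak from the pre-stimulus regression line by exactly
the programmed amount (realized by stretching the limb that ends at that
peak), and a period delta changes all later knot spacings. Second, the
instantaneous frequency is *continuous through the extrema*. A
piecewise-linear warp would put a frequency kink exactly at the peaks; any
symmetric smoothing or fitting then biases peak timing by 0.1–0.2 h, which
is larger than the recovery tolerances this package holds itself to. The
smooth interpolant confines frequency changes to the limb interiors, at the
cost that samples between the previous trough and a warped limb deviate
slightly from the free-running reference (the warp "eases in"); extremum
times and values remain exact.

Defaults emulate the instrument and preparation: 6-min sampling (0.1 h),
period 24 h, damping 0.95/cycle, ≥ 3 free-running cycles before any
stimulation (recordings run 240–380 h), imaging at 10-min frames. The
induction transient is `a·A(t_s)·exp(−(t−t_s)/κ)` with κ = 3 h — the acute
PER2 rise decays within half a cycle. No quantitative model of the
transient shape is available, so the exponential is a stand-in; only its
amplitude and rough support matter to the pipeline. The `IND-CT14`
amplitude (1.960368) is calibrated once so that the pipeline's own
normalized-induction procedure returns 0.70 on the noise-free pair, then
frozen in `presets.yaml`.

Entrainment presets program trough-to-trough cycles of fixed (rising,
falling) durations: T22 = (9.48, 12.52) h (rising 0.79 FC), T25 = (10.96,
14.04) h (falling 1.17 FC), skeleton 16:8 = (8.4, 15.6) h and 8:16 =
(10.08, 13.92) h — the skeleton pairs sum to exactly 24 h, as the measured
fold changes imply. Transitions into and out of the entrained epoch are
instantaneous; real explants entrain over transient cycles, so tests of
transient dynamics are out of scope. The phase-jump preset interposes three
21.5-h cycles between a long-day-aligned start and the stable short-day
alignment, advancing the rising phase across the nominal dawn pulse by
~7.5 h in 3 cycles.

The spatial generator plants three contiguous regions (lateral shell, core,
medial bands aligned to the 15-px ROI lattice in a 96×96 frame) with
baseline phase offsets (+0.75, 0, −0.75 h), phase shifts (−1.33, −1.64,
−0.64 h) and period deltas (+0.36, +0.08, +0.31 h). The five-slice cohort
varies the shell's shift by ±0.28 h per slice (mean exactly −1.33). This
inter-slice variability is what makes the group-average clustering stage
meaningful: with literally identical slices the averaged binary memberships
cannot resolve three regions, whereas with realistic slice-to-slice spread
the per-slice 2-way splits fall on different sides of the shell and the
averaged membership takes three levels — mirroring how the procedure works
on real cohorts.

## Preprocessing

Baseline subtraction uses a centered **trapezoid-weighted running mean**
(half-weight endpoints) spanning the requested hours (24 h default, rounded
up to an odd sample count). A trapezoid window integrates a cosine over one
full period to exactly zero, so detrending with window = period passes the
rhythm through untouched; constants and linear drift are removed exactly
away from the edges. The default pipeline iterates the baseline estimator
twice: a single 24-h mean retains a first-order fraction of the oscillation
wherever the local period deviates from 24 h (retention ≈ 1 − sinc(πW/T)),
and subtracting that contaminated baseline perturbs extremum timing; the
second pass makes the leakage quadratically small. Smoothing is the same
filter at 2.4 h. Both are linear and commute on interior samples.

**Extremum timing.** Candidate peaks/troughs come from the smoothed,
detrended signal (prominence ≥ 0.2 × median per-cycle amplitude, separation
≥ 16 h, alternation enforced by keeping the more extreme of same-type
neighbors). Each extremum time is then refined by a local **cubic**
least-squares fit on the *raw* signal: the cubic's odd term absorbs
rising/falling asymmetry that biases a parabola's vertex, and the raw basis
avoids the residual timing distortions of both smoothing and baseline
subtraction (a quadratic-plus term absorbs any locally linear baseline).
The fit half-width adapts to the measurement noise estimated from second
differences: 1.2 h on clean data (tracks strongly asymmetric cycles),
up to 4 h at ≳ 2 % noise (averages the noise out of the vertex). Extrema
within 12 h of either end of the recording are discarded — the shrinking
filter windows there distort timing; half-max markers keep 24 h clear
because they are read off the detrended signal and cannot be re-timed
against the raw one.

**Induction transients.** A strong acute PER2 rise right after a pulse can
be called as a spurious peak and can gut the prominence of the genuine peak
beside it. When the 6-h window after a pulse shows clear excess over a
quartic fitted to its flanks, detection also runs on a copy with the window
bridged by interpolation, the union is taken, window-internal peaks are
dropped, and extremum fits exclude the contaminated samples. The flank fit
(not a chord) is essential: waveform curvature across a 7-h window is of
the same order as a genuine transient.

Per-cycle amplitudes (peak minus preceding trough) are measured on the raw
signal — mesor and slow drift cancel in the difference, and the raw signal
carries no baseline-subtraction transient, which matters when amplitude
collapses abruptly (long-light-exposure emulation). Damping is exp of the
slope of log amplitude vs cycle index, fitted on pre-stimulus cycles when a
stimulus time is given.

## Resetting estimators

Phase shift: regression of all pre-stimulus peak times on cycle index,
prediction at the next index, shift = predicted − observed (advance
positive). The observed peak is the first detected peak after pulse onset
plus an induction-exclusion window of 0.25 τ, and must lie within 1.5
predicted periods. Period change around a single pulse excludes the
stimulated cycle: marker regressions use all pre-stimulus peaks and the
post-stimulus peaks from the observed peak onward; Lomb–Scargle segments
run from the recording start + 12 h to the last pre-stimulus trough, and
from the first trough after the observed peak to the end − 12 h (the edge
margins keep filter-distorted samples out of the periodogram). The
Lomb–Scargle grid spans 16–32 h in 0.01-h steps; a maximum on the grid
boundary is an error, not an answer.

Envelope normalization fits log-linear (geometric) envelopes through the
pre-stimulus peak and trough values and extrapolates them over the trace;
output is `(y − Q)/(P − Q)`. The long-T variant anchors the lower envelope
on actual troughs and interpolates the peak envelope across the entrained
epoch from the surrounding free-running peaks. The stimulated and
unstimulated traces of an induction pair are normalized over the same
pre-stimulus window so envelope extrapolation error cancels in their
difference; normalized induction is the max − min of that difference over
the first post-stimulus cycle. Known floor: a large transient leaks into
the running-mean baseline of the stimulated trace (the baseline window
spans ±24 h), which perturbs its envelope anchors; several cycles
downstream the two normalizations can disagree by ~0.1–0.2 normalized
units. The first-cycle metric is insensitive to this, and the calibration
of the induction preset is performed through the identical pipeline.

Rising/falling durations: zero crossings of the 2.4-h-smoothed central
derivative of the smoothed normalized trace, each crossing re-timed by the
same raw-basis cubic fit (crossings are extrema of the signal). Where the
derivative dips below ε = 5 % of its typical magnitude after a pulse
without a sign change, the derivative's local minimum ends the rising
phase. Fold changes divide the stimulated cycle (first limb of each type
ending after pulse onset) by the mean of all complete pre-stimulus cycles;
entrained fold changes average all cycles whose peak falls within the
schedule span.

## Entrainment

CT12 is the PER2::LUC peak; CT(t) scales elapsed time since the last peak
by 24/τ. The phase angle of entrainment is dusk-pulse onset minus the
nearest rising half-max; its regression slope must stay within
0.15 h/cycle and the half-max period within 0.25 h of the schedule's cycle
length for a run to count as entrained (the source experiments assert
entrainment qualitatively; these thresholds are this package's, chosen to
separate the programmed stable and free-running conditions by a wide
margin). A phase jump is flagged when the cumulative advance of the
half-max exceeds 4 h within ≤ 4 cycles, the half-max crosses the nominal
dawn pulse (from after it to before it within half a cycle — larger jumps
in the angle series are wrap-around artifacts), and the angle is stable
over the following cycles; otherwise an unstable run is free-running.
After-effects compare the same period estimator on the pre-entrainment and
post-release epochs.

One sign note: with angle defined as pulse − half-max, a free-running 24-h
rhythm scored against a T22 schedule drifts at −2.0 h/cycle (22 − 24); the
magnitude is the period mismatch.

## Spatial pipeline

Grouped minimum-intensity projection with group size 2 (pixelwise min of
consecutive frame pairs, timestamps at pair midpoints) removes any artifact
confined to one frame of a pair and never increases a pixel. ROIs are
15 × 15-px tiles over the bounding box of the foreground of the
average-intensity projection; the threshold is half the median of the
nonzero projection (the median itself sits inside the foreground intensity
distribution and would discard about half of it). Per-ROI mean traces are
smoothed and analyzed with the same single-pulse estimators; phase maps are
peak times normalized to the grid mean, the period map uses a three-peak
regression. Circular statistics map peak times onto a `period`-circle
(24 h by default, matching convention) and report 1 − mean resultant
length.

Clustering follows the group-average design: (1) per-slice Ward 2-clustering
of the raw scalar map (value-only features — the goal is to separate larger
from smaller responses, not to enforce contiguity), membership oriented so
1 = larger values; (2) nearest-neighbor registration of each slice's ROI
lattice onto the first slice's (slices of equal layout register
identically) and averaging of the binary memberships; (3) Ward clustering
of the averaged membership into three groups (fewer if the average has
fewer distinct values — degenerate cohorts warn and degrade gracefully);
(4) per-cluster means recomputed from each slice's *raw* map restricted to
the cluster, then averaged across slices — cluster centroids of the
membership values are never reported as effect sizes.

## Problem sizes and determinism

The shipped presets use 240–380-h traces at 0.1-h sampling (2 400–3 800
samples) and five 96 × 96 × 1080-frame stacks; the full test suite runs in
under a minute and the acceptance script in ~10 s on one CPU. All
randomness flows from explicit seeds; noise-free runs are bit-reproducible.

## Limitations

* The generator realizes measured effects on a phase function; it is not a
  dynamical (limit-cycle) SCN model, and jump trajectories are programmed,
  not emergent.
* Programmed entrainment has no transient cycles; classifier thresholds
  were not tuned against gradual re-entrainment.
* The synthetic noise is white and Gaussian; real photomultiplier traces
  have Poisson character and occasional artifacts, and real imaging
  requires nontrivial cross-slice registration (here slices share a
  layout, so registration reduces to lattice scaling). Passing tests
  demonstrate estimator correctness on the modeled signal class, not
  robustness to every instrumental pathology.
* Gap handling at ingestion is linear interpolation of ≤ 3 consecutive
  missing samples; longer gaps are rejected rather than imputed.
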