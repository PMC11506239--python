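# Methods

## Stimulation protocol and regressors

The design is fixed by a `StimulationProtocol`: a 5700-s acquisition,
stimulation starting at 1200 s, six 600-s blocks separated by 180-s
rests; within a block, 60-s light-on / 15-s light-off cycles; within an
on phase, 20-Hz pulses at 50% duty cycle (pulse duration
`duty_cycle / frequency` = 25 ms). All timing quantities are derived
from this one object. Frames are classified by their centre time;
intervals are half-open `[start, end)`; indices are 0-based internally
and 1-based in reports, so the sixth block maps to frames 86–95 of a
95 × 60-s grid. The protocol text also quotes a last-block onset of
second 2551, which is arithmetically incompatible with frames 86–95
under any frame convention; the frame-index statement is taken as
authoritative.

Task regressors:

- *boxcar* — 1 inside stimulation (block-level by default; a cycle-level
  option flags only on phases);
- *ramp* — cumulative count of stimulation frames, i.e. the discrete
  integral of the block-level boxcar, flat during rests; with unit slope
  its coefficient is directly the extra uptake per stimulation frame;
- *HRF convolution* — the canonical double-gamma response (gamma-density
  difference with modes at 5 s and 15 s, peak:undershoot 6:1, unit
  dispersion, peak-normalized). The convolution kernel is the HRF
  *averaged over frame-length bins* rather than point-sampled: at coarse
  spacings (15-s frames of the decimated BOLD option) point samples miss
  the positive lobe entirely and would invert the response.

## Phantom

The phantom generates the statistical structure the analyses assume, on
a 32×32×16 grid of 0.5-mm voxels (16×16×8 for fast studies) with a
deterministic box-parcel atlas (bilateral striatum, thalamus, cortex,
right SN, cerebellum, an extra gray-matter parcel; every region ≥ 27
voxels, disjoint, inside an ellipsoidal brain mask).

- **fPET**: voxel TAC = `slope · frame_number` (slope 1 per frame in
  arbitrary kBq-like units, matching the unit-slope ramp regressor) plus
  `increment(region) · ramp(t)` in responsive regions of responsive
  subjects, plus i.i.d. Gaussian noise (sd 0.5). Default increments:
  right striatum 0.10, right SN 0.15, right thalamus 0.08 — i.e.
  8–15% extra slope, a plausible task-metabolism scale. Controls and
  the cerebellum carry no increment.
- **BOLD**: baseline 100 with fractional responses — on-phase boxcar ⊗
  HRF with amplitudes +2% (right striatum), +1% (right thalamus), −1%
  (left striatum, left cortex), plus an overshoot transient (impulse at
  each block termination ⊗ HRF, +2%/+1%) so the post-block peak exceeds
  the suppressed on-plateau; a half-cosine drift over the acquisition
  (period 2 × 5700 s ≥ 512 s, amplitude 1%) that the 256-s high-pass
  demonstrably removes; Gaussian noise sd 1. The native 2-s frame grid
  (2850 volumes) is configurable; tests and studies use a decimated
  15-s grid to keep memory and time desk-scale.
- **Coupling** (for connectivity studies): a zero-mean unit-sd latent
  course active only during stimulation blocks, added with configurable
  strength to chosen regions (default off).
- Reported response amplitudes for this design are qualitative only, so
  the phantom's effect sizes are free parameters fixed once at the
  values above; they are not calibrated to any measured dataset.

Per-subject generators are spawned from the cohort seed via
`SeedSequence`, making cohorts bit-reproducible. Noise is i.i.d. by
default with an optional AR(1) switch; inference is permutation-based
and tolerates either. What passing phantom tests show is that the
*machinery* is correct and calibrated under its assumptions — not that
real PET/BOLD noise (count statistics, motion, physiology, partial
volume) is captured.

## Preprocessing

Gaussian smoothing is frame-wise, FWHM in mm (default 1.5 mm isotropic,
the PET-resolution-matched kernel), mask-normalized (smoothed data
divided by the smoothed mask) so constants are preserved inside the
brain and nothing bleeds across the mask edge. The temporal high-pass
is a discrete-cosine basis projection removing periods longer than the
cutoff while retaining the mean (idempotent); the quoted "256 Hz"
cutoff of the source software is the SPM convention for a 256-s cutoff
*period* — a literal 256 Hz is meaningless at 0.5-Hz sampling. The
low-pass is a zero-phase 4th-order Butterworth with a 300-s default
cutoff (half the block duration). Intensity normalization divides each
frame by its cerebellum mean (reference region, for between-group fPET)
or by its whole-brain mean (relative uptake, before ICA). Neither
realization (DCT / Butterworth) is dictated by the design; both are
standard and unit-tested for their pass/stop behaviour. Order when
several steps are combined: smooth → normalize → filter.

## GLM and permutation inference

First level is voxelwise OLS, `t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`. The fPET
design is [ramp, baseline, intercept] with the baseline regressor the
gray-matter mean excluding activated voxels; the exclusion mask is an
*input* (the companion modality's activation map, or an a-priori mask)
and is the caller's responsibility — this guards the circularity of
defining baseline from the data. The BOLD design is [HRF-convolved
task, intercept]; the rest condition is the implicit reference of the
task > baseline contrast. No autocorrelation prewhitening: group
inference is by permutation, which does not require it.

Cluster inference thresholds the group t map at the one-sided P < 0.001
t-quantile, forms clusters with 26-connectivity, and compares each
observed cluster's size against the permutation null of the *maximum*
cluster size (sign flips for one-sample, label shuffles for
two-sample), `p_corr = (1 + #{null ≥ size}) / (1 + n_perm)`; peak ties
break at the lowest linear voxel index. This replaces random-field
theory with an assumption-light, exactly testable procedure.

In the validation studies, subject coefficient maps are smoothed with
the 1.5-mm analysis kernel before cluster inference (OLS is linear per
voxel, so smoothing maps equals fitting smoothed data). This matters
for calibration: on unsmoothed i.i.d. noise, suprathreshold voxels are
nearly all singletons and the integer-valued max-cluster-size null
becomes so discrete that the test is conservative (measured FWE ≈ 0.015
at nominal 0.05); with the analysis kernel the measured FWE sits at the
nominal rate.

## Group ICA and component descriptors

Whole-brain-normalized subject series are each PCA-reduced retaining
≥ 99% variance, whitened, temporally concatenated, reduced again to 20
components and unmixed with FastICA (logcosh contrast, tol 1e-6, max
500 iterations, fixed seed). The tolerance is tighter than the
conventional 1e-4 because FastICA can stop at a visibly rotated
solution on near-symmetric sparse sources at 1e-4 (source correlation
0.70 instead of > 0.999 on the constructed unmixing check).
Non-convergence is flagged on the result, not raised. Component sign is
canonicalized to positive skewness (ICA sign is arbitrary; task
components then load positively). Subject maps come from dual
regression; the component's group map is a one-sample t over subject
maps fed to the same cluster inference.

Descriptors per component: excess (Fisher) kurtosis and skewness of the
z-scored map; *variability* = RMS distance of |z| > 2 voxels from their
centroid ÷ RMS distance of all in-mask voxels from the mask centroid
(≈ 0 focal, ≈ 1 widespread; flagged undefined when nothing is
supra-threshold); *frequency* = spectral centre of mass of the mixing
course's periodogram in cycles per frame. Variability and frequency are
documented interpretations — rank-compatible with the original
descriptors but not numerically comparable to any published values.
Ranking is by descending kurtosis (or ascending frequency), ties by
component index; raw vs excess kurtosis differ by a constant and give
identical orderings.

## MVPA

Samples are per-block summaries: for each block one "ogs" sample and
one "baseline" sample from the rest window immediately preceding it
(per-window GLM betas by default; window means optional). Features are
detrended per voxel (global line) and then corrected for residual slow
drift by fitting a per-voxel line over the *baseline-window* features
against run index and subtracting it from every window. Without this,
the fPET uptake sawtooth dominates the class difference; fitting on
baseline windows only (rather than centering each block/rest pair)
avoids making every ogs sample the exact mirror of its rest sample,
which would halve the number of independent decisions. The classifier
is L2 logistic regression (C = 1) with training-fold standardization,
leave-one-subject-out; permutations shuffle labels within subject
(respecting exchangeability) and recompute the full CV accuracy, so
the test-subject labels can never reach training. The searchlight runs
the same decoder over spherical neighborhoods and corrects the
accuracy > 65% map by the permutation max-cluster-size null.

## Connectivity

fPET series are first residualized on the global in-mask mean course
(per voxel, with intercept): the shared uptake curve would otherwise
correlate every voxel with every seed. Correlations between the seed's
mean course and all voxels are computed separately on
stimulation-block frames and inter-block rest frames (equalized in
count by truncation, ≥ 8 frames each), after linear detrending of the
selected frames — the ramp is linear in cumulative stimulation time,
so the detrend removes it within the OGS window. Fisher z maps are
contrasted (OGS − baseline) as paired differences under sign-flip
cluster inference. Coupling is computed across frames within subject;
r is capped at 1 − 1e-7 so z stays finite for within-seed voxels.

## Overlap

ω = 2·V_km/(V_k+V_m) on thresholded masks, with ω defined as 0 (and
flagged) when both masks are empty; peak distances are Euclidean mm
between within-ROI maximum-t voxel centres, ties at the lowest linear
index.

## Validation-study problem sizes

The seeded studies in `fpetbold.validation` (also driven by
`scripts/acceptance.py`) use: ramp recovery — 10 cohorts × 10 subjects
at 32×32×16, 95 frames, default noise, 200 permutations; ICA ranking —
10 cohorts × 6 subjects, 20 components; FWE calibration — 200 control
cohorts × 8 subjects at 16×16×8 with 200 permutations; MVPA — 8 + 8
subjects, SN-analog ROI, 200 permutations; connectivity — 20 cohorts ×
8 subjects at 16×16×8 with coupling strength 0.5 in the seed and one
target region. These sizes were chosen once as the package's desk-scale
study conditions; the whole suite completes in minutes on one CPU.

## Known limitations

- The phantom omits PET count statistics/reconstruction noise, partial
  volume, motion and physiological confounds; calibration results are
  about the inference machinery, not scanner realism.
- Cluster-size permutation inference is conservative on unsmoothed,
  spatially independent noise (see above); cluster-mass statistics are
  not implemented.
- Dual regression is one of several back-reconstruction conventions;
  subject maps are defined up to the regression model used.
- The searchlight recomputes the whole map per permutation, which is
  exact but expensive; keep grids or permutation counts modest.
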