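# Methods

## Measurement model

A cine PC-MRI slice is a stack of magnitude/phase frames gated to the ECG
R-wave.  Phase encodes through-plane velocity linearly, v = VENC·φ/π, with a
one-sided VENC of 50 cm/s for the arterial slice and 20 cm/s for the venous
slice; |v| above 95% of VENC is flagged as near-aliasing but not corrected
(no phase unwrapping).  Slices are assumed perpendicular to flow, so no
angle-correction term is applied.  Frames start at the R-wave (prospective
gating) and cover a fraction of the R-R interval (default 75%, 16 frames).

### Lumen segmentation

Per frame, the background noise is characterised in the four image-corner
patches (each 10% of each dimension, validated to stay clear of every vessel
neighbourhood).  The segmentation threshold is the background level plus
twice the background SD.  On magnitude images the signal-free background is
Rayleigh distributed around a non-zero level; a threshold of two SD measured
*from zero* would fall below the Rayleigh mean and admit ~42% of background
voxels — above the 8-connected site-percolation threshold (~0.41), so the
seeded component would flood the image.  Referencing the noise criterion to
the background level is therefore the operational reading used here.  The
lumen is the seeded 8-connected supra-threshold component
(`segment_lumen`); components touching the image border are flagged, and a
sub-threshold seed is reported as a missing frame, never silently dropped.

Even at background + 2 SD, ~3.7% of background voxels pass per frame, and a
noise-only voxel attached to the lumen carries a uniformly random phase
(velocity noise of order VENC/2), which is fatal for the small sinus series.
`segment_series` therefore applies a magnitude-consistency refinement:
voxels dimmer than half the component's median magnitude are removed and the
component re-extracted.  True lumen voxels carry near-full signal while
attached speckle sits just above threshold, so the cut is sharp; on
noiseless data it is a no-op.  This stands in for the operator's manual ROI
cleanup of semi-automated segmentations and can be disabled
(`refine=False`).

### Flow, normalization, features, coupling

Per frame, the lumen-mean velocity is the arithmetic mean of decoded voxel
velocities (mean, not maximum-voxel, velocity), and flow is v̄ × area.
Series are resampled to 32 cycle steps (step k at k×3.125 %CC; step 32 is
the next R-wave) by linear interpolation; steps beyond the last sample
follow the secant of the final two samples, floored at 0 µl/s for sinuses
and at the minimum observed flow for arteries (the floor applies to the
forward extrapolation; the rare backward extrapolation is exact so affine
inputs are reproduced exactly).  A periodic-interpolation mode is available
(`mode="periodic"`) but is not the default.

Features per 32-step profile: peak M = argmax (earliest step on ties);
dicrotic notch D = the step in (peak, 75 %CC] with the largest positive
discrete second difference, defined only for arterial profiles peaking
before 50 %CC (absent when the descent is concave); systolic upslope =
(peak flow − flow at step 3)/elapsed time, undefined when the peak is at or
before step 3; PI and RI over the 32 steps (computed on normalized profiles,
not raw frames).  Pairwise peak lags are computed per subject and then
averaged across subjects, not as differences of group means.

Per-cycle volume uses the step-rectangle rule V = Σ Q_k·(RR/32).  CF =
V_art/V_ven rescales the venous waveform so both compartments carry equal
per-cycle volume; the cumulative Art − CF·Ven balance then closes at zero by
construction, and the oscillating volume is its peak-to-peak range (a
maximum-positive-excursion variant would be a one-line change; peak-to-peak
is the default estimator).  The hysteresis loop is the ordered closed
polygon of (arterial, venous) flow at the 32 steps; its area is the absolute
shoelace sum, with self-intersecting loops flagged via a simple-curve test.
Percent contributions (e.g. % arterial input from the carotids) are
per-subject ratios, so group summaries are means of ratios; ratio-of-means
can be formed from the summary table's volume means when needed.

### Group statistics

The cohort table is tidy (one row per subject × metric).  Two-group
comparisons use the rank-sum statistic with mid-ranks; for ≤10 subjects per
group the two-sided p-value is exact, from full enumeration of all group
splits of the observed (possibly tied) ranks, as twice the smaller tail
probability capped at 1.  Paired comparisons enumerate all 2^n sign
assignments of the signed ranks for ≤14 pairs.  Larger samples fall back to
the normal approximation.  Fisher's exact test (two-sided) covers the
sex-by-age association, and Bonferroni correction (p·m capped at 1) is
applied per declared comparison family.

## Synthetic-data generator

The generator is the package's test bed: it renders gated cine stacks whose
every downstream quantity is known exactly.

**Waveforms.**  Arterial flow = baseline + gamma-variate systolic pulse
(rise α = 2.5) + a smaller bump (0.22 of the main amplitude) whose onset at
the notch position creates the dicrotic slope break; venous flow = a
gamma-variate pulse circularly convolved with a causal exponential kernel
(τ = 0.6 × rise width) and shifted so its maximum lands at the requested
arrival time.  Waveforms are periodic in %CC and scaled so the cycle
integral equals the per-cycle volume exactly.

**Rendering.**  Each vessel is a filled disk (pixel centres within the lumen
radius) at 150 µm in-plane resolution on a 200×160 grid; the in-lumen
velocity profile is parabolic (zero at the wall, twice the mean at the
centre), renormalised over the pixelated disk so the pixel-mean velocity
matches the waveform flow exactly per frame.  Complex Gaussian noise (SD
0.06 of the lumen signal) is added to both channels before
magnitude/phase extraction, giving Rician lumen noise and Rayleigh
background.  Velocities exceeding VENC raise an error.

**Cohort defaults** are calibrated to the published young-adult (YA) /
old-adult (OA) marmoset cohort: per-vessel per-cycle volumes
(19.0/13.2/15.5/6.2/6.8 µl YA; 30.3/19.3/19.5/5.6/5.7 µl OA for
BT/RC/LC/SS/StS), heart rates (189/152 bpm), tissue volumes, peak arrival
times (composite arterial peak ~31 %CC YA vs ~25 %CC OA, with BT slightly
leading the carotids; venous peaks 44.2/38.4 %CC YA vs 33.5/28.6 %CC OA),
and a dicrotic notch at 53.125 %CC (step 17).  Lumen radii are set on the
pixelated-disk ladder so cross-sections span 13–37 voxels, matching the
reported ranges.  Free shape parameters (baseline fractions, pulse widths)
were fixed during generator calibration so that arterial PI sits near the
reported ~1.2–1.5, peak arterial lumen-mean velocity is ~15 cm/s, the
oscillating volume is ~5.6 µl (YA) vs ~7.2 µl (OA), and the old group shows
the larger hysteresis-loop area.  The old venous pulse is distinctly sharper
than the young one (rise width 13 vs 24 %CC): venous pulsatility trades the
oscillating-volume contrast against the loop-area contrast, and the sharper
old pulse is the configuration that reproduces both age effects
simultaneously — consistent with the smoother venous progression of the
young system.

**Between-subject variability** is multiplicative lognormal: a global flow
scale (CV 0.13) times per-vessel jitter (CV 0.12) on volumes (combined
≈ the reported per-vessel volume CVs), heart rate CV 0.13, tissue volumes CV
0.08, plus additive peak-time jitter decomposed into a subject-level timing
shift (SD 2.5 %CC, common to all vessels) and independent per-vessel terms
(SD 1.5/1.2 %CC arterial, 2.0/1.5 %CC venous, YA/OA).  Two deliberate
departures from the real cohort's spread: the heart-rate CV is below the
published ~0.3 (full spread pushes peak parabolic centre velocities past
VENC, whereas the acquisition observed no aliasing), and the timing SDs are
below the published venous ones (with the real spread a 7+7 cohort has no
power for the directional age contrasts — the published venous-timing
p-values of 0.05–0.11 say the same of the real data).  Subjects whose
jittered flows would still alias are redrawn, emulating a cohort that by
construction contained no aliased series; the induced bias on group-mean
volumes is about −2 to −3%.  Everything is reproducible bit-for-bit from a
single seed.

**What the generator does not emulate:** partial-volume lumen edges,
background phase (eddy-current) offsets, gating jitter, motion, coil
inhomogeneity, vessel curvature/obliquity, and manual ROI editing.  Passing
tests therefore demonstrate the correctness and robustness of the analysis
chain under the stated noise and sampling model, not performance on real
scanner data.

## Numerical choices

- Dense waveform grid: 4096 points per cycle; volume scaling is exact in the
  grid mean, and trapezoidal integration reproduces volumes to ≪1%.
- Problem sizes: tests run 7+7-subject cohorts at 16 frames (the recovery
  checks) and 20 replicate cohorts for the group-contrast checks; these
  sizes mirror the study's paired-analysis cohort and keep the suite fast.
- Tie-breaks: peak = earliest maximal step; notch = largest positive second
  difference; exact tests use mid-ranks with two-sided p = 2·min(tails),
  capped at 1.
- Degenerate inputs: noiseless frames yield a zero noise estimate, so the
  threshold falls back to a tiny positive fraction of the frame maximum;
  constant profiles report PI = RI = 0, an undefined upslope (flagged), and
  a step-1 peak by the tie rule.
- Floating-point: balance closure and fraction sums are exact to ~1e-9
  relative; determinism is bit-exact for fixed seeds.

## Limitations

Venous outflow is measured in two sinuses only, so drainage and CF inherit
the study's peripheral-drainage blind spot by design.  The 32-step
normalization extrapolates the uncovered diastolic tail linearly; waveforms
with strong late-diastolic structure would be misrepresented.  The exact
tests enumerate splits (≤10 per group) or sign patterns (≤14 pairs) and fall
back to the normal approximation beyond.  The hysteresis area of a
self-intersecting loop mixes sub-loop orientations; such loops are flagged
rather than decomposed.
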