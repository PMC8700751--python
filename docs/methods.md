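# Methods

## Measurement model

A color-Doppler cine is an RGB frame stack in which the scanner has
painted, over a gray B-mode background, a color-coded estimate of the
blood velocity component along the insonation beam.  The package treats
the scanner's colorbar as an invertible lookup table: a pixel is
*perfused* when its chroma (max(R,G,B) − min(R,G,B)) exceeds a threshold
(default 24/255 — the B-mode background is gray, so chroma separates
overlay from anatomy), and its signed velocity is that of the nearest
colorbar entry in Euclidean RGB distance.  Nearest-color ties resolve
toward the smaller velocity magnitude, the conservative direction that
never inflates perfusion.  Decoding therefore recovers the *measured*
(beam-projected) velocity; no angle correction is applied at the pixel
level.

### Tissue perfusion (DTPM)

Per frame, over the ROI: mean velocity magnitude over perfused pixels
(zero when none — a frame without color *is* the diastolic no-flow state,
and excluding it would bias TFV upward and make TRI = 1 unreachable),
perfused area (pixel count × pixel area), and perfusion intensity
I = mean velocity × area / ROI area, which equals the sum of |v| over
perfused pixels divided by the ROI pixel count.  Velocity magnitudes pool
arterial and venous flow; the sign is only used for vessel-direction
checks.

Cardiac cycles are delimited by successive systolic peaks of the
intensity signal (intensity combines velocity and area pulsation and is
the smoother signal): local maxima with prominence ≥ 20% of the signal
range, peak spacing constrained to 40–180 bpm.  TFV and TPI average the
trace over the union of complete cycles; TRI is computed per cycle on the
mean-velocity trace, (v_max − v_min)/v_max with 0 for an all-zero cycle,
and averaged across cycles.  With fewer than two peaks the whole-trace
extrema are used and the result is flagged as a fallback rather than
dropped.

### Single-vessel flow (SVFM)

Candidate vessels are 4-connected components of the "ever perfused" mask.
Each component's flow direction is scored by the fraction of flow-bearing
frames whose modal velocity sign matches the component's overall modal
sign; a vessel with score ≥ 0.8 has a "known direction", and the largest
such component is measured.  Its axis is the principal eigenvector of the
pixel-coordinate covariance; the Doppler angle is arccos |axis · beam|;
the diameter is mask area / axis extent (a mean width, less sensitive to
pixelation than a single profile).  Per frame the envelope velocity is
the 98th percentile of |v| over the vessel pixels — a robust stand-in for
the spectral-envelope peak of a pulsed-wave gate that a strict maximum
would make fragile to single-pixel decode errors — divided by cos(angle).
FV/RI reuse the cycle machinery on this corrected trace; VolF = FV ×
π(d/2)².  Angles above 60° are computed but flagged invalid (the cos
correction amplifies small axis errors by tan θ; at 75° a 1° error is
already ~7% of FV), and a 90° vessel is unmeasurable.

### Statistics

Group comparisons follow the two-branch recipe: both groups passing a
Shapiro–Wilk gate at α = 0.05 → Welch t-test with mean ± SD summaries,
otherwise Mann–Whitney U with median (Q1–Q3).  The ROC AUC is the
Mann–Whitney concordance estimator (ties count ½), auto-oriented so
AUC ≥ 0.5; the reported cut-off ("nadir value") maximizes Youden's J over
observed values with ties broken toward higher specificity and then the
smaller threshold, making reports deterministic.  The AUC-vs-0.5 p-value
uses the tie-corrected normal approximation of the U statistic.  Paired
AUC comparison uses DeLong's method with placement values; identical or
monotone-transformed inputs give a zero statistic and p = 1 exactly.

## Synthetic cohorts

The generator emulates the *published group distributions* of the six
parameters, then constructs per-case velocity fields realizing each draw,
then renders them through the colorbar codec.

Calibration per label: TFV is a truncated normal with the published
mean ± SD (1.422 ± 0.742 malignant, 2.653 ± 0.733 inflammatory).  TPI,
FV and VolF are two-piece log-normals: the median is matched exactly and
the lower/upper log-SDs are solved separately from Q1 and Q3, so all
three printed quartiles are reproduced exactly (the printed IQRs are far
too asymmetric for a one-sigma log-normal; with the median pinned, the
single-sigma least-squares fit over log-quartiles would still miss both
quartiles, and it pushes the implied tissue-perfusion AUC far from the
reported value, whereas the two-piece fit lands on it).  TRI and RI are
mixtures: malignant lesions have a dominant point mass at 1.0 (diastolic
no-flow) with a small band below 1 and a low tail, weighted so the
published sensitivity at the reported cut-off holds; inflammatory TRI is
a Beta (refitted around a 12% no-flow mass), inflammatory RI a normal
clipped to [0, 1] whose clipped quartiles reproduce the published
0.648 / 0.843 / 1.000.  Draws violating physics (velocity beyond the
colorbar, implausible lumen diameter, TPI ≥ TFV) are redrawn.

Case construction: a straight main vessel carries the single-vessel
signal — diameter from the drawn VolF and FV, orientation at the drawn
Doppler angle (normal 48.7 ± 19.1°, truncated to [5°, 80°]), parabolic
cross-profile, raised-cosine cardiac waveform (systole occupies half the
cycle; the waveform floor is 1 − RI).  Small "scenery" segments supply
the remaining tissue perfusion: their pixel count and flat velocity are
solved so the pooled ROI mean velocity equals the drawn TFV, and their
waveform floor is solved so the pooled trace floor equals the drawn TRI.
Pixels whose instantaneous velocity falls below the smallest colorbar
velocity are not painted (wall-filter behavior) — this is what makes
malignant TRI exactly 1.  The ROI is a disk sized so the vessels occupy
the drawn vascular fraction (TPI/TFV), capped at 220 000 pixels; at the
published fractions (~0.3%) and vessel calibers this ROI is larger than a
physical pancreatic lesion — the published parameter combination forces
that choice, and only relative areas enter any parameter.  Default
geometry: 0.02 cm/px, 15 Hz, 4 s clips.

Ground truth is computed *numerically* from the constructed velocity
fields over the analytically known cardiac cycles, with the same
estimators the pipeline uses — so discretization, sampling and
wall-filter effects live inside the truth, and recovery tests measure
only what decoding and detection add.  Identical parameters and seed
give bit-identical cases.

### What the generator does not emulate

Speckle statistics, attenuation, aliasing, wall filters beyond a hard
velocity floor, vessel curvature and 3-D geometry, probe or tissue
motion, and inter-parameter correlations beyond those implied by the
physical consistency constraints.  Passing recovery tests shows the
pipeline inverts its own forward model faithfully; it does not certify
performance on scanner data with unknown colorbars or heavy post
processing.

## Numerical choices

- Colorbar default: two branches of 48 geometrically spaced velocities,
  0.25–20 cm/s (~5% relative step, so quantization error is a fixed
  fraction of velocity at every scale).
- Chroma threshold 24/255; RGB noise default 2 counts — misclassification
  then moves a pixel at most one or two colorbar entries, which the
  98th-percentile envelope and ROI averaging absorb.
- Peak detection: prominence 0.2 × signal range, heart-rate window
  40–180 bpm; cycle intervals longer than the slowest plausible beat are
  discarded.
- Direction-consistency threshold 0.8; angle validity cap 60°.
- Degenerate inputs are errors, not silent defaults: empty ROI, constant
  statistical samples, single-class ROC inputs and sub-3-pixel vessel
  masks all raise typed exceptions that the pipeline converts into
  per-case exclusion records.

## Problem sizes in the test-suite studies

Distribution-level studies (cohort pattern across 100 seeds, calibration
fidelity at n = 500 per label) run on parameter draws without rendering.
Rendered-case studies use 50 noiseless cases for parameter recovery and
six-case cohorts for pipeline plumbing.  The DeLong-vs-bootstrap
calibration check uses 600 DeLong and 250 bootstrap cohorts; medians of
the heavy-tailed parameters are asserted at the sampling precision a
500-case median supports (±10–15%), means and low-skew medians at ±5%.

## Known limitations

- The colorbar must be supplied (or the default synthetic one used);
  there is no automatic colorbar extraction from burned-in legends.
- Vessel diameter from mask area/length systematically averages width
  along the vessel; VolF inherits that approximation, consistent with
  lumen measurement being the least reliable part of the physical
  measurement as well.
- TRI/TFV estimates assume a stationary ROI; probe or organ motion is
  out of scope.
- Above 60° the angle-corrected FV is reported but should be treated as
  falsified, mirroring the validity limit of the physical method.
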