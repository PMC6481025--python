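# Methods

## Scope and model

`ocutort` measures the tortuosity of retinal and bulbar-conjunctival
vessels from 8-bit ocular photographs (protocol frame 1536 × 1024 px) and
runs the corresponding two-group observational analysis. Its stages are

1. **synthetic data** — parametric vessel centerlines, rasterized
   vessel-like images, and simulated two-group cohorts;
2. **tracing** — semi-automatic centerline extraction from three
   operator-selected points;
3. **metrics** — SOAM, PAD and I2e on resampled centerlines;
4. **statistics** — per-site Mann–Whitney group and sex comparisons,
   OLS regressions on age and systemic severity markers, demographics.

## Tortuosity metrics

All indexes are computed on the polyline resampled to uniform arc-length
spacing (default 5 px) because turning-angle statistics depend on
sampling density; fixed spacing makes segments of 250–500 px comparable.
Angles use `arccos` of the normalized chord dot product, clamped to
[−1, 1] against floating-point drift. The polyline is first oriented
canonically (lexicographically smaller endpoint first) so results are
exactly independent of tracing direction. Definitions:

* SOAM = Σθ_k / L (rad/px);
* PAD = Σθ_k d_k / L, d_k the mean of the two adjacent chord lengths —
  equal to spacing × SOAM under exactly uniform spacing;
* I2e = mean sliding arc-to-chord ratio over point triplets e = 2 samples
  apart; a fold-back that degenerates the base chord raises an error.

Closed forms used as test oracles: a circular arc gives SOAM = 1/r and
I2e = 1/cos(eΔs/2r); a right-angle triplet gives SOAM = PAD = π/4 and
I2e(e=1) = √2; straight lines give (0, 0, 1) exactly.

## Synthetic vessels and cohorts

Centerline families: straight line, circular arc, sinusoid, and a
random-curvature walk. The cohort generator uses sinusoids, whose
amplitude at fixed wavelength serves as a one-parameter ground-truth
tortuosity axis. This monotonicity is *regime-limited*: SOAM and PAD peak
near amplitude ≈ 0.2 × wavelength (arc length in the denominator then
outgrows total turning) and I2e peaks later. The cohort defaults are
therefore chosen to keep essentially the whole amplitude distribution
inside the monotone regime (see below).

Rasterization renders a dark Gaussian cross-section profile
(full width at half depth 10 px ⇒ σ ≈ 4.25 px) on a bright background
(background 200, depth 80 on the 0–255 scale), with optional additive
Gaussian noise, evaluated from the exact distance to the densely
resampled centerline and clipped to 8 bits. Vessels are darker than the
background, as in fundus and conjunctival photography; the model is
single-channel (the analog of the green channel, which carries the
highest vessel contrast).

Cohort defaults (the simulated study conditions): 11 subjects per group,
two eyes, 5 retinal + 3 segments per conjunctival sector, segment chords
uniform in 350–500 px (retina) / 250–400 px (conjunctiva), wavelength
100 px, baseline amplitude 2 px, subject-level lognormal factor with
log-SD 0.5 shared across a subject's eyes and sites, independent
per-segment lognormal noise with log-SD 0.15, ages uniform 30–71 years,
sexes balanced. The affected group's amplitude is multiplied by 2.0 at
the retina and nasal conjunctiva and 1.0 elsewhere, mirroring the sites
where a disease effect is expected. With these values the 99.5th
percentile of affected amplitudes at a 3× effect (~23 px) still sits at
the edge of the monotone regime, so group separation survives any
monotone index transform. Renal/cardiac covariates (GFR, wall thickness,
NYHA, stroke) are generated for affected subjects only, matching a
healthy-volunteer control design.

What the generator does *not* emulate: vessel branching and crossings,
caliber variation, illumination gradients, optic disc and macula,
camera noise correlation, or any empirical distribution of human
tortuosity values (none is published for this design). Passing tests
therefore demonstrate correctness of the measurement and inference
machinery under a controlled model, not clinical performance on real
photographs.

## Tracing

The tracer emulates the study's semi-automatic protocol ("click three
points along the vessel"):

1. the image (green channel if RGB) is cropped around the seed bounding
   box plus a 60 px margin; vesselness is a multiscale Hessian ridge
   (Sato) response at scales 2–5 px, min–max normalized per crop;
2. each seed is snapped to the darkest pixel within 4 px — clicks land
   near, not on, the axis, and snapping is what makes repeated seeding
   reproducible (without it, seeds jittered perpendicular to or beyond a
   vessel tip leave hooks that push the SOAM CV far above acceptable);
3. two 8-connected minimal-cost paths (seed1→seed2→seed3) are found with
   step cost = step length × (ε + 1 − vesselness), ε = 0.05 so all
   pixels stay reachable;
4. the grid path is smoothed (centered moving average, window 5), then
   refined to subpixel accuracy: the inverted intensity, blurred with a
   σ = 2 px Gaussian to suppress 8-bit quantization noise, is sampled
   with cubic splines along each point's normal and a least-squares
   parabola over the ±2.5 px profile locates the vertex (full-window
   fitting averages quantization noise that a 3-point fit amplifies);
5. a quadratic Savitzky–Golay filter (window 9) removes residual
   per-point noise without the amplitude attenuation a moving average
   would add, and the known inward shift of a blurred curved ridge
   (≈ curvature × σ², here σ² = 4) is corrected analytically.

Tracing runs in a canonical seed direction and flips the result back, so
reversed seeds give exactly the reversed polyline. Segment validation is
soft: warnings for arc length outside the protocol window (350–500 px
retina, 250–400 px conjunctiva), for self-intersection, and for low mean
vesselness along the path.

Measured on noiseless synthetic images (20 random tortuous geometries
per seed, amplitudes 8–16 px as the protocol selects the most tortuous
segments): mean centerline deviation ≤ 0.1 px, worst index disagreement
with ground truth < 1%. Fidelity comparisons clip the ground-truth curve
to the arc the trace actually spans, since seed snapping can shorten a
segment by a few pixels at the vessel tips; per-unit-length indexes are
otherwise biased by pure windowing. Arteries and veins are not
distinguished.

## Statistics

Unit of analysis: segment values are averaged within each eye, then the
two eye means are averaged, giving one value per subject × site × index.
This avoids pseudo-replication from correlated eyes; a per-eye mode
exists behind configuration. The Mann–Whitney U test computes U from
midranks; for n1 + n2 ≤ 16 without ties the two-sided p-value is exact by
full enumeration of rank assignments (two-sided p = min(1, 2 × smaller
tail)), otherwise a normal approximation with tie-corrected variance and
0.5 continuity correction is used — study-sized groups (11 vs 11) sit
near this boundary, so both paths exist and are cross-checked. Sample SD
uses the n−1 denominator. Regressions are ordinary least squares with a
t-test on the slope. α = 0.05 with no multiplicity correction (each
question compares exactly two groups). Any comparison lacking data
(missing covariate, empty stratum, constant regressor) is reported as
skipped with a reason, never dropped silently. The conjunctiva–retina
association regresses each subject's mean conjunctival value on the
retinal value, per index.

## Monte Carlo design

Type-I error and power are estimated by replicating the statistic
pipeline end to end — cohort generation → per-segment indexes →
subject-level aggregation → Mann–Whitney — on generated centerlines
sampled directly at the 5 px metric spacing. The tracing stage is
validated separately to subpixel accuracy, so omitting rasterize+trace
from each of the ~750k simulated segments changes nothing about the
statistic's distribution while keeping 1000-replicate runs around a
minute. Null calibration uses 1000 replicates at n = 11 + 11 (retina,
SOAM); the power sweep uses 500 replicates per effect level
{1.0, 1.5, 2.0, 3.0} with common random numbers across levels (the same
replicate seeds), a standard variance-reduction device that also makes
the estimated power curve monotone replicate by replicate.

## Reproducibility harness

The seed-jitter experiment re-traces a noiseless moderate-tortuosity
vessel (sinusoid amplitude 10 px, wavelength 100 px, span 400 px) with
all three seed coordinates independently perturbed by uniform ±3 px, 20
repeats per vessel across 10 vessels differing in phase, and reports the
per-index coefficient of variation. Measured CVs are ≤ 0.6% for SOAM and
PAD and ≤ 0.01% for I2e — comfortably inside the ≤ 2% reproducibility
reported for repeated manual seeding of such software on normal-subject
vessels, which this experiment emulates.

## Numerical and design choices

* Pixel convention: centers at integer coordinates, x rightward, y
  downward, 0-based.
* Resampling preserves both endpoints exactly; the remainder lands in
  the final interval; metric computation re-orients the polyline
  canonically so direction never matters.
* `arc` curve family: the span parameter is the arc length along the
  circle (radius is the amplitude parameter); SOAM = 1/r either way.
* I2e's denominator guard (1e−9) turns fold-back geometries into
  explicit errors rather than silent infinities.
* Exact/approximate Mann–Whitney threshold n1 + n2 ≤ 16; identical
  samples (zero tie-corrected variance) return p = 1.
* The pipeline's default `trace_mode="centerline"` computes metrics on
  generated centerlines; `"raster"` additionally rasterizes and
  re-traces every segment (used for validation and demos; about 0.5 s
  per segment).
* Report payloads carry no timestamps, so a fixed seed reproduces runs
  byte for byte.

## Known limitations

* The synthetic tortuosity model is single-harmonic; real tortuous
  vessels mix spatial frequencies and the indexes' sensitivity to that
  mixture is untested here.
* Index values are resolution- and spacing-dependent (SOAM scales as
  1/pixel size); values are comparable only within a fixed protocol.
* Above amplitude ≈ 0.2 × wavelength the turning-angle indexes are
  non-monotone in amplitude; effect sizes simulated outside that regime
  would not map monotonically onto the indexes.
* The tracer assumes a single dominant dark vessel between the seeds;
  branching or crossing vessels can capture the minimal-cost path.
* The exact Mann–Whitney enumerates C(n1+n2, n1) splits and is only
  engaged up to n1 + n2 = 16.
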