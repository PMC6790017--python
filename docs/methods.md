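# Methods

## Scope

`archfatigue` analyses cyclic-loading experiments on the foot arch: it
segments multi-channel load/displacement traces into loading cycles, computes
per-cycle arch metrics (bony arch index, flexibility, energy absorption),
stages the fatigue trajectory by AIC-selected polynomial fits with
second-derivative inflection detection, and runs the nonparametric
group-comparison battery. A synthetic-data generator stands in for the
cadaveric experiment so the whole chain is verifiable without access to
specimens.

## The experimental protocol being emulated

Three groups of six specimens each: *normal* (500 N peak axial load), *obese*
(1000 N), and *insole* (1000 N with an arch-support insole). Each specimen
receives 10,000 triangular 0→F→0 load cycles at 1 Hz, sampled at 20 Hz.
A cycle's weight-bearing phase is the run of samples with load ≥ 50 N; the
non-weight-bearing phase is everything below. A 32 N posterior-tibial-tendon
traction engages whenever the axial load reaches 150 N. The navicular marker
height is read with 0.06 mm translational accuracy. Weight-bearing height is
taken at the sample of maximum load within an excursion, non-weight-bearing
height at the sample of minimum load in the following trough (ties break to
the earliest sample; a final excursion with no following trough is dropped).
Cycle indices are 1-based.

## Generative model

### Group-mean trajectory

The weight-bearing BAI of a group follows a cubic B(c) in the cycle index.
Writing B′(x) = −A(x − x₀)² + k with A > 0 and k < 0 gives a cubic that is
strictly decreasing on all of ℝ, declines steeply at first (creep stage I),
flattens near the inflection x₀ (stage II) and re-accelerates after it
(stage III). Calibration solves the 4×4 linear system fixing:

| group  | B(1) | anchor           | B″ = 0 at | B(10000) |
|--------|------|------------------|-----------|----------|
| normal | 0.24 | B(1000) = 0.234  | 9000      | 0.218    |
| obese  | 0.24 | B(1000) = 0.203  | 6500      | 0.124    |
| insole | 0.24 | B(6000) = 0.200  | 7833      | 0.195    |

The first-cycle value 0.24 is the midpoint of the normal arch band
(0.21–0.27); groups share it because first-load BAI does not differ between
groups. The checkpoint anchors and inflection cycles for the obese and
insole groups are the published group means. The 10,000-cycle endpoints are
**calibration constants, not measured values**: once the first-cycle value,
the checkpoint anchor and the inflection are fixed, monotonicity pins the
endpoint to a narrow range (a cubic through a steep stage I and an interior
inflection cannot also end high without rising in between). The solver
rejects non-monotone solutions with a diagnostic, and reports linearly
dependent constraint sets. Internally the system is solved on a scaled
abscissa (cycles / 10⁴) and coefficients are returned on the raw cycle
scale.

### Specimen-level variation

* **Foot length** ~ N(250, 10²) mm. BAI is scale-free, so this only sets
  absolute heights.
* **BAI offset**: one additive draw per specimen; SD 0.006 (normal), 0.0055
  (obese), 0.0085 (insole). Chosen so the across-specimen SD at the anchor
  checkpoints reproduces the published 95% CIs (obese at cycle 1000:
  CI 0.196–0.209 ⇒ SD ≈ 0.0062 after adding the jitter and cycle-noise
  contributions; insole at 6000: CI 0.191–0.209 ⇒ SD ≈ 0.0086).
* **Inflection jitter**: per specimen the cubic's argument is time-scaled,
  B_s(c) = B(αc) with α = x₀/(x₀ + δ), δ ~ N(0, SD²) truncated at ±3 SD
  (SD = 547.7 cycles obese, 753 insole, 600 normal — the first two are the
  published across-specimen inflection SDs). Scaling (rather than shifting)
  the argument keeps the first-cycle BAI common to all specimens, keeps the
  trajectory monotone (k < 0 makes the cubic decreasing on all of ℝ), and
  places the specimen's true inflection at exactly x₀ + δ.
* **Cycle-level height noise**: i.i.d. per-cycle fluctuation of the
  weight-bearing height (repositioning/soft-tissue scatter), SD 0.15 mm
  (normal), 0.3 mm (obese), 0.1 mm (insole), plus per-sample marker noise of
  0.06 mm (the stated accuracy of the optical tracker).
* **Lack-of-fit profile**: real creep curves are not exactly cubic. Each
  group's weight-bearing height carries a smooth deterministic waveform,
  shared by all specimens of the group, built from low-frequency sine
  harmonics constrained to (a) zero discrete inner product with every
  monomial up to degree 5 on the cycle grid and (b) zero value at the
  checkpoint cycles. It therefore changes **neither** the checkpoint group
  means and CIs **nor** the coefficients (hence inflections) of polynomial
  fits up to order 5 — its only effect is the residual variance of the
  trajectory fits. Its RMS amplitude (0.32 / 1.57 / 0.69 mm for
  normal / obese / insole) is set so the cubic's coefficient of
  determination on the full per-cycle series is ≈ 0.947, the reported fit
  quality. This was the only construction we found that is simultaneously
  consistent with the published fit quality, the published checkpoint CIs,
  and the published inflection SDs: unstructured within-specimen noise large
  enough to bring R² down to 0.947 would inflate the across-specimen
  checkpoint SDs severalfold and would swamp the inflection estimates.
* **Deformation**: initial elastic deformation d₀ = 4.0 mm (normal, 500 N),
  6.0 mm (obese), 4.0 mm (insole) with 5% per-specimen SD, decaying as
  d(c) = d₀·[1 − (1−r)·s^0.5] with s the normalized cycle index and retained
  fraction r = 1.0 / 0.6 / 0.75 — i.e. no fatigue stiffening under 500 N,
  strong stiffening in the obese group, partial protection with the insole.
  These values are not published anywhere (the source reports box plots
  only); they were chosen once to reproduce the qualitative orderings:
  first-load flexibility normal > obese > insole, first-load energy
  absorption highest in the obese group, and first-vs-last deltas
  obese > insole. Per-cycle deformation noise SD 0.05 mm.
* **Tendon channel**: 32 N ± 0.2 N whenever load ≥ 150 N, exactly 0
  otherwise.

Within a cycle the height interpolates linearly in the load between the
weight-bearing height (at peak) and that plus d(c) (at zero load). Height
parameters switch at the first loaded sample of each cycle, so the trough
*after* cycle c carries cycle c's deformation and a noise-free trace
round-trips exactly through segmentation. A short zero-load tail after the
final cycle gives it a complete trough. One master seed drives everything;
specimen streams are seeded with (master_seed, specimen index).

## Fitting and staging

Candidate polynomial orders are {1, …, 5}; each is fitted by least squares on
a scaled abscissa (coefficients are reported on the raw cycle scale) and
scored by AIC = n{log(2πSₑ/n) + 1} + 2(p + 1) with the natural logarithm;
ties break toward the smaller order, and a numerically zero Sₑ is floored
with a warning. By default fits use **every recorded cycle** rather than the
11-point checkpoint grid: with 11 points, the sampling error of the cubic
coefficients alone would add ≈1,000 cycles of scatter to each inflection
estimate (swamping the ≈550-cycle biological spread), whereas the full-series
fit makes the estimate essentially exact per specimen, so the reported
inflection SD is the specimen-to-specimen spread — the only reading under
which the published fit quality (R² ≈ 0.947) and the published inflection
SDs (547.7 and 753 cycles) can coexist. A `fit_grid="checkpoints"` option
restores the sparse fit.

Inflection points are the real roots of the fitted polynomial's second
derivative inside the observed cycle range, reported in ascending order; the
*primary* inflection (stage II→III) is the first root where f″ crosses from
positive to negative (f‴ < 0). A cubic whose leading coefficient vanished
yields none, with a warning.

R² is reported per specimen (1 − Sₑ/SStot, defined as 1.0 with a warning for
a constant series) and summarized as a mean across specimens; the resampling
unit behind the published R² interval is not stated anywhere, so the
per-specimen distribution is an assumption, flagged here.

## Statistics

Checkpoint grid {1, 1000, 2000, …, 10000}. Per group and checkpoint: mean,
SD and the t-interval mean ± t(0.975, n−1)·SD/√n (a percentile-bootstrap
option exists; the t-interval is the default because means with 95% CIs are
what this literature reports alongside nonparametric tests). Normality is
screened by one-sample Kolmogorov–Smirnov against a normal with plug-in
parameters (a Lilliefors-corrected variant is available; the original
analysis does not say which was used). Between-group comparisons use
Kruskal–Wallis; pairwise comparisons run only when the omnibus test is
significant (gatekeeping), as exact two-sample Mann–Whitney tests — exact
because at n = 6 per group the asymptotic p is unreliable — with Bonferroni
adjustment over the three pairs. Time trends within a group use the Friedman
test (specimens as blocks, checkpoints as treatments; missing cells are
rejected by name). First-vs-last deltas are cycle-1 minus cycle-10,000
values per specimen. "BAI significantly below the low-arch criterion" is
operationalized as the 95% CI upper bound falling below 0.21, and the
low-arch onset is the earliest such checkpoint.

## Numerical and degenerate-input choices

* Constraint systems: singularity detected at relative rank tolerance 1e-10,
  with the dependent constraints named; monotonicity checked analytically
  (B′ is quadratic, so its maximum on the range is at an endpoint or vertex).
* Segmentation requires uniform timestamps (relative tolerance 1e-6) and
  warns, returning an empty table, when the threshold is never crossed.
* Negative deformations (h_nwb < h_wb) are kept, with a warning — clipping
  would bias real data.
* All-tied group comparisons report statistic 0, p = 1; time-constant
  Friedman blocks likewise.
* Cohorts of one specimen per group run end to end with CIs flagged
  undefined and group tests skipped.

## What the synthetic cohort does and does not show

The generator reproduces the *group-level statistical structure* of the
bench experiment: trajectory anchors and inflection locations, checkpoint CI
widths, cubic fit quality, and the qualitative orderings of flexibility,
energy absorption and their time trends. Passing tests therefore demonstrate
that the analysis chain — segmentation, metric formulas, AIC selection,
inflection detection, statistics — is correct and would recover such
structure from real traces. They do not validate the biology: the creep
model is phenomenological (no tissue mechanics, no insole material model, no
3-D kinematics), the deviation of real trajectories from a cubic is emulated
by a constructed orthogonal waveform rather than derived from physics, the
first-load deformation scales are calibration choices, and the lack-of-fit
profile's exact-zero behaviour at checkpoints is a design convenience real
data will not share. Onsets of the low-arch criterion at specific
checkpoints are knife-edge events at n = 6 (the published obese CI upper
bound at cycle 1000 is 0.209 against the 0.21 criterion), so the robust,
testable claims are the orderings (obese before insole, normal never), not
the exact checkpoint indices.

## Problem sizes used by the test suite

The suite analyses one full 18-specimen × 10,000-cycle cohort and twenty
replicate obese+insole cohorts (the replicate grand mean is the right
estimator for calibration checks: a single n = 6 cohort has a standard error
comparable to the published CI half-widths). Null-distribution checks use
2,000 simulated three-group samples. The whole suite runs in well under a
minute of compute plus the cohort generation time.
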