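# Methods

## Individually adjusted METs and individual cut points

A subject's MET value at a treadmill stage is the steady-state VO2
(ml/kg/min, mean of the last two minutes of the stage) divided by that
subject's measured resting VO2, following the original definition of
1 MET as resting metabolic rate. A `standard` mode dividing by the
3.5 ml/kg/min convention is available for sensitivity analyses; the two
modes differ systematically in heavy subjects, whose resting VO2 per kg is
typically below 3.5.

The individual cut point (ICP) is derived by ordinary least squares of MET
on counts/min over the five stages (2–6 km/h), solved at the target of
3 METs: ICP = (3 − a)/b. Fit diagnostics are the Pearson correlation
between METs and counts (reported as 0 with a warning when either variable
is constant) and the standard error of the estimate with denominator
(n − p). A quadratic fit (smallest positive root at the target) is
implemented but off by default: with five observations per subject a
quadratic is prone to over-fitting, so the linear model is the primary
specification.

**Floor rule.** A fitted line can cross 3 METs at or below zero counts/min
(subjects above 3 METs at the slowest stage with a shallow slope). Such cut
points are replaced by 100 counts/min and flagged. The boundary case of a
crossing at exactly zero is floored too — a zero cut point would classify
every worn minute as MVPA, which the floor exists to prevent.

**Walking speed at the target.** Speed at 3 METs is obtained by
piecewise-linear interpolation of the stage MET profile against speed. When
the subject exceeds 3 METs already at 2 km/h the first segment is
extrapolated downward (clamped positive); if measurement noise makes that
segment non-increasing, the least-squares MET~speed trend over all stages
supplies the extrapolation slope. Non-monotone profiles return the first
crossing with a warning.

## The pooled mixed model and the group cut point

The group cut point (GCP) comes from

    MET_ij = β₀ + β₁·counts_ij + u_i + e_ij,
    u_i ~ N(0, σ²_u),   e_i ~ AR(1)(ρ), Var(e_ij) = σ²_e,

with residuals ordered by stage rank (treadmill speed as the repeated
measure). Estimation is restricted maximum likelihood. The implementation
profiles the fixed effects out of the restricted likelihood and maximizes
numerically over (log σ²_u, atanh ρ, log σ²_e) with Nelder-Mead from three
fixed starting points (moderate/strong/weak clustering) to guard against
local optima; counts are rescaled to O(1) for conditioning and the residual
variance is floored at 1e-10 so exactly collinear (noiseless) data cannot
underflow the objective. Per-subject covariance matrices depend only on
group size, so one inverse per distinct size serves every subject in an
objective evaluation. Fixed-effect intervals are 95% Wald intervals from
the GLS covariance at the REML optimum; interval type for the pooled model
is a design choice, as is reporting the GCP both unrounded and rounded to
the nearest integer count. When the variance components vanish the profiled
GLS estimator reduces to pooled OLS exactly; this identity is tested, as is
parameter recovery (bias within Monte-Carlo error, ~95% CI coverage) over
200 simulated cohorts of 40 subjects.

## Free-living scoring

Field streams are reintegrated from 10-s epochs to 60-s resolution
(trailing partial blocks are dropped, never zero-padded, since padding
would fabricate wear time) and split at midnight into calendar days; the
60-s resolution matches the counts/min scale on which cut points are
defined and the convention of the software era the pipeline emulates.
Scoring rules, all configurable with these defaults:

* **Non-wear**: maximal windows >= 60 min containing <= 2 non-zero minutes,
  found by a greedy left-to-right scan that terminates a candidate
  immediately before its third non-zero minute and trims trailing non-zero
  minutes. Interruption minutes may have any magnitude — no 100-count spike
  ceiling is applied, a documented divergence from Troiano-style rules.
* **Valid day / measurement**: >= 600 wear minutes; >= 5 valid days.
* **MVPA minute**: worn and counts/min >= cut point. The boundary is
  inclusive because the cut point is the exact solution of the calibration
  regression at 3 METs.
* **Bout**: a window >= 10 min starting and ending on an MVPA minute with
  <= 2 non-MVPA minutes in total ("2-minute drop allowance", counted per
  bout, not per interruption, and not required to be consecutive); non-wear
  minutes count as drops. Bout minutes include the allowed drops. The same
  greedy scan is used; whether commercial software terminates on the third
  drop or uses a sliding-percentage rule is not documented, so the rule
  here is declared and oracle-tested rather than assumed bit-compatible.

Both detectors are verified against an independent brute-force oracle that
enumerates every candidate window and applies the stated rules directly;
the greedy tiling (smallest start, then longest valid window, resume after
it) is identical by construction and confirmed on thousands of random
streams. All interval outputs are 0-based half-open minute indices.

## Agreement statistics

SEM = SD of paired differences / √2 and LoA = SEM·√2·1.96 (algebraically
1.96·SD; the identity is property-tested). Limits are centred on the median
difference by default — matching the convention of reporting differences as
median (IQR) — with the mean available. The between-method CV is the SD of
paired differences over the grand mean of all observations, ×100 (the
typical-error-as-CV reading of "CV = SD/mean"); an averaged per-pair CV is
available behind a flag. Partial correlations are computed from the full
linear model as t/√(t² + df) with the sign of the coefficient, which equals
the residual-on-residual correlation (tested to 1e-10). The paired Wilcoxon
test uses the exact enumerated null on non-zero differences up to n = 25
and a continuity-corrected normal approximation beyond. Cohen's kappa for
the >= 30 min/day bouted-MVPA guideline uses the standard 2×2 formula with
a Fleiss normal-approximation p-value against κ = 0; degenerate margins
yield an undefined (NaN) kappa with percent agreement still reported. No
multiple-testing correction is applied anywhere, matching the single-study
reporting convention the pipeline reproduces.

## Synthetic data

The generator emulates a severely obese calibration cohort. Each subject is
constructed backwards from a drawn true cut point: ICP ~ N(1151, 685²)
truncated at 100 counts/min (jointly with BMI ~ N(39.8, 5.7²), correlation
0.3), resting VO2 ~ N(3.04, 0.40²) ml/kg/min, and a counts-per-speed slope
k ~ N(550, 120²) counts/min per km/h above a 0.8 km/h offset, constrained
so the implied speed at 3 METs stays below 5.5 km/h. The walking VO2
profile is linear in speed at 1.8 ml/kg/min per km/h, anchored so that
3×resting VO2 falls exactly at v₃ = 0.8 + ICP/k; the subject's work
economy (VO2 at 3 km/h) is therefore derived from, not drawn independently
of, the cut point. This makes ICP heterogeneity arise jointly from resting
VO2 (+), work economy (−) and the count slope, reproducing the cohort's
explanatory structure qualitatively without hard-coding any partial
correlation. Stage noise defaults (VO2 SD 0.75 ml/kg/min, counts SD 60
counts/min) put the median per-subject correlation near 0.98 and the median
SEE near 0.22 METs, in line with the cohort the generator emulates. With
noise at zero the construction is exactly invertible and the calibration
fit recovers the drawn ICPs to machine precision.

Mixed-model recovery cohorts are generated directly from the pooled model
(β₀ = 2.5276, β₁ = 0.000690, σ²_u = 0.04, ρ = 0.5, σ²_e = 0.02 by
default), with stage VO2 defined as MET × resting VO2 so the planted MET
values round-trip exactly through the MET computation.

For the two-hip comparison the metabolic measurement is shared between hips
while each hip's count slope is perturbed by an independent multiplicative
error with CV 0.215, plus independent stage count noise. In the noiseless
limit each hip's ICP is ICP·(1 + δ), so the expected between-hip SEM is
analytic: CV·√(E[ICP²]) ≈ 288 counts/min at the cohort's ICP moments. The
multiplicative form also reproduces regression toward the mean (extreme
right-hip cut points pull back on the left) as a pure consequence of
independent errors.

Free-living streams are planned at minute resolution: a 06:30–22:30 wear
window, one 75-min planted removal block of true zeros per day, positive
background activity below 60% of the smallest candidate cut point, planted
bouts (10–30 min, about half exercising the 2-minute drop allowance) and
short sporadic runs at >= 2× the largest candidate cut point. Activity
segments are separated by >= 3 background minutes so no window spanning two
segments can satisfy the drop allowance — the truth table is then a pure
function of the plan and scoring must reproduce it exactly, for every
candidate cut point. Optional intermediate-intensity runs and whole-bout
intermediate intensities (drawn strictly between the candidate cut points)
let the cut points genuinely disagree while keeping the truth exact; a
bout carries a single intensity so it qualifies wholesale under a given cut
or not at all. Minute counts are disaggregated uniformly onto six 10-s
epochs conserving each minute total exactly.

**What the generator does not emulate.** Real accelerometer output is not
piecewise-constant within minutes, background activity is autocorrelated
and brushes against cut points, device filtering and tilt are not modelled,
and the pooled count–MET cloud has none of the intercept/slope correlation
idiosyncrasies of the real cohort — in synthetic cohorts the pooled GCP
tracks the cohort mean ICP, whereas the real cohort's pooled estimate sat
well below its mean ICP. Passing the truth-table and recovery tests
therefore demonstrates the correctness of the scoring and estimation
machinery under the stated rules, not field validity of any cut point; and
cohort-specific published values (R², partial r magnitudes, medians of
MVPA minutes, CV percentages) are data-dependent and are not reproduction
targets.

## Numerical choices and degenerate inputs

* Epoch files without per-row timestamps reconstruct time as
  start + index × epoch length; header metadata overrides dialect defaults,
  and an explicit contradiction is a configuration error, not an override.
* Zero-variance differences in Bland-Altman give LoA = 0 with a warning;
  a non-positive grand mean makes the CV undefined (NaN in reports, an
  error when requested directly).
* A flat individual regression (b = 0) has no 3-MET crossing and raises;
  a negative slope warns (physiologically implausible) but computes.
* REML non-convergence from all starts raises carrying the best objective;
  |ρ| ≈ 1 warns of a boundary estimate.
* Analysis problem sizes: the recovery study uses 200 cohorts × 40
  subjects × 5 stages; detector verification uses 1000 random 300-minute
  streams; the default synthetic cohort is 42 subjects with a 22-subject
  two-hip subsample and 7-day free-living streams, mirroring the cohort
  structure the pipeline was designed around.
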