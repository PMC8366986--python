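# Methods

## Sway-index computation

A recording is two displacement series (AP, ML; mm) on a uniform grid
(device constant 50 Hz; nominal 60 s per eye condition, giving
n = 3001 samples and record span T = (n − 1)/fs — the inter-sample
span convention keeps the mean velocity of even a two-point record
finite).  Preprocessing removes each axis mean; the resultant distance
RD[i] = √(AP[i]² + ML[i]²) measures instantaneous distance from the
mean CoP position.  Irregularly sampled input is linearly interpolated
onto the target grid first (`resample`); analysis functions refuse
non-uniform grids rather than guessing.

Per condition the package computes 39 indexes, listed with units in
`cop_metrics.METRIC_REGISTRY` (a data table, so the roster can be
amended without touching code):

- distance (15): MDIST, RDIST, RANGE, TOTEX, MVEL — each planar and
  per axis.  The planar RANGE (largest distance between any two
  trajectory points) is computed on the convex hull, O(n log n); the
  O(n²) brute force is kept as a test oracle.
- area (3): 95% confidence circle AREA_CC = π(MDIST + 1.645·s_RD)²;
  95% confidence ellipse AREA_CE = 2πF·√(s_AP²s_ML² − s_APML²) with
  the large-sample F(0.05; 2, n−2) = 3.00 (exact quantiles via the
  `exact_quantiles` flag); sway area AREA_SW = (1/2T)·Σ|cross
  products|, the shoelace area swept about the mean per unit time.
- hybrid (6): MFREQ = MVEL/(2π·MDIST) (the rotation rate of a circle
  of radius MDIST swept at MVEL; per-axis analogue
  MVELd/(4√2·MDISTd)) and the three fractal dimensions
  ln N / ln(N·d/TOTEX) with d the planar range, the confidence-circle
  diameter, or the equivalent-ellipse diameter.
- spectral (15): Welch PSD per series (AP, ML, RD), Hann window, 10 s
  segments, 50% overlap, linear detrend per segment — a standard
  low-variance choice for 60 s records; records shorter than one
  segment fall back to a single segment with a warning.  Spectral
  moments μ_k = Σ f^k G(f) Δf on the 0.15–5 Hz band (the conventional
  posturography band: below 0.15 Hz lives slow drift, above 5 Hz
  noise; both edges configurable) give POWER = μ₀, POWER50/POWER95
  (cumulative-power quantiles), CFREQ = √(μ₂/μ₀) and frequency
  dispersion √(1 − μ₁²/(μ₀μ₂)).

Degenerate inputs are defined, not exceptional: a constant recording
yields zero distances, areas and power, and every ratio-type index
(MFREQ, CFREQ, FREQD, the fractal dimensions) returns 0 with a warning
when its denominator vanishes, so cohort-level statistics are never
poisoned by non-finite values.

Built-in invariants (enforced by the test suite): translation
invariance of every index; scale covariance (distances/velocities
linear, areas and power quadratic, pure frequencies invariant);
MVEL ≥ MVELAP, MVELML; POWER50 ≤ POWER95; MFREQ·2π·MDIST = MVEL to
machine precision.

## Synthetic study generator

No raw recordings are distributed with the source study, so the
generator reproduces its *statistical structure*: 414 subjects, 115
with the balance-alteration endpoint, per-group covariate means/SDs
(age 68.49 ± 6.07 vs 74.73 ± 6.10 y; BMI 26.95 ± 3.92 vs
29.15 ± 4.86 kg/m²; multimorbidity, polypharmacy, prior-fall and sex
proportions; gait speed; squat count) and per-group AP mean-velocity
distributions (10.88 ± 4.43 vs 15.35 ± 7.06 mm/s eyes open).  Sex is
drawn at 72.2% women in both groups, matching the source's identical
proportions.  Gait speed is stored in cm/s: the source table labels it
m/s but prints 103.98 ± 25.00, plausible only as cm/s; the unit is
flagged here and nowhere silently corrected.

Choices made where the study reports nothing:

- Velocity targets are lognormal, moment-matched to the printed
  mean/SD — velocities are positive and right-skewed; a normal option
  is retained for analytic checks.  The implied planar AUC of the
  default configuration is ≈ 0.71, consistent with the printed 0.714.
- Age and BMI use truncated normals at the inclusion bounds
  (age ≥ 60); the underlying (μ, σ) are solved so the *truncated*
  distribution has the configured mean/SD, since truncation alone
  would bias the group means (≈ +1 y for the younger group).
- ML-axis velocities are not tabulated per axis.  They are drawn with
  weaker group separation (12.0 ± 5.0 vs 14.0 ± 6.5 mm/s eyes open)
  and Gaussian-copula correlation ρ = 0.5 with the AP target, so that
  (a) the emergent planar mean velocity matches the printed planar
  means (17.75 / 23.15 mm/s) and (b) the planar index discriminates
  *worse* than the AP index, reproducing the printed AUC ordering
  (0.674 < 0.714).
- Covariates are generated independently within group (their
  correlations are not printed) — a documented limitation: joint
  covariate structure in real cohorts is richer.

Endpoint modes: `fixed` (default) fixes the group margins, so printed
tables are reproduced in expectation; `logistic` redraws the endpoint
from the generating coefficients β = (−17.32, 1.08, 0.23, 0.16, 0.16)
given each subject's covariates, which is the mode used for parameter
recovery.

Trajectories are 2nd-order Butterworth low-pass (1 Hz) filtered
Gaussian noise per axis — power concentrated in the sub-1 Hz band
where quiet-stance sway lives — rescaled so the computed mean axis
velocity equals the subject's target *exactly* (the Σ|Δx|/T functional
is linear in amplitude, so the rescaling is exact, not approximate).
All other indexes are emergent.  Because every AP eyes-open amplitude
index (MDIST, TOTEX, POWER, …) inherits the planted AP scale, the
top of a screened realization is a cluster of near-tied AP indexes;
which one wins a single draw of 414 subjects is sampling noise, and
tests assert membership in that cluster rather than one name.  This
generator emulates only what the downstream statistics consume; it is
not a biomechanical (inverted-pendulum) sway model, and passing tests
say nothing about physiological realism of individual trajectories.

## Screening and cut-off

Group comparisons: t-test when both groups pass Shapiro–Wilk at
α = 0.05, Mann–Whitney otherwise (normal approximation with tie
correction for groups larger than 20), χ² without continuity
correction for flags (the correction, available by flag, would not
reproduce the source's sex p = 0.989).  Raw p-values are reported
across the 78 indexes, as in the source; Benjamini–Hochberg adjustment
is a clearly-labelled optional extension, not a default.

ROC curves place thresholds at midpoints between consecutive distinct
scores with ±∞ sentinels; positive means score ≥ threshold (higher
sway velocity → higher risk; scores discriminating the other way get a
warning, never a silent flip).  The trapezoid AUC equals the
Mann–Whitney pair-counting estimate (ties worth ½) on every input —
this exact equivalence is property-tested.  AUC intervals use DeLong's
variance with a Wald interval clipped to [0, 1] (Hanley–McNeil by
flag).  The Youden cut-off maximizes J over all candidate thresholds,
ties broken toward the lowest (most sensitive) cut-off; the sentinels
are admissible, so a worthless score yields J = 0 at a degenerate
rule rather than a negative-J "optimum".  Dichotomization is boundary
inclusive (score ≥ cut-off flags risk).

## Risk model

Logistic regression is fitted by maximum likelihood (Newton/IRLS via
statsmodels, score tolerance 1e-8, 50 iterations; non-convergence and
perfect separation raise errors naming the suspect covariate).
Complete-case analysis: rows with any missing covariate are dropped
and counted.  Inference is Wald on the β scale; odds ratios and CI
bounds are exponentiated, so OR = exp(β) holds to machine precision.
Display rounding (β/OR to 2 dp, p to 3 dp) never propagates into
computation.

Hosmer–Lemeshow: subjects ranked by fitted probability, split into
g = 10 equal-count groups with tied probabilities kept together;
χ² = Σ (obs − exp)²/exp over both outcomes; df = g − 2, the reference
distribution for probabilities fitted on the same data.  Its type-I
error is verified by simulation (≈5% at α = 0.05 over 1000
well-specified fits).

Prediction applies the inverse logit to β₀ + β·x with sex coded
woman = 1 and the velocity dichotomized at the configured cut-off
(default 14.24 mm/s).  With the published 2-dp coefficients the two
canonical profiles evaluate to 7.67% (man, 70 y, BMI 22.70, below
cut-off) and 89.11% (woman, 80 y, BMI 33.20, at/above cut-off); the
source's own 7.17% / 88.28% derive from unrounded coefficients, and
the ±1 percentage-point agreement is the resolution the 2-dp rounding
permits.

Cochran planning uses the conventional two-decimal normal quantile
(z = 1.96 at 95%) and rounds n = z²pq/d² up.

## Problem sizes

Defaults chosen for routine runs: the full synthetic replica uses 414
subjects × 60 s × both eye conditions (≈ 15 s end to end); unit tests
use smaller cohorts and shorter records; simulation-based checks use
1000 replicates (binormal AUC recovery, HL calibration) and n = 50 000
for coefficient recovery.  All randomness flows from explicit seeds;
identical seeds give byte-identical study reports.

## Known limitations

- The 39-index roster follows the classical posturographic measure
  set; if a deployment needs a different roster the registry is the
  single point of change.
- Welch-based spectral measures at 0.1 Hz resolution cannot localize
  power features finer than one bin; POWER50/POWER95 are reported on
  the bin grid.
- The generator's independence of covariates within group and its
  non-biomechanical trajectories mean cohort-level conclusions
  transfer to real data only insofar as the summary structure
  (means/SDs, group separation) is what drives them.
- The Hosmer–Lemeshow test is known to be sensitive to the grouping
  rule near ties; the equal-count-with-ties-unsplit rule used here is
  stated so results are reproducible across implementations.
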