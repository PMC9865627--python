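# Methods

## Problem and scope

`stepvo2` estimates maximal oxygen consumption (VO2max, mL·kg⁻¹·min⁻¹) for
working-age adults from a submaximal step test — three 1-min stepping stages
on a 30 cm step (15, 20, 25 steps/min) followed by two 1-min seated recovery
stages — together with basic demographics and a 0–44-point physical-activity
(PA) questionnaire score. It implements three estimators, the agreement
statistics used to validate them against treadmill-measured VO2max, and a
synthetic cohort generator so the whole pipeline can be exercised end to end
without access to clinical data.

## Estimators

**Heart-rate index.** The step test is summarized by

    HR index = (HR_ex3 − HR_ex1) + (HR_rec1 − HR_rec2)   [bpm]

which adds the HR rise across the exercise stages to the HR drop during
recovery. Fitter subjects reach a lower exercise HR and have less elevation
to shed during recovery, so lower values indicate higher fitness. The index
is translation-invariant (adding a constant to all four HRs leaves it
unchanged) and undefined when stage 3 is skipped.

**MRM (multiple regression model).** A fixed-coefficient linear equation:

    eVO2max = 64.22 − 0.23·age + 5.74·I(male) − 0.57·BMI
            + 0.19·PA − 0.18·HRindex

The coefficients are published constants from a separate development sample
and are never re-fit here; they are overridable only as a full set, since
they were estimated jointly. Evaluation is exact and unclipped.

**LEM (linear extrapolation method).** Each step-test stage is assigned a
predetermined oxygen-uptake constant (mL·kg⁻¹·min⁻¹): (4, 13, 19, 22, 17, 8)
for women and (4, 14, 20, 23, 18, 8) for men across (rest, ex1–ex3, rec1,
rec2). An ordinary-least-squares line of stage HR (y) on stage VO2 (x) is
fit per subject over the available stages (six, or five if stage 3 was
skipped), then inverted at the subject's age-predicted maximal HR:

    eVO2max = (HRmax_pred − intercept) / slope,  HRmax_pred = 208 − 0.7·age

The regression direction (HR on VO2, then algebraic inversion) matches the
protocol's scatter-plot construction; regressing VO2 on HR would differ
whenever the points are not collinear. Two age-predicted maximal-HR formulas
coexist deliberately: the Tanaka form (208 − 0.7·age) is the extrapolation
target, while the Fox form (220 − age) is used by the protocol's stage-3
skip rule and by maximal-effort verification — exactly the roles each plays
in practice.

**Combined.** Compute the MRM estimate; if it meets the fitness cutoff
(default: ≥ 45.0 mL·kg⁻¹·min⁻¹), recalculate with the LEM. Rationale: fixed-
coefficient regressions compress the upper range (underestimating fit
subjects), while the extrapolation estimator is noisier overall but free of
that compression; switching only at the top combines the two strengths. The
output is always bit-identical to one leg, and the leg is selected solely by
the MRM value. The inclusive comparison (≥) is the default, with a strict
(>) variant available so the measure-zero boundary case is deterministic
either way. A failed LEM leg after switching propagates as a missing result
with a reason; it never silently falls back to the MRM value the rule just
rejected.

## Numerical and degenerate-input choices

* HR plausibility window [30, 230] bpm: generous enough for athletes,
  narrow enough to reject unit mistakes (e.g. RR intervals in ms).
* Ages outside the validated 30–60 band warn rather than error — the
  equations are formally evaluable at any adult age.
* LEM slope guard: fits with slope < 0.1 bpm per mL·kg⁻¹·min⁻¹ (including
  flat and negative lines) return a missing result with a reason; inverting
  a near-flat line would produce absurd extrapolations. The threshold is
  configurable and its use is reported in the result.
* Non-positive extrapolations are reported missing, never clipped; no
  winsorization anywhere.
* A skipped stage 3 leaves the MRM undefined (the HR index needs stage 3)
  while the LEM fits the remaining five points with stage 3's constant
  dropped. This path is an extension beyond the validated protocol and is
  flagged via reason codes.
* The maximal-effort check on the criterion treadmill test requires three
  of four: RER > 1.10, observed max HR within 10 bpm of 220 − age,
  RPE > 17, and a VO2 plateau. The RER/RPE thresholds are strict
  ("exceeded"), intentionally asymmetric with the skip rule's inclusive
  targets ("an RPE of 17"). The plateau is a boolean input (unknown counts
  as unmet); a helper comparing two final-stage VO2 values against a
  2.0 mL·kg⁻¹·min⁻¹ delta exists but is never auto-invoked, because plateau
  operationalizations vary across laboratories.

## Agreement statistics

For paired measured (Y) and estimated (Ŷ) values:

* CE = mean(Y − Ŷ), with sample SD and a two-tailed one-sample t-test.
* SEE = SD(Y)·sqrt(1 − r²), r the Pearson correlation of Y with Ŷ; the
  sample (n−1) SD is used (the choice is immaterial at n ≈ 128 but fixed
  for determinism).
* TE = sqrt(Σ(Y − Ŷ)²/n), the RMSE. Taking the root keeps TE in
  mL·kg⁻¹·min⁻¹ and comparable with SEE, and yields the exact decomposition
  TE² = CE² + (n−1)/n·SD(diff)².
* Bland–Altman: differences d = Ŷ − Y (so the fixed bias is exactly −CE;
  the two sign conventions are mirror images and both are conventional in
  this literature), 95% limits of agreement at ±1.96 sample SDs (the
  conventional multiplier, not a t-quantile), and proportional bias as the
  Pearson correlation of d against the pair mean (Y + Ŷ)/2 — the standard
  abscissa, which avoids the spurious correlation that regressing on either
  single method induces. The correlation t-test p equals the regression
  slope's t-test p for a simple regression, so the two framings coincide.
* Missing estimates are excluded pairwise per method, never imputed.

A useful exact identity: cov(Ŷ − Y, (Ŷ + Y)/2) = (var Ŷ − var Y)/2, so the
sign of the proportional bias equals the sign of var(estimated) −
var(measured). A range-compressing estimator against a gold standard
therefore shows a negative trend — the signature the combined estimator is
designed to remove. Note that TE ≥ SEE is *not* an algebraic identity
(TE² − SEE² = CE² + s_d²·(ρ̂² − 1/n), with ρ̂ the sample correlation of the
differences with the estimates); it holds robustly for miscalibrated
estimators at study scale (n ≳ 60) and is tested there, but can fail by
chance for tiny, perfectly calibrated cohorts.

## Synthetic cohort generator

The generator emulates a 128-subject cohort (60 women, 68 men; fixed
stratum counts rather than Bernoulli draws) with sex-stratified marginals:
age 48.3 ± 7.0/6.9 years (F/M), BMI 21.6 ± 3.2 / 24.6 ± 2.9 kg·m⁻², PA
score 8.6 ± 7.5 / 11.9 ± 7.9 points truncated to [0, 44], and true fitness
F ~ 34.4 ± 5.0 / 41.2 ± 6.3 mL·kg⁻¹·min⁻¹. Because the [0, 44] floor sits
at z ≈ −1.15 for the female PA distribution, feeding the targets to the
parent normal would inflate the realized mean by about one point; the
parent (μ, σ) is therefore calibrated with exact truncated-normal moment
formulas so the *post-truncation* moments equal the targets, and values are
drawn by rejection (capped at 1000 rounds). Predictors are independent by
default — only marginals are published for the emulated population — with a
correlation-matrix hook for stress tests.

Step-test HRs are built on the extrapolation estimator's own premise: per
subject, the six stage HRs lie on the line through (resting VO2 constant,
resting HR ~ N(70, 8)) and (F, true maximal HR), plus independent
N(0, 3 bpm) per-stage noise. True maximal HR is Tanaka(age) + N(0, σ_mhr),
σ_mhr = 10 bpm, encoding the documented unreliability of age-predicted
maximal HR; it is the knob that degrades the extrapolation estimator, which
aims at the age-predicted (not true) maximum. Measured VO2max is
F + b0 + b1·(F − population mean) + N(0, σ_e) with defaults (0, 0, 4.2),
the residual scale reported for regression estimators of this kind.
Consequences by construction: with all noise at zero the LEM inverts the
generator exactly; the HR index is strongly negatively associated with F
(Spearman ρ ≈ −0.7); same config + seed reproduces cohorts bit-for-bit.

`inject_mrm_residual_structure` builds measured values around a given
estimate vector with a known fixed offset, proportional term, and noise;
it exists to verify that the agreement statistics recover injected
structure (offset recovered exactly up to per-element rounding;
proportional-bias sign given by the variance identity above).

### What the generator does and does not emulate

It reproduces published *marginal* moments and the linear HR–VO2 premise,
not the joint distribution of a real population, real HR kinetics
(on-transients, recovery curvature), or questionnaire measurement error.
One structural consequence matters for interpretation: anchoring each HR
line at (rest VO2, ~70 bpm) and an approximately Tanaka-level maximum
implies HR-index values around 62/55 bpm (F/M) — substantially higher than
the 46.9/35.4 observed in the population the regression coefficients came
from, whose step-test HR lines evidently do not extrapolate through the
age-predicted maximum. The fixed-coefficient MRM applied to these
synthetic cohorts is therefore biased low (CE ≈ +3.5) and noisier relative
to the LEM than it is on real data, and almost no synthetic subject
crosses the 45.0 cutoff (≈ 1%, versus 11/128 in the validation study). As
a result, simulations on generator defaults demonstrate correctness of the
machinery (identities, oracle equivalence, calibration, bias recovery) but
do *not* reproduce the real-data method ordering (SEE: combined < MRM <
LEM) or the combined method's bias removal; the corresponding study-shape
test documents this limitation by failing under defaults. Reproducing that
ordering in simulation would require an HR model whose index matches the
development population's scale — a deliberate non-goal, since it would
abandon the generator's noise-free invertibility contract.

## Problem sizes used in tests

Oracle-equivalence checks run 1,000 randomized records against exact
rational normal equations; agreement identities run on 500 seeded cohorts
of n ∈ [64, 160]; bias-recovery power and type-I-error checks use 200
replicates at n = 128; generator calibration uses n = 2000 (3-standard-
error moment bands); the study-shape check uses 100 replicates at n = 128.
The acceptance script regenerates a default 128-subject cohort from the
given seed and reports each method's agreement statistics at full
precision.

## Known limitations

* The PA questionnaire's item-level scoring is out of scope; the total
  score is an input.
* The regression coefficients and stage VO2 constants are taken as given;
  re-fitting them is a non-goal.
* Confidence intervals for the limits of agreement are not computed.
* Plotting is not part of the package surface.
* All simulation-based claims are claims about the generator, not about
  any real cohort (see above).
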