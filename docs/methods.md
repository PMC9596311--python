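# Methods

## Risk model

Both variants of the Framingham general-CVD risk profile are sex-specific
Cox-type equations: `risk = 1 − S₀(10)^exp(LP − m̄)` with log-transformed
continuous predictors and 0/1 indicators in the linear predictor LP.  The
office-based (non-laboratory) variant uses ln(age), ln(SBP) — with a
separate weight when the person reports antihypertensive treatment —
current smoking, diabetes and ln(BMI); the laboratory variant replaces
ln(BMI) with ln(total cholesterol) + ln(HDL).  The numeric constants
(term weights, S₀, mean linear predictor m̄) are transcribed from the
published risk-score tables into `src/heartage/data/framingham.yaml`; they
are data, not code, and a checksum test plus a frozen worked-example
regression test (61-year-old female smoker, TC 180 / HDL 47 / SBP 124
untreated → 10-year risk 0.1048) lock the transcription.  Risk is carried
as a fraction in (0,1) throughout; no upper cap is applied (some published
calculators cap display at 30%, but the thresholded logic used here is
unaffected).  Age enters as supplied, without rounding, and the calculator
input windows (SBP 90–200 mmHg, BMI 15–50 kg/m²) are applied by clamping
with a recorded flag.

## Heart-age inversion

Predicted heart age is defined by risk equivalence against the ideal
reference profile: SBP 125 mmHg untreated, BMI 22.5 kg/m², non-smoker,
non-diabetic.  Matching risks is equivalent to matching linear predictors,
giving the closed form `a* = exp((LP − C_ideal)/β_ln_age)`.  Two exact
properties follow and are enforced in tests: an ideal-profile subject's
heart age equals their chronological age, and evaluating risk at
(a*, ideal factors) reproduces the subject's risk; the closed form is also
cross-checked against an independent bisection root-finder.  For the
laboratory variant the ideal lipids are TC 180 mg/dl and HDL 45 mg/dl (the
risk-score publication's "normal" values); the primary analysis uses the
non-laboratory variant throughout.

Continuous heart age is rounded to whole years, half away from zero, and
*then* censored to the sentinels "<30" and ">80" (so 29.6 → 30, not
"<30"); the upstream calculator's rounding convention is not published, so
this convention is fixed here and the alternative is a one-line change.
Exact replication of third-party tool output may therefore differ by one
year exactly at .5 boundaries.  The PHA − age gap is classified low/equal/
high (1–4)/very high (≥5); sentinels classify by bound (for study ages
30–74, ">80" implies a gap ≥ 7 → very high, "<30" a gap ≤ −1 → low) rather
than by imputing 29 or 81, so no numeric PHA is invented for values the
calculator refuses to emit.  The gap is deliberately never reported as a
continuous outcome; where a numeric gap is needed for threshold membership
(eligibility among people with excess ≥ 5/10/20 years), sentinels take
their sharp bound 81 − age (or 29 − age).

## Cleaning

The analysis population is non-pregnant adults aged 30–74 without
self-reported CVD history, complete-case on all analysis variables.
Implausible measurements are dropped first using inclusive ranges: SBP
70–270, DBP 30–150 mmHg, height 1.00–2.50 m, weight 12–300 kg, derived
BMI 10–80 kg/m², waist 30–200 cm, FPG 45–540, total cholesterol 67–773
mg/dl.  Blood pressure is the mean of the 2nd and 3rd of three recorded
measurements; the DBP rule mirrors the stated SBP rule.  Plausibility is
evaluated on the averaged BP, and derived BMI is range-checked (10–80)
before the calculator clamp (15–50) — two distinct windows with different
roles.  Each dropped record is tagged with the *first* failing rule in a
fixed order (age window → pregnancy → CVD → the eight ranges in the order
above → missingness), making the drop ledger deterministic and count-
conserving; the exact step order of the original flowchart is not public,
so this order is a documented convention of the package.  Missing
education/marital/work codes exclude records from the regressions only,
not from PHA estimation — the least destructive reading of global
complete-case language, and configurable by dropping those rows upstream.

Derived definitions: diabetes = FPG ≥ 126 mg/dl or self-reported
diagnosis; high cholesterol = TC ≥ 200 mg/dl; abdominal obesity = waist
≥ 102 cm (men) / ≥ 88 cm (women); education collapsed 7 → 4 levels,
marital 6 → 3, work 9 → 5.

## Eligibility rules

Antihypertensive treatment: risk 10–19% with BP ≥ 140/90; or risk ≥ 20%
with BP ≥ 130/80; or BP ≥ 160/100 regardless of risk.  Lipid-lowering:
risk ≥ 20%, or age ≥ 40 with diabetes.  The "10–19%" band is implemented
as [0.10, 0.20) so the bands partition [0.10, ∞); risk enters as an exact
fraction (the guideline's integer phrasing leaves e.g. 19.5% ambiguous —
rounding to whole percent before thresholding is *not* done).  Rules are
evaluated in the listed priority order and the triggering rule is
reported.

## Survey estimation

Weighted proportions use the ratio estimator with stratified between-PSU
Taylor linearization; domains zero out linearized values rather than
subsetting the design.  Strata with a single PSU contribute deviations
from the grand mean of PSU totals (a standard "lonely PSU" centering
rule; the original analysis names its survey machinery but not its
lonely-PSU handling).  CIs are normal-approximation on the proportion
scale, truncated to [0,1].  On a self-weighting design the linearized SE
agrees with the binomial SRS formula to the n/(n−1) factor, verified
within 1%.  Risk quintiles are computed per country on the weighted risk
distribution (inverse-CDF definition; boundary ties fall to the lower
quintile, so fully tied values land in Q1).  The chronological-band ×
PHA-band flow table is unweighted, as the divergence description does not
use the design.  One-way ANOVA on country-level prevalences uses the
classic between/within decomposition; groups with fewer than two
countries are excluded with a warning.

## Mixed-effects models

Excess PHA (and, among records with excess PHA, each treatment
eligibility) is modelled by logistic regression with Gaussian random
intercepts for world region and country-in-region.  Survey weights are
deliberately not used — the design parameters are not consistently
available in the emulated setting, and the fitter takes no weights by
construction.  Estimation is Laplace-approximate ML (the approximation
glmer uses at nAGQ=1): penalized IRLS for the joint (β, b) mode, the
profiled Laplace criterion optimized over the two log-SDs by L-BFGS-B
(log-SD bounded in [−7, 2]); standard errors are Wald, from the
fixed-effect block of the inverse joint penalized Hessian, so p values
are Wald z tests (the original analysis does not state its test).  No
Python package in the dependency stack provides a frequentist GLMM with
this structure, so the fitter is implemented here and held to two
contracts verified in tests: collapse (one region, one country → matches
ordinary logistic regression within 1e-3 log-odds; ordinary logistic via
statsmodels serves as the independent oracle) and calibration/recovery
(null-simulation CI coverage of OR = 1 near 95% for every term, a known
log-odds 0.7 smoking effect recovered within its CI, and shrinking error
with sample size).  Diabetes is excluded from the lipid-lowering model
because adults ≥ 40 with diabetes are eligible by definition.
Coefficients with |log-odds| > 10 or SE > 50 are flagged as probable
complete separation rather than silently reported.  Reference levels:
education none, normal waist, normal cholesterol, single, unemployed,
non-smoker, no diabetes.

## Synthetic data

The generator emulates the *structure* of STEPS-like microdata, not any
real country's joint distribution.  A single latent metabolic factor
M ~ N(0,1) loads positively on SBP, BMI, waist, total cholesterol and the
diabetes liability and negatively on HDL, so cardiometabolic traits
co-occur the way the regressions assume; a full copula is deliberately
avoided because only marginals are published.  Binary traits use
Gaussian-copula thresholds, which keeps every marginal prevalence exactly
at its parameter; diabetes is constructed so the derived definition
(FPG ≥ 126 or self-report) recovers the true state exactly.  Country
presets carry the published per-survey means/prevalences (mean age, %
men, mean SBP, mean BMI, smoking, diabetes) for 14 countries across all
six regions; dispersions are not published and default to plausible
values (age SD 11 y, SBP SD 18 mmHg, BMI SD 4.5 kg/m², TC 185 ± 38
mg/dl), clearly non-published inputs.  Income labels are approximate
static World Bank bands.  Design geometry: 8 strata × 6 PSUs with a small
PSU-level SBP shift (SD 2 mmHg) to create a design effect, and
per-record lognormal weights (σ = 0.4; σ = 0 gives a self-weighting
design in which weighted and unweighted estimates coincide exactly).

Error injection draws replacements uniformly from documented out-of-range
bands; both the 2nd and 3rd BP readings are replaced together so the
measurement mean lands out of range, and BMI corruption rewrites weight
so that derived BMI is implausible while height and weight stay
individually plausible.  Every corruption is ledgered.  Seeds: country
substreams derive from `SeedSequence([master, crc32(country)])`, so
pooled generation never perturbs a country's records.

What passing tests on this generator do *not* show: recovery of any real
country's printed estimates (those require the restricted microdata),
realism of higher-order moments or of age–trait interactions (traits are
independent of age given M), or behaviour under informative missingness
(injected missingness is completely at random).

## Problem sizes and numerics

Test and acceptance-script sizes are chosen to make Monte-Carlo bounds
meaningful while keeping runs desk-scale: inversion checks use 1,000
random profiles per sex at tolerances 1e-9 (risk round-trip) and 1e-6
years (vs bisection); generator recovery uses one 50,000-record country
with 3-SE bounds; GLMM null calibration uses 100 replicates of 30
countries × 400 records (coverage asserted ≥ 0.87 per term, mean in
[0.92, 0.99]); the paired-t type-I check uses 500 replicates of 200
pairs; the pipeline determinism check runs 2 countries × 200 records.
The acceptance script simulates six preset countries at 3,000 records
each.  Tie-breaks and degenerate inputs are fixed explicitly: IRLS
weights floored at 1e-10, identical paired differences reported as a
degenerate comparison with NaN t/p, all-tied risks in Q1, empty
eligibility denominators flagged rather than dropped.

## Known limitations

The equation is not recalibrated to non-source populations (a stated
caveat of the original application as well); the 2019 WHO charts have no
published heart-age inversion and are out of scope.  The Laplace
approximation can understate variance components for few clusters with
small cluster sizes; with ≤ 6 regions the region-level variance is only
weakly identified (the same would hold in any GLMM fitted to such data).
Wald CIs on proportions near 0 or 1 are truncated rather than replaced by
logit-scale intervals.
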