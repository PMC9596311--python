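# heartage

Predicted heart age (PHA) analysis for population risk-factor surveys:
Framingham 10-year general-CVD risk scoring, inversion to a heart age,
STEPS-style data cleaning, WHO HEARTS treatment-eligibility rules,
design-based prevalence estimation, mixed-effects correlate models, and a
synthetic multi-country survey generator with known ground truth.

## Who this is for

Epidemiologists and biostatisticians who want to characterise predicted
heart age — a risk-communication device that restates a person's absolute
cardiovascular risk as "the age of someone with the same risk but ideal
risk factors" — in national survey data with complex sampling designs
(stratum / PSU / weight), and to ask what fraction of people with an aged
heart would actually qualify for preventive medication under risk-based
guidelines.

## The model

For sex *s*, the 10-year risk of a general CVD event is a Cox-type
equation

&nbsp;&nbsp;&nbsp;&nbsp;risk = 1 − S₀(10)^exp(LP − m̄)

where the linear predictor of the office-based (non-laboratory) variant is

&nbsp;&nbsp;&nbsp;&nbsp;LP = β₁·ln(age) + β₂·ln(SBP) + β₃·smoker + β₄·diabetes + β₅·ln(BMI),

with a separate SBP weight for people on antihypertensive treatment, S₀
the sex-specific baseline 10-year survival and m̄ the cohort mean of LP.
The laboratory variant replaces ln(BMI) by ln(total cholesterol) and
ln(HDL).  The calculator accepts SBP in 90–200 mmHg and BMI in 15–50
kg/m²; inputs outside are clamped.

Predicted heart age is the age a* at which a person with **ideal** risk
factors (SBP 125 mmHg untreated, BMI 22.5 kg/m², non-smoker, non-diabetic)
has the same risk.  Because risk is monotone in LP this has the closed
form

&nbsp;&nbsp;&nbsp;&nbsp;a\* = exp((LP − C_ideal) / β₁),

with C_ideal the sum of non-age terms at the ideal profile.  PHA is
rounded to whole years and reported numerically only within 30–80; values
outside are censored to "<30" / ">80".  The PHA − age gap is classified
low (< 0), equal (0), high (1–4 years) or very high (≥ 5 years); high and
very high together are *excess* PHA.

On top of the per-person quantities the package implements the
population analysis: selection and plausibility cleaning of raw survey
rows, WHO HEARTS antihypertensive and lipid-lowering eligibility rules,
survey-weighted category prevalences with stratified between-PSU Taylor
linearization variances, risk-quintile stratification, region/income
one-way ANOVA, paired lab-vs-non-lab sensitivity comparison, and
mixed-effects logistic models (random intercepts for country nested in
region, Laplace approximation) for correlates of excess PHA and of
treatment eligibility.

## Worked example

```python
import heartage as ha

coeffs = ha.load_coefficients()
p = ha.RiskProfile(sex="male", age=45, sbp=150, on_bp_treatment=False,
                   smoker=True, diabetes=False, bmi=31.0)
p = ha.clamp_calculator_inputs(p)
cell = coeffs[("non_lab", "male")]

res = ha.risk_10y(p, cell)
pha = ha.heart_age(p, cell)
coded = ha.censor_code(pha)
print(res.risk_10y)                      # 0.20764886981080088
print(pha, coded)                        # 68.36448062684447 68
print(ha.classify_gap(45, coded))        # very_high
print(ha.eligibility(res.risk_10y, p.sbp, 85.0, 45, False))
# EligibilityResult(antihypertensive=True, antihypertensive_rule='risk20_bp130',
#                   lipid_lowering=True, lipid_lowering_rule='risk20')
```

A 45-year-old male smoker with SBP 150 and BMI 31 carries a 20.8% ten-year
CVD risk — the risk of a 68-year-old with ideal risk factors, i.e. a heart
23 years older than he is — and his risk ≥ 20% makes him eligible for both
antihypertensive and lipid-lowering treatment under the WHO HEARTS rules.

The same computations run vectorised over survey tables, and the whole
pipeline is one call (or `heartage run` on the command line):

```python
cfg = ha.RunConfig(out_dir="out", seed=1,
                   countries=["Mongolia", "Ethiopia"], n_records=2000)
manifest = ha.run_pipeline(cfg)
```

which emits the cleaned data, drop ledger, scored/classified records and
tidy CSV summary tables plus a manifest with config hash and per-stage row
counts.  The CLI exposes the stages individually: `heartage simulate`,
`clean`, `score`, `heartage`, `summarize`, `model`, `run`.

## Layout

| module | contents |
|---|---|
| `heartage.risk` | risk profiles, coefficient loading, clamping, linear predictor, 10-year risk, paired lab/non-lab comparison |
| `heartage.inversion` | heart-age closed form, censoring, gap classification, 5-year bands |
| `heartage.cleaning` | selection, plausibility filter, derivation, drop ledger and flow report |
| `heartage.eligibility` | WHO HEARTS antihypertensive / lipid-lowering rules |
| `heartage.survey` | weighted prevalence with linearized SEs, category/eligibility/quintile tables, ANOVA, flow table |
| `heartage.correlates` | Laplace GLMM for excess PHA and eligibility outcomes |
| `heartage.simulate` | synthetic STEPS-like generator, presets, error injection |
| `heartage.pipeline` / `heartage.cli` | orchestration, manifest, command line |

See `docs/methods.md` for the methodological details and design choices.
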