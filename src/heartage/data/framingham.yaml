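# Sex-specific Cox-model constants for the Framingham general cardiovascular
# disease risk profile (10-year horizon), office-based (non-laboratory, BMI)
# and laboratory (lipid) variants.
#
# Provenance: transcribed from the published general-CVD risk profile paper
# (D'Agostino et al., Circulation 2008;117:743-53, Table 2 and Table 4).
# These constants are third-party published values, kept as data rather than
# code; a checksum test locks the file and a worked-example regression test
# guards the transcription.
#
# Terms:
#   ln_age            coefficient on ln(age in years)
#   ln_sbp_untreated  coefficient on ln(SBP mmHg) when not on BP treatment
#   ln_sbp_treated    coefficient on ln(SBP mmHg) when on BP treatment
#   ln_bmi            coefficient on ln(BMI kg/m^2)          (non_lab only)
#   ln_total_chol     coefficient on ln(total cholesterol)   (lab only)
#   ln_hdl            coefficient on ln(HDL cholesterol)     (lab only)
#   smoker, diabetes  coefficients on 0/1 indicators
# baseline_survival_10y: S0(10); mean_linear_predictor: mean risk-factor sum.
# ideal_reference: the risk-factor profile that anchors heart-age inversion.

non_lab:
  female:
    weights:
      ln_age: 2.72107
      ln_sbp_untreated: 2.81291
      ln_sbp_treated: 2.88267
      ln_bmi: 0.51125
      smoker: 0.61868
      diabetes: 0.77763
    baseline_survival_10y: 0.94833
    mean_linear_predictor: 26.0145
  male:
    weights:
      ln_age: 3.11296
      ln_sbp_untreated: 1.85508
      ln_sbp_treated: 1.92672
      ln_bmi: 0.79277
      smoker: 0.70953
      diabetes: 0.53160
    baseline_survival_10y: 0.88431
    mean_linear_predictor: 23.9388

lab:
  female:
    weights:
      ln_age: 2.32888
      ln_sbp_untreated: 2.76157
      ln_sbp_treated: 2.82263
      ln_total_chol: 1.20904
      ln_hdl: -0.70833
      smoker: 0.52873
      diabetes: 0.69154
    baseline_survival_10y: 0.95012
    mean_linear_predictor: 26.1931
  male:
    weights:
      ln_age: 3.06117
      ln_sbp_untreated: 1.93303
      ln_sbp_treated: 1.99881
      ln_total_chol: 1.12370
      ln_hdl: -0.93263
      smoker: 0.65451
      diabetes: 0.57367
    baseline_survival_10y: 0.88936
    mean_linear_predictor: 23.9802

ideal_reference:
  sbp: 125.0
  bmi: 22.5
  total_chol: 180.0
  hdl: 45.0
  on_bp_treatment: false
  smoker: false
  diabetes: false
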