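"""Risk-engine unit and property tests."""

import hashlib
import importlib.resources
import math

import numpy as np
import pandas as pd
import pytest
import yaml
from scipy import stats

from heartage import (RiskProfile, clamp_calculator_inputs, compare_lab_nonlab,
                      linear_predictor, load_coefficients, risk_10y,
                      score_dataframe)
from heartage.risk import CoefficientError

from conftest import random_profiles


def test_clamping_bounds_and_flag():
    p = RiskProfile(sex="male", age=50, sbp=205, on_bp_treatment=False,
                    smoker=False, diabetes=False, bmi=12.8)
    c = clamp_calculator_inputs(p)
    assert c.sbp == 200 and c.bmi == 15 and c.clamped
    low = clamp_calculator_inputs(
        RiskProfile(sex="male", age=50, sbp=85, on_bp_treatment=False,
                    smoker=False, diabetes=False, bmi=55))
    assert low.sbp == 90 and low.bmi == 50 and low.clamped
    interior = clamp_calculator_inputs(
        RiskProfile(sex="female", age=40, sbp=125, on_bp_treatment=False,
                    smoker=False, diabetes=False, bmi=22.5))
    assert (interior.sbp, interior.bmi, interior.clamped) == (125, 22.5, False)
    # untouched fields stay put
    assert c.age == 50 and c.sex == "male"


def _oracle_lp(profile, cell):
    """Independent term-by-term evaluation straight from the data file."""
    w = cell["weights"]
    lp = w["ln_age"] * math.log(profile.age)
    key = "ln_sbp_treated" if profile.on_bp_treatment else "ln_sbp_untreated"
    lp += w[key] * math.log(profile.sbp)
    if "ln_bmi" in w and profile.bmi is not None:
        lp += w["ln_bmi"] * math.log(profile.bmi)
    if "ln_total_chol" in w and profile.total_cholesterol is not None:
        lp += w["ln_total_chol"] * math.log(profile.total_cholesterol)
        lp += w["ln_hdl"] * math.log(profile.hdl_cholesterol)
    lp += w["smoker"] * profile.smoker + w["diabetes"] * profile.diabetes
    return lp


@pytest.mark.parametrize("variant", ["non_lab", "lab"])
@pytest.mark.parametrize("sex", ["male", "female"])
def test_linear_predictor_matches_term_sum_oracle(coeffs, variant, sex):
    raw = yaml.safe_load(importlib.resources.files("heartage")
                         .joinpath("data/framingham.yaml").read_text())
    rng = np.random.default_rng(42)
    for p in random_profiles(rng, 1000, sex, variant):
        got = linear_predictor(p, coeffs[(variant, sex)])
        assert got == pytest.approx(_oracle_lp(p, raw[variant][sex]), abs=1e-10)


def test_treatment_toggle_shifts_lp_by_weight_difference(coeffs):
    c = coeffs[("non_lab", "female")]
    base = RiskProfile(sex="female", age=61, sbp=140, on_bp_treatment=False,
                       smoker=True, diabetes=False, bmi=28)
    treated = RiskProfile(sex="female", age=61, sbp=140, on_bp_treatment=True,
                          smoker=True, diabetes=False, bmi=28)
    expected = (c.weights["ln_sbp_treated"]
                - c.weights["ln_sbp_untreated"]) * math.log(140)
    assert linear_predictor(treated, c) - linear_predictor(base, c) \
        == pytest.approx(expected, abs=1e-12)


def test_risk_transform_identity_at_mean_lp(coeffs):
    from heartage import risk_from_linear_predictor
    for cell in coeffs.values():
        got = float(risk_from_linear_predictor(cell.mean_linear_predictor, cell))
        assert got == pytest.approx(1.0 - cell.baseline_survival_10y, abs=1e-14)


def test_published_worked_example_lab_female(coeffs):
    # 61-y woman, TC 180, HDL 47, SBP 124 untreated, smoker, non-diabetic:
    # the risk-score publication's worked example gives ~10.5%
    p = RiskProfile(sex="female", age=61, sbp=124, on_bp_treatment=False,
                    smoker=True, diabetes=False,
                    total_cholesterol=180, hdl_cholesterol=47)
    assert risk_10y(p, coeffs[("lab", "female")]).risk_10y \
        == pytest.approx(0.104842, abs=5e-5)


@pytest.mark.parametrize("sex", ["male", "female"])
def test_risk_monotone_in_each_continuous_input(coeffs, sex):
    c = coeffs[("non_lab", sex)]
    ages, sbps, bmis = [30, 45, 60, 74], [90, 120, 160, 200], [15, 25, 35, 50]
    def r(age, sbp, bmi, smoker=False, diabetes=False):
        return risk_10y(RiskProfile(sex=sex, age=age, sbp=sbp, bmi=bmi,
                                    on_bp_treatment=False, smoker=smoker,
                                    diabetes=diabetes), c).risk_10y
    for sbp in sbps:
        for bmi in bmis:
            vals = [r(a, sbp, bmi) for a in ages]
            assert all(x < y for x, y in zip(vals, vals[1:]))
    for age in ages:
        for bmi in bmis:
            vals = [r(age, s, bmi) for s in sbps]
            assert all(x < y for x, y in zip(vals, vals[1:]))
        for sbp in sbps:
            vals = [r(age, sbp, b) for b in bmis]
            assert all(x < y for x, y in zip(vals, vals[1:]))
            base = r(age, sbp, 25)
            assert r(age, sbp, 25, smoker=True) >= base
            assert r(age, sbp, 25, diabetes=True) >= base


@pytest.mark.parametrize("variant", ["non_lab", "lab"])
def test_risk_stays_inside_unit_interval(coeffs, variant):
    rng = np.random.default_rng(7)
    for sex in ("male", "female"):
        for p in random_profiles(rng, 300, sex, variant):
            r = risk_10y(p, coeffs[(variant, sex)]).risk_10y
            assert 0.0 < r < 1.0


def test_sex_variant_mismatch_rejected(coeffs):
    p = RiskProfile(sex="male", age=50, sbp=130, on_bp_treatment=False,
                    smoker=False, diabetes=False, bmi=25)
    with pytest.raises(ValueError, match="sex"):
        linear_predictor(p, coeffs[("non_lab", "female")])
    with pytest.raises(ValueError, match="lab variant"):
        linear_predictor(p, coeffs[("lab", "male")])


def test_score_dataframe_matches_scalar_path(coeffs):
    rng = np.random.default_rng(3)
    profiles = random_profiles(rng, 50, "male") + random_profiles(rng, 50, "female")
    df = pd.DataFrame({
        "sex": [p.sex for p in profiles],
        "age": [p.age for p in profiles],
        "sbp": [p.sbp for p in profiles],
        "bmi": [p.bmi for p in profiles],
        "on_bp_treatment": [p.on_bp_treatment for p in profiles],
        "smoker": [p.smoker for p in profiles],
        "diabetes": [p.diabetes for p in profiles],
    })
    out = score_dataframe(df, coeffs)
    for i, p in enumerate(profiles):
        assert out["risk_10y"].iat[i] == pytest.approx(
            risk_10y(p, coeffs[("non_lab", p.sex)]).risk_10y, abs=1e-12)


def test_coefficient_file_checksum_locked():
    blob = importlib.resources.files("heartage") \
        .joinpath("data/framingham.yaml").read_bytes()
    assert hashlib.sha256(blob).hexdigest() == \
        "b132133983239e3ef1dc6ee8dcbddb55e7bf3bbe9f67e62be4c4d67c2be4ec64"


def test_coefficient_schema_validation(tmp_path):
    bad = tmp_path / "bad.yaml"
    raw = yaml.safe_load(importlib.resources.files("heartage")
                         .joinpath("data/framingham.yaml").read_text())
    raw["non_lab"]["male"]["weights"]["ln_age"] = -1.0
    bad.write_text(yaml.safe_dump(raw))
    with pytest.raises(CoefficientError, match="ln_age"):
        load_coefficients(bad)


# --- paired lab vs non-lab machinery ---------------------------------------

def test_paired_test_identical_pairs_degenerate():
    res = compare_lab_nonlab([(x, x) for x in (1.0, 2.0, 3.0)])
    assert res.mean_difference == 0.0 and res.degenerate
    assert math.isnan(res.t_statistic) and math.isnan(res.p_value)


def test_paired_test_toy_pairs_match_hand_formula():
    pairs = [(1, 2), (2, 2), (3, 5), (4, 4), (5, 7)]
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    t_hand = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(len(diffs)))
    p_hand = 2 * stats.t.sf(abs(t_hand), df=len(diffs) - 1)
    res = compare_lab_nonlab(pairs)
    assert res.t_statistic == pytest.approx(t_hand, abs=1e-10)
    assert res.p_value == pytest.approx(p_hand, abs=1e-10)
    assert res.mean_difference == pytest.approx(-1.0, abs=1e-12)
    # cross-check against scipy's implementation as an independent oracle
    sp = stats.ttest_rel([a for a, _ in pairs], [b for _, b in pairs])
    assert res.t_statistic == pytest.approx(sp.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(sp.pvalue, abs=1e-10)


def test_paired_test_input_validation():
    with pytest.raises(ValueError):
        compare_lab_nonlab([(1.0, 2.0)])
    with pytest.raises(ValueError):
        compare_lab_nonlab([(1.0, np.inf), (2.0, 3.0)])
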