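"""Synthetic-data generator tests against its own ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from heartage import (GENERIC_LMIC, PRESETS, CountrySimParams, clean_dataframe,
                      inject_errors, preset, simulate_country,
                      simulate_multi_country, weighted_prevalence)


def test_same_seed_reproduces_byte_identical_output():
    p = preset("Mongolia", n_records=300)
    a, la = simulate_country(p, seed=5)
    b, lb = simulate_country(p, seed=5)
    assert a.to_csv(index=False) == b.to_csv(index=False)
    assert la.truth.to_csv(index=False) == lb.truth.to_csv(index=False)
    c, _ = simulate_country(p, seed=6)
    assert a.to_csv(index=False) != c.to_csv(index=False)


def test_country_substreams_are_independent():
    pa, pb = preset("Ethiopia", n_records=200), preset("Nauru", n_records=200)
    joint, _ = simulate_multi_country([pa, pb], seed=3)
    alone, _ = simulate_country(pa, seed=3)
    joint_a = joint[joint.country == "Ethiopia"].reset_index(drop=True)
    pd.testing.assert_frame_equal(joint_a, alone)
    # and order/composition of the list does not matter
    joint2, _ = simulate_multi_country([pb, pa], seed=3)
    joint2_a = (joint2[joint2.country == "Ethiopia"]
                .reset_index(drop=True).assign(row_id=lambda d: d.row_id - 200))
    pd.testing.assert_frame_equal(joint2_a, alone)


def test_multi_country_size_and_duplicate_check():
    params = [preset(c, n_records=50) for c in ("Ethiopia", "Jordan", "Nepal")]
    pooled, ledgers = simulate_multi_country(params, seed=1)
    assert len(pooled) == 150
    assert set(ledgers) == {"Ethiopia", "Jordan", "Nepal"}
    with pytest.raises(ValueError, match="duplicate"):
        simulate_multi_country([params[0], params[0]], seed=1)


def test_invalid_params_name_the_field():
    with pytest.raises(ValueError, match="p_smoker"):
        dataclasses.replace(GENERIC_LMIC, p_smoker=1.5).validate()
    with pytest.raises(ValueError, match="bmi_sd"):
        dataclasses.replace(GENERIC_LMIC, bmi_sd=0.0).validate()
    with pytest.raises(ValueError, match="error_rates"):
        dataclasses.replace(GENERIC_LMIC,
                            error_rates={"sbp": 2.0}).validate()


def test_presets_cover_all_regions():
    regions = {p.region for p in PRESETS.values()}
    assert len(regions) == 6
    for region in regions:  # >=2 countries per region so ANOVA never excludes
        assert sum(p.region == region for p in PRESETS.values()) >= 2


def test_binary_trait_prevalences_recovered():
    """Weighted prevalence of generated traits matches the nominal
    parameters within 3 design-based SEs (exact Gaussian-copula marginals)."""
    p = preset("Mongolia", n_records=20000)
    raw, ledger = simulate_country(p, seed=9)
    for col, target in (("current_smoker", p.p_smoker),
                        ("bp_treatment_2wk", p.p_bp_treatment)):
        y = (raw[col] == "yes").to_numpy(float)
        est = weighted_prevalence(y, raw["weight"], raw["psu"], raw["stratum"])
        assert abs(est.proportion - target) < 3 * est.standard_error
    dia = ledger.truth["diabetes_true"].to_numpy(float)
    est = weighted_prevalence(dia, raw["weight"], raw["psu"], raw["stratum"])
    assert abs(est.proportion - p.p_diabetes) < 3 * est.standard_error


def test_derived_diabetes_matches_generated_truth_exactly():
    raw, ledger = simulate_country(preset("Guyana", n_records=4000), seed=2)
    clean, _, _ = clean_dataframe(raw)
    truth = ledger.truth.set_index("row_id")["diabetes_true"]
    derived = clean.set_index("row_id")["diabetes"]
    assert (derived == truth.loc[derived.index]).all()


def test_mean_bmi_target_recovered():
    p = preset("Nauru", n_records=20000)
    raw, ledger = simulate_country(p, seed=4)
    w = raw["weight"].to_numpy()
    bmi = ledger.truth["bmi_true"].to_numpy()
    m = float((w * bmi).sum() / w.sum())
    se = np.sqrt(float((w ** 2 * (bmi - m) ** 2).sum()) / w.sum() ** 2)
    assert abs(m - 35.6) < 3 * se + 0.05  # small allowance for tail clipping


def test_zero_weight_dispersion_gives_self_weighting():
    p = dataclasses.replace(GENERIC_LMIC, n_records=3000, weight_dispersion=0.0)
    raw, _ = simulate_country(p, seed=7)
    assert (raw["weight"] == 1.0).all()
    y = (raw["current_smoker"] == "yes").to_numpy(float)
    est = weighted_prevalence(y, raw["weight"])
    assert est.proportion == pytest.approx(y.mean(), abs=1e-15)


# --- error injection ---------------------------------------------------------

def test_zero_rates_leave_records_untouched():
    raw, _ = simulate_country(preset("Nepal", n_records=200), seed=1)
    out, ledger = inject_errors(raw, {}, seed=0)
    pd.testing.assert_frame_equal(out, raw)
    assert len(ledger) == 0


def test_injected_sbp_rate_recovered_by_cleaning():
    p = preset("Nepal", n_records=10000, error_rates={"sbp": 0.05})
    raw, ledger = simulate_country(p, seed=13)
    _, drop_ledger, _ = clean_dataframe(raw)
    n_inj = ledger.corruption.query("column == 'sbp2'")["row_id"].nunique()
    n_drop = (drop_ledger["reason"] == "sbp_implausible").sum()
    assert abs(n_inj - 0.05 * 10000) < 3 * np.sqrt(10000 * 0.05 * 0.95)
    # corrupted rows may exit earlier (age window etc.) and a handful of
    # natural values sit near the plausibility boundary, so the sets need
    # not coincide exactly; the bulk must be recovered
    injected = set(ledger.corruption.query("column == 'sbp2'")["row_id"])
    dropped_sbp = set(drop_ledger.loc[drop_ledger.reason == "sbp_implausible",
                                      "row_id"])
    assert len(dropped_sbp & injected) >= 0.8 * n_inj
    assert n_drop <= n_inj + 0.01 * len(raw)


def test_every_corruption_is_ledgered_with_matching_reason():
    """Each corrupted variable maps to its cleaning drop reason."""
    rules = {"sbp": "sbp_implausible", "dbp": "dbp_implausible",
             "height": "height_implausible", "weight": "weight_implausible",
             "bmi": "bmi_implausible", "waist": "waist_implausible",
             "fpg": "fpg_implausible", "total_chol": "chol_implausible"}
    raw, _ = simulate_country(preset("Iraq", n_records=400), seed=8)
    for rule, reason in rules.items():
        corrupted, ledger = inject_errors(raw, {rule: 0.1}, seed=3)
        assert len(ledger) > 0
        _, drop_ledger, _ = clean_dataframe(corrupted)
        hit = set(ledger["row_id"])
        got = drop_ledger[drop_ledger["row_id"].isin(hit)]
        # every corrupted record present in the drop ledger carries the
        # matching reason unless an earlier rule fired first
        earlier = {"age", "pregnant", "cvd_history"}
        for _, row in got.iterrows():
            assert row["reason"] == reason or row["reason"] in earlier


def test_bmi_injection_keeps_height_weight_individually_plausible():
    raw, _ = simulate_country(preset("Belarus", n_records=500), seed=2)
    corrupted, ledger = inject_errors(raw, {"bmi": 0.2}, seed=5)
    assert (ledger["column"] == "weight_kg").all()
    hit = corrupted[corrupted["row_id"].isin(ledger["row_id"])]
    bmi = hit["weight_kg"] / hit["height_m"] ** 2
    assert ((bmi < 10) | (bmi > 80)).all()
    assert hit["weight_kg"].between(12, 300).all()
    assert hit["height_m"].between(1.0, 2.5).all()


def test_missingness_injection_blanks_cells():
    raw, _ = simulate_country(preset("Ecuador", n_records=2000), seed=3)
    corrupted, ledger = inject_errors(raw, {}, seed=1,
                                      missing_rates={"waist_cm": 0.1})
    n_missing = corrupted["waist_cm"].isna().sum()
    assert n_missing == len(ledger)
    assert abs(n_missing - 200) < 3 * np.sqrt(2000 * 0.1 * 0.9)
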