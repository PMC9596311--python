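import numpy as np
import pandas as pd
import pytest

from heartage import (load_coefficients, preset, simulate_multi_country,
                      clean_dataframe, score_dataframe, heartage_dataframe,
                      eligibility_dataframe, RiskProfile)


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients()


def random_profiles(rng, n, sex, variant="non_lab"):
    """Random profiles spanning the clamped calculator domain."""
    profiles = []
    for _ in range(n):
        kw = dict(
            sex=sex,
            age=float(rng.uniform(30, 74)),
            sbp=float(rng.uniform(90, 200)),
            on_bp_treatment=bool(rng.random() < 0.3),
            smoker=bool(rng.random() < 0.3),
            diabetes=bool(rng.random() < 0.2),
        )
        if variant == "non_lab":
            kw["bmi"] = float(rng.uniform(15, 50))
        else:
            kw["total_cholesterol"] = float(rng.uniform(100, 350))
            kw["hdl_cholesterol"] = float(rng.uniform(20, 100))
        profiles.append(RiskProfile(**kw))
    return profiles


def make_valid_raw(n=20, country="Testland", seed=0):
    """A raw survey frame in which every record passes cleaning."""
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    sbp = rng.uniform(100, 160, n)
    dbp = rng.uniform(60, 95, n)
    height = rng.uniform(1.5, 1.9, n)
    bmi = rng.uniform(18, 35, n)
    return pd.DataFrame({
        "row_id": np.arange(n), "country": country, "region": "Africa",
        "income": "low", "year": 2017,
        "psu": [f"p{i % 4}" for i in range(n)],
        "stratum": [f"s{i % 2}" for i in range(n)],
        "weight": rng.uniform(0.5, 2.0, n),
        "sex": sex, "age": rng.integers(30, 75, n),
        "sbp1": sbp + 2, "sbp2": sbp, "sbp3": sbp + 1,
        "dbp1": dbp + 2, "dbp2": dbp, "dbp3": dbp + 1,
        "height_m": height, "weight_kg": bmi * height ** 2,
        "waist_cm": rng.uniform(60, 110, n),
        "fpg": rng.uniform(70, 120, n),
        "total_chol": rng.uniform(120, 260, n),
        "hdl": rng.uniform(30, 70, n),
        "self_reported_diabetes": "no", "bp_treatment_2wk": "no",
        "current_smoker": np.where(rng.random(n) < 0.3, "yes", "no"),
        "pregnant": "no", "cvd_history": "no",
        "education_raw": rng.integers(1, 8, n),
        "marital_raw": rng.integers(1, 7, n),
        "work_raw": rng.integers(1, 10, n),
    })


@pytest.fixture(scope="session")
def analysis_frame(coeffs):
    """Cleaned, scored, classified two-country frame for summary tests."""
    params = [preset("Mongolia", n_records=600),
              preset("Ethiopia", n_records=600)]
    raw, _ = simulate_multi_country(params, seed=11)
    clean, _, _ = clean_dataframe(raw)
    df = score_dataframe(clean, coeffs)
    df = heartage_dataframe(df, coeffs)
    return eligibility_dataframe(df)
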