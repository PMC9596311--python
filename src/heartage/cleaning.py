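"""STEPS-style population selection, plausibility filtering and derivation.

The analysis population is non-pregnant adults aged 30-74 years without
self-reported CVD history, complete-case on every variable the risk score
and the descriptive analyses need.  Records with biologically implausible
measurements are dropped before any derivation: SBP outside 70-270 mmHg,
DBP outside 30-150 mmHg, height outside 1.00-2.50 m, weight outside 12-300
kg, derived BMI outside 10-80 kg/m^2, waist outside 30-200 cm, fasting
plasma glucose outside 45-540 mg/dl and total cholesterol outside 67-773
mg/dl.  Blood pressure uses the mean of the second and third of the three
recorded measurements (the first is discarded); DBP mirrors the SBP rule.

Every dropped record is tagged with the *first* failing rule in a fixed,
documented order (age window, pregnancy, CVD history, the eight
plausibility ranges, then missingness), so the drop ledger is
deterministic and conserves counts: kept + dropped == initial, per country.

Missing education/marital/work codes do **not** drop a record here — those
covariates are only needed by the correlate regressions, which subset to
complete covariate rows themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: inclusive plausibility ranges, in the order rules are evaluated
PLAUSIBILITY_RANGES: dict[str, tuple[float, float]] = {
    "sbp": (70.0, 270.0),        # mmHg, mean of measurements 2 and 3
    "dbp": (30.0, 150.0),        # mmHg, mean of measurements 2 and 3
    "height": (1.00, 2.50),      # m
    "weight": (12.0, 300.0),     # kg
    "bmi": (10.0, 80.0),         # kg/m^2, derived
    "waist": (30.0, 200.0),      # cm
    "fpg": (45.0, 540.0),        # mg/dl
    "total_chol": (67.0, 773.0), # mg/dl
}

AGE_RANGE = (30, 74)

#: complete-case fields checked (in order) at the missingness step
_REQUIRED_FIELDS = (
    "sex", "sbp2", "sbp3", "dbp2", "dbp3", "height_m", "weight_kg",
    "waist_cm", "fpg", "total_chol", "current_smoker", "bp_treatment_2wk",
    "self_reported_diabetes", "cvd_history", "pregnant",
    "psu", "stratum", "weight",
)

_EDUCATION4 = {1: "none", 2: "primary", 3: "primary",
               4: "secondary_high", 5: "secondary_high",
               6: "university", 7: "university"}
_MARITAL3 = {1: "single", 2: "married_cohab", 6: "married_cohab",
             3: "div_sep_wid", 4: "div_sep_wid", 5: "div_sep_wid"}
_WORK5 = {1: "employed_paid", 2: "employed_paid", 3: "employed_paid",
          4: "employed_unpaid", 5: "student", 6: "homemaker",
          7: "unemployed", 8: "unemployed", 9: "unemployed"}

#: reporting order of the cleaning steps
STEPS = ("initial", "age_window", "non_pregnant", "no_cvd",
         "plausible", "complete_case")


@dataclass
class CleaningOutput:
    clean: pd.DataFrame
    drop_ledger: pd.DataFrame  # row_id, country, reason
    report: pd.DataFrame       # per-country counts after each step

    def __iter__(self):  # allow tuple unpacking
        return iter((self.clean, self.drop_ledger, self.report))


def _as_bool(s: pd.Series) -> pd.Series:
    """Parse yes/no (or 0/1, bool) survey answers to a nullable boolean."""
    mapping = {"yes": True, "no": False, "y": True, "n": False,
               1: True, 0: False, 1.0: True, 0.0: False,
               True: True, False: False}
    def conv(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, str):
            v = v.strip().lower()
        return mapping.get(v, pd.NA)
    return s.map(conv).astype("boolean")


def _mean23(df: pd.DataFrame, stem: str) -> pd.Series:
    """Mean of the 2nd and 3rd measurement; NaN unless both are present."""
    a = pd.to_numeric(df[f"{stem}2"], errors="coerce")
    b = pd.to_numeric(df[f"{stem}3"], errors="coerce")
    return (a + b) / 2.0


def clean_dataframe(raw: pd.DataFrame,
                    ranges: dict[str, tuple[float, float]] | None = None,
                    column_map: dict[str, str] | None = None) -> CleaningOutput:
    """Apply selection, plausibility and derivation to a raw survey table.

    ``column_map`` renames survey-dialect columns to the canonical names
    first.  ``ranges`` overrides :data:`PLAUSIBILITY_RANGES` (they are data,
    not code).  Returns the cleaned analysis table, a per-record drop
    ledger and the per-country flow report.
    """
    ranges = dict(PLAUSIBILITY_RANGES, **(ranges or {}))
    df = raw.rename(columns=column_map or {}).copy()
    if "row_id" not in df.columns:
        df["row_id"] = np.arange(len(df))
    if "country" not in df.columns:
        df["country"] = "ALL"

    n = len(df)
    age = pd.to_numeric(df.get("age"), errors="coerce")
    sex = df.get("sex")
    sex = sex.where(sex.isin(["male", "female"]), pd.NA) if sex is not None \
        else pd.Series(pd.NA, index=df.index)
    pregnant = _as_bool(df["pregnant"]) if "pregnant" in df else \
        pd.Series(pd.NA, index=df.index, dtype="boolean")
    # men are never pregnant, whatever the (unasked) field holds
    pregnant = pregnant.mask(sex == "male", False)
    cvd = _as_bool(df["cvd_history"]) if "cvd_history" in df else \
        pd.Series(pd.NA, index=df.index, dtype="boolean")

    sbp = _mean23(df, "sbp")
    dbp = _mean23(df, "dbp")
    height = pd.to_numeric(df.get("height_m"), errors="coerce")
    weight_kg = pd.to_numeric(df.get("weight_kg"), errors="coerce")
    bmi = weight_kg / height ** 2
    waist = pd.to_numeric(df.get("waist_cm"), errors="coerce")
    fpg = pd.to_numeric(df.get("fpg"), errors="coerce")
    tc = pd.to_numeric(df.get("total_chol"), errors="coerce")

    def outside(s: pd.Series, key: str) -> np.ndarray:
        lo, hi = ranges[key]
        return (s.notna() & ((s < lo) | (s > hi))).to_numpy()

    # rules in documented priority order; the first that fires is the reason
    rules: list[tuple[str, np.ndarray]] = [
        ("age", (age.isna() | (age < AGE_RANGE[0]) | (age > AGE_RANGE[1])).to_numpy()),
        ("pregnant", pregnant.fillna(False).to_numpy(dtype=bool)),
        ("cvd_history", cvd.fillna(False).to_numpy(dtype=bool)),
        ("sbp_implausible", outside(sbp, "sbp")),
        ("dbp_implausible", outside(dbp, "dbp")),
        ("height_implausible", outside(height, "height")),
        ("weight_implausible", outside(weight_kg, "weight")),
        # BMI judged only when height and weight are individually plausible
        ("bmi_implausible", outside(bmi, "bmi")
         & ~outside(height, "height") & ~outside(weight_kg, "weight")),
        ("waist_implausible", outside(waist, "waist")),
        ("fpg_implausible", outside(fpg, "fpg")),
        ("chol_implausible", outside(tc, "total_chol")),
    ]
    values = {"sex": sex, "sbp2": df.get("sbp2"), "sbp3": df.get("sbp3"),
              "dbp2": df.get("dbp2"), "dbp3": df.get("dbp3"),
              "height_m": height, "weight_kg": weight_kg, "waist_cm": waist,
              "fpg": fpg, "total_chol": tc,
              "current_smoker": _as_bool(df["current_smoker"]) if "current_smoker" in df else None,
              "bp_treatment_2wk": _as_bool(df["bp_treatment_2wk"]) if "bp_treatment_2wk" in df else None,
              "self_reported_diabetes": _as_bool(df["self_reported_diabetes"]) if "self_reported_diabetes" in df else None,
              "cvd_history": cvd,
              "pregnant": pregnant,
              "psu": df.get("psu"), "stratum": df.get("stratum"),
              "weight": pd.to_numeric(df.get("weight"), errors="coerce")}
    for name in _REQUIRED_FIELDS:
        col = values.get(name)
        miss = np.ones(n, dtype=bool) if col is None else col.isna().to_numpy()
        rules.append((f"missing_{name}", miss))

    reason = np.full(n, "", dtype=object)
    for name, mask in rules:
        fire = mask & (reason == "")
        reason[fire] = name

    kept = reason == ""
    ledger = pd.DataFrame({"row_id": df["row_id"].to_numpy()[~kept],
                           "country": df["country"].to_numpy()[~kept],
                           "reason": reason[~kept]})

    clean = pd.DataFrame({
        "row_id": df["row_id"], "country": df["country"],
        "region": df.get("region"), "income": df.get("income"),
        "year": df.get("year"),
        "psu": df.get("psu"), "stratum": df.get("stratum"),
        "weight": values["weight"],
        "sex": sex, "age": age,
        "sbp": sbp, "dbp": dbp, "bmi": bmi,
        "height_m": height, "weight_kg": weight_kg, "waist_cm": waist,
        "fpg": fpg, "total_chol": tc,
        "hdl": pd.to_numeric(df.get("hdl"), errors="coerce"),
        "on_bp_treatment": values["bp_treatment_2wk"],
        "smoker": values["current_smoker"],
        "self_reported_diabetes": values["self_reported_diabetes"],
    })[kept].copy()
    clean["age"] = clean["age"].astype(int)
    for c in ("on_bp_treatment", "smoker", "self_reported_diabetes"):
        clean[c] = clean[c].astype(bool)
    clean["diabetes"] = (clean["fpg"] >= 126.0) | clean["self_reported_diabetes"]
    clean["high_cholesterol"] = clean["total_chol"] >= 200.0
    thr = np.where(clean["sex"] == "male", 102.0, 88.0)
    clean["abdominal_obesity"] = clean["waist_cm"].to_numpy() >= thr
    for raw_col, out_col, mapping in (("education_raw", "education4", _EDUCATION4),
                                      ("marital_raw", "marital3", _MARITAL3),
                                      ("work_raw", "work5", _WORK5)):
        if raw_col in df.columns:
            src = pd.to_numeric(df[raw_col], errors="coerce")[kept]
            clean[out_col] = src.map(mapping)
        else:
            clean[out_col] = pd.NA

    report = cleaning_report(df, ledger)
    return CleaningOutput(clean.reset_index(drop=True), ledger.reset_index(drop=True),
                          report)


def cleaning_report(raw: pd.DataFrame, drop_ledger: pd.DataFrame) -> pd.DataFrame:
    """Per-country record counts after each sequential cleaning step.

    Columns follow :data:`STEPS`; ``complete_case`` is the kept count.
    Totals are conserved: for every country,
    ``initial == complete_case + total drops``.
    """
    step_of = {"age": "age_window", "pregnant": "non_pregnant",
               "cvd_history": "no_cvd"}
    def step_for(reason: str) -> str:
        if reason in step_of:
            return step_of[reason]
        return "complete_case" if reason.startswith("missing_") else "plausible"

    countries = (raw["country"] if "country" in raw.columns
                 else pd.Series("ALL", index=raw.index))
    init = countries.value_counts()
    rows = []
    for country in sorted(init.index.astype(str)):
        sub = drop_ledger[drop_ledger["country"].astype(str) == country]
        drops = {s: 0 for s in STEPS[1:]}
        for r in sub["reason"]:
            drops[step_for(r)] += 1
        n = int(init[country])
        row = {"country": country, "initial": n}
        for s in STEPS[1:]:
            n -= drops[s]
            row[s] = n
        rows.append(row)
    cols = ["country"] + list(STEPS)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
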