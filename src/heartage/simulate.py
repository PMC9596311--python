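"""STEPS-like synthetic survey microdata with known ground truth.

The generator emulates the structure of national NCD risk-factor surveys:
one row per participant with three blood-pressure readings, anthropometry,
fasting glucose, cholesterol, questionnaire items (smoking, treatment,
self-reported diabetes, pregnancy, CVD history, education/marital/work
codes) and complex-design variables (stratum, PSU, sampling weight).  Every
stage of the analysis pipeline can then be tested against the generating
truth instead of restricted microdata.

Correlation structure: one shared latent "metabolic" factor M ~ N(0,1) per
person loads positively on SBP, BMI, waist, cholesterol and the diabetes
liability (and negatively on HDL), so adiposity, dyslipidaemia and
dysglycaemia co-occur.  Binary traits use Gaussian-copula thresholds, which
keeps every marginal prevalence exactly at its parameter value.  Diabetes
is constructed so the derived definition (FPG >= 126 mg/dl or self-report)
recovers the true diabetic state exactly: non-diabetics draw FPG below 126
and answer no; diagnosed diabetics answer yes; undiagnosed diabetics draw
FPG above 126.

Country presets carry the published per-survey risk-factor summaries
(mean age, % men, mean SBP, mean BMI, smoking and diabetes prevalence);
dispersions are not published and default to plausible values.  Income
labels are static approximate World Bank bands.  Error injection replaces
values with draws from documented out-of-range bands (both BP readings 2
and 3 together, so the 2nd/3rd-measurement mean lands out of range), and
missingness blanks individual raw columns; both are ledgered per record.

Seed policy: records for country c under master seed s are drawn from
``SeedSequence([s, crc32(c)])``, so adding or reordering countries never
perturbs another country's records.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: out-of-range bands used by error injection, keyed by plausibility rule
OUT_OF_RANGE_BANDS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "sbp": ((40.0, 69.0), (271.0, 330.0)),
    "dbp": ((10.0, 29.0), (151.0, 200.0)),
    "height": ((0.30, 0.99), (2.51, 3.00)),
    "weight": ((2.0, 11.5), (301.0, 400.0)),
    "waist": ((5.0, 29.0), (201.0, 260.0)),
    "fpg": ((10.0, 44.0), (541.0, 700.0)),
    "total_chol": ((20.0, 66.0), (774.0, 900.0)),
    "age": ((18.0, 29.0), (75.0, 90.0)),
}

_RAW_COLUMNS_OF = {
    "sbp": ("sbp2", "sbp3"), "dbp": ("dbp2", "dbp3"),
    "height": ("height_m",), "weight": ("weight_kg",),
    "waist": ("waist_cm",), "fpg": ("fpg",), "total_chol": ("total_chol",),
    "age": ("age",),
}


def _default_education():
    return (0.15, 0.20, 0.20, 0.15, 0.10, 0.15, 0.05)


def _default_marital():
    return (0.15, 0.55, 0.04, 0.04, 0.10, 0.12)


def _default_work():
    return (0.12, 0.18, 0.25, 0.03, 0.02, 0.20, 0.08, 0.08, 0.04)


@dataclass(frozen=True)
class CountrySimParams:
    """Generator parameters for one synthetic country.

    Marginal locations for age/SBP/BMI and the smoking/diabetes prevalences
    default to the published per-survey summaries when a preset is used;
    scale parameters and loadings are unpublished and default to plausible
    dispersions.  ``error_rates``/``missing_rates`` are per-variable
    corruption probabilities (keys of :data:`OUT_OF_RANGE_BANDS` and raw
    column names respectively).
    """

    country: str
    region: str
    income: str | None
    year: int
    n_records: int = 2000
    p_male: float = 0.5
    age_mean: float = 45.0
    age_sd: float = 11.0
    sbp_mean: float = 128.0
    sbp_sd: float = 18.0
    sbp_loading: float = 0.35
    bmi_mean: float = 26.0
    bmi_sd: float = 4.5
    bmi_loading: float = 0.55
    waist_loading: float = 3.0
    tc_mean: float = 185.0
    tc_sd: float = 38.0
    tc_loading: float = 0.35
    hdl_mean_male: float = 45.0
    hdl_mean_female: float = 52.0
    hdl_sd: float = 12.0
    has_hdl: bool = True
    p_smoker: float = 0.20
    p_diabetes: float = 0.10
    diabetes_loading: float = 0.50
    p_diagnosed_given_diabetes: float = 0.5
    p_bp_treatment: float = 0.10
    treatment_sbp_corr: float = 0.45
    p_pregnant: float = 0.03
    p_cvd_history: float = 0.05
    education_probs: tuple = field(default_factory=_default_education)
    marital_probs: tuple = field(default_factory=_default_marital)
    work_probs: tuple = field(default_factory=_default_work)
    n_strata: int = 8
    psus_per_stratum: int = 6
    psu_sbp_sd: float = 2.0
    weight_dispersion: float = 0.4
    error_rates: Mapping[str, float] = field(default_factory=dict)
    missing_rates: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("p_male", "p_smoker", "p_diabetes", "p_bp_treatment",
                     "p_pregnant", "p_cvd_history",
                     "p_diagnosed_given_diabetes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("age_sd", "sbp_sd", "bmi_sd", "tc_sd", "hdl_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        for probs, name in ((self.education_probs, "education_probs"),
                            (self.marital_probs, "marital_probs"),
                            (self.work_probs, "work_probs")):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} must be a probability vector")
        for rates, name in ((self.error_rates, "error_rates"),
                            (self.missing_rates, "missing_rates")):
            for k, v in rates.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k!r}] must be in [0,1]")


#: presets transcribed from the published per-survey summaries
#: (mean age, % men, mean SBP, mean BMI, % smokers, % diabetes);
#: income bands are static approximate metadata.
PRESETS: dict[str, CountrySimParams] = {
    name: CountrySimParams(country=name, region=region, income=income,
                           year=year, age_mean=age, p_male=pm,
                           sbp_mean=sbp, bmi_mean=bmi,
                           p_smoker=smk, p_diabetes=dia)
    for name, (region, income, year, age, pm, sbp, bmi, smk, dia) in {
        "Ethiopia": ("Africa", "low", 2015, 43, 0.556, 123.3, 20.7, 0.057, 0.032),
        "Zambia": ("Africa", "lower-middle", 2017, 43, 0.489, 126.3, 23.8, 0.145, 0.108),
        "Algeria": ("Africa", "upper-middle", 2017, 45, 0.509, 129.6, 27.4, 0.150, 0.136),
        "Ecuador": ("Americas", "upper-middle", 2018, 47, 0.480, 122.1, 28.0, 0.128, 0.139),
        "Guyana": ("Americas", "upper-middle", 2016, 46, 0.454, 129.4, 28.1, 0.122, 0.232),
        "Jordan": ("Eastern Mediterranean", "upper-middle", 2019, 45, 0.412, 120.5, 30.2, 0.358, 0.173),
        "Iraq": ("Eastern Mediterranean", "upper-middle", 2015, 45, 0.485, 133.4, 30.2, 0.207, 0.186),
        "Belarus": ("Europe", "upper-middle", 2017, 48, 0.466, 137.1, 27.8, 0.299, 0.075),
        "Georgia": ("Europe", "lower-middle", 2016, 48, 0.425, 132.4, 29.2, 0.260, 0.077),
        "Bangladesh": ("Southeast Asia", "lower-middle", 2018, 46, 0.517, 123.1, 22.7, 0.283, 0.125),
        "Nepal": ("Southeast Asia", "low", 2019, 45, 0.472, 127.5, 23.4, 0.208, 0.085),
        "Mongolia": ("Western Pacific", "lower-middle", 2019, 44, 0.499, 124.3, 27.0, 0.285, 0.124),
        "Nauru": ("Western Pacific", "high", 2016, 43, 0.518, 126.6, 35.6, 0.420, 0.301),
        "Vietnam": ("Western Pacific", "lower-middle", 2015, 46, 0.496, 123.1, 22.4, 0.297, 0.043),
    }.items()
}

GENERIC_LMIC = CountrySimParams(country="GenericLMIC", region="Africa",
                                income="lower-middle", year=2017)


@dataclass
class TruthLedger:
    """Ground truth behind one simulated country."""

    truth: pd.DataFrame         # per-record latent/true values
    prevalence: dict            # true marginal prevalence of binary traits
    corruption: pd.DataFrame    # row_id, column, original, corrupted
    weights_note: str


def _rng_for(country: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(country.encode())]))


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_country(params: CountrySimParams, seed: int) -> tuple[pd.DataFrame,
                                                                   TruthLedger]:
    """Generate one country's raw survey table plus its ground-truth ledger.

    Deterministic for a fixed (params, seed).  Error injection and
    missingness per ``params.error_rates``/``params.missing_rates`` are
    applied after the truth is recorded, and every corruption is ledgered.
    """
    params.validate()
    rng = _rng_for(params.country, seed)
    n = params.n_records

    male = rng.random(n) < params.p_male
    sex = np.where(male, "male", "female")
    age = np.rint(_trunc_normal(rng, params.age_mean, params.age_sd,
                                29.5, 74.49, n)).astype(int)
    age = np.clip(age, 30, 74)

    m_factor = rng.standard_normal(n)

    def loaded(loading, size=n):
        return loading * m_factor + np.sqrt(1 - loading ** 2) * rng.standard_normal(size)

    z_sbp = loaded(params.sbp_loading)
    sbp_true = np.clip(params.sbp_mean + params.sbp_sd * z_sbp, 75.0, 265.0)
    bmi_true = np.clip(params.bmi_mean + params.bmi_sd * loaded(params.bmi_loading),
                       12.5, 70.0)
    height = np.clip(np.where(male, rng.normal(1.70, 0.07, n),
                              rng.normal(1.58, 0.065, n)), 1.30, 2.20)
    weight_kg = bmi_true * height ** 2
    waist = np.clip(2.5 * bmi_true + np.where(male, 28.0, 22.0)
                    + params.waist_loading * m_factor + rng.normal(0, 4, n),
                    35.0, 195.0)
    tc = np.clip(params.tc_mean + params.tc_sd * loaded(params.tc_loading),
                 80.0, 600.0)
    hdl_mean = np.where(male, params.hdl_mean_male, params.hdl_mean_female)
    hdl = np.clip(hdl_mean + params.hdl_sd * (-0.3 * m_factor
                  + np.sqrt(1 - 0.09) * rng.standard_normal(n)), 15.0, 120.0)

    # diabetes: Gaussian-copula threshold on a liability loading on M
    lam = params.diabetes_loading
    z_dia = lam * m_factor + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
    diabetic = z_dia > stats.norm.ppf(1.0 - params.p_diabetes)
    diagnosed = diabetic & (rng.random(n) < params.p_diagnosed_given_diabetes)
    fpg = np.empty(n)
    nd = ~diabetic
    fpg[nd] = _trunc_normal(rng, 95.0, 12.0, 60.0, 125.4, int(nd.sum()))
    dx = diagnosed
    fpg[dx] = _trunc_normal(rng, 150.0, 40.0, 80.0, 400.0, int(dx.sum()))
    udx = diabetic & ~diagnosed
    fpg[udx] = _trunc_normal(rng, 160.0, 30.0, 126.5, 450.0, int(udx.sum()))

    # BP treatment: copula-correlated with the SBP z-score, exact marginal
    rho = params.treatment_sbp_corr
    z_trt = rho * z_sbp + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    treated = z_trt > stats.norm.ppf(1.0 - params.p_bp_treatment)

    smoker = rng.random(n) < params.p_smoker
    pregnant = (~male) & (age < 50) & (rng.random(n) < params.p_pregnant)
    cvd = rng.random(n) < params.p_cvd_history

    # design geometry: strata, PSUs, weights; a small PSU-level SBP shift
    stratum = rng.integers(0, params.n_strata, n)
    psu_local = rng.integers(0, params.psus_per_stratum, n)
    psu = np.array([f"{params.country}-s{s}-p{p}"
                    for s, p in zip(stratum, psu_local)])
    psu_codes, psu_idx = np.unique(psu, return_inverse=True)
    psu_shift = rng.normal(0.0, params.psu_sbp_sd, len(psu_codes))[psu_idx]
    sbp_true = np.clip(sbp_true + psu_shift, 72.0, 268.0)
    if params.weight_dispersion > 0:
        weight = np.exp(rng.normal(0.0, params.weight_dispersion, n))
    else:
        weight = np.ones(n)

    dbp_true = np.clip(50.0 + 0.25 * sbp_true + rng.normal(0, 6, n), 35.0, 145.0)
    meas = {f"sbp{k}": np.round(sbp_true + rng.normal(0, 4.0, n), 1)
            for k in (1, 2, 3)}
    meas.update({f"dbp{k}": np.round(dbp_true + rng.normal(0, 3.0, n), 1)
                 for k in (1, 2, 3)})

    edu = rng.choice(np.arange(1, 8), size=n, p=params.education_probs)
    mar = rng.choice(np.arange(1, 7), size=n, p=params.marital_probs)
    wrk = rng.choice(np.arange(1, 10), size=n, p=params.work_probs)

    yn = lambda b: np.where(b, "yes", "no")
    raw = pd.DataFrame({
        "row_id": np.arange(n), "country": params.country,
        "region": params.region, "income": params.income, "year": params.year,
        "psu": psu, "stratum": [f"{params.country}-s{s}" for s in stratum],
        "weight": weight,
        "sex": sex, "age": age,
        **{k: meas[k] for k in ("sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3")},
        "height_m": np.round(height, 3), "weight_kg": np.round(weight_kg, 1),
        "waist_cm": np.round(waist, 1), "fpg": np.round(fpg, 1),
        "total_chol": np.round(tc, 1),
        "hdl": np.round(hdl, 1) if params.has_hdl else np.nan,
        "self_reported_diabetes": yn(diagnosed),
        "bp_treatment_2wk": yn(treated),
        "current_smoker": yn(smoker),
        "pregnant": yn(pregnant),
        "cvd_history": yn(cvd),
        "education_raw": edu, "marital_raw": mar, "work_raw": wrk,
    })

    truth = pd.DataFrame({
        "row_id": np.arange(n), "m_factor": m_factor,
        "sbp_true": sbp_true, "dbp_true": dbp_true, "bmi_true": bmi_true,
        "diabetes_true": diabetic, "diagnosed_true": diagnosed,
        "smoker_true": smoker, "bp_treatment_true": treated,
        "pregnant_true": pregnant, "cvd_history_true": cvd,
    })
    wsum = weight.sum()
    prevalence = {
        "smoker": float((weight * smoker).sum() / wsum),
        "diabetes": float((weight * diabetic).sum() / wsum),
        "bp_treatment": float((weight * treated).sum() / wsum),
        "pregnant": float((weight * pregnant).sum() / wsum),
        "cvd_history": float((weight * cvd).sum() / wsum),
        "nominal": {"smoker": params.p_smoker, "diabetes": params.p_diabetes,
                    "bp_treatment": params.p_bp_treatment},
    }

    raw, corruption = inject_errors(raw, dict(params.error_rates),
                                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                                    missing_rates=dict(params.missing_rates))
    ledger = TruthLedger(
        truth=truth, prevalence=prevalence, corruption=corruption,
        weights_note=("lognormal(0, %.3f) per record, independent of traits"
                      % params.weight_dispersion))
    return raw, ledger


def _draw_out_of_range(rng, rule: str, height: float | None = None) -> float:
    """One implausible value from the documented bands for ``rule``."""
    if rule == "bmi":
        raise ValueError("bmi corruption is handled via weight_kg")
    lo_band, hi_band = OUT_OF_RANGE_BANDS[rule]
    band = lo_band if rng.random() < 0.5 else hi_band
    return float(rng.uniform(*band))


def inject_errors(records: pd.DataFrame, rates: Mapping[str, float],
                  seed: int, missing_rates: Mapping[str, float] | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt records with implausible values and/or missingness.

    ``rates`` keys are plausibility rules ('sbp', 'dbp', 'height',
    'weight', 'bmi', 'waist', 'fpg', 'total_chol', 'age', plus the
    exclusion flips 'pregnant' and 'cvd_history'); each selected record
    gets a value drawn uniformly from a documented out-of-range band.  For
    'sbp'/'dbp' both the 2nd and 3rd readings are replaced with the same
    draw so the measurement mean lands out of range; 'bmi' rewrites
    weight_kg so the derived BMI is implausible while height and weight
    stay individually plausible.  ``missing_rates`` keys are raw column
    names; selected cells become NaN.  Returns the corrupted copy and a
    ledger (row_id, column, original, corrupted) listing every change.
    """
    for k, v in {**rates, **(missing_rates or {})}.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"rate for {k!r} must be in [0,1], got {v}")
    rng = np.random.default_rng(seed)
    df = records.copy()
    entries: list[dict] = []

    def log(row_pos, col, new):
        entries.append({"row_id": df["row_id"].iat[row_pos], "column": col,
                        "original": records[col].iat[row_pos],
                        "corrupted": new})
        df.iloc[row_pos, df.columns.get_loc(col)] = new

    n = len(df)
    for rule, rate in rates.items():
        if rate <= 0:
            continue
        hit = np.flatnonzero(rng.random(n) < rate)
        for i in hit:
            if rule in ("pregnant", "cvd_history"):
                if rule == "pregnant" and df["sex"].iat[i] != "female":
                    continue
                log(i, rule, "yes")
            elif rule == "bmi":
                h = float(df["height_m"].iat[i])
                if 82.0 * h * h <= 300.0:
                    u = rng.uniform(81.0, min(92.0, 300.0 / (h * h) - 0.5))
                else:  # tall: push BMI below 10 instead, weight stays >= 12
                    u = rng.uniform(max(12.0 / (h * h) + 0.1, 4.0), 9.8)
                log(i, "weight_kg", round(u * h * h, 1))
            elif rule in ("sbp", "dbp"):
                val = round(_draw_out_of_range(rng, rule), 1)
                log(i, f"{rule}2", val)
                log(i, f"{rule}3", val)
            else:
                col = _RAW_COLUMNS_OF[rule][0]
                val = _draw_out_of_range(rng, rule)
                if rule == "age":
                    val = int(val)
                elif rule == "height":
                    val = round(val, 3)
                else:
                    val = round(val, 1)
                log(i, col, val)
    for col, rate in (missing_rates or {}).items():
        if rate <= 0:
            continue
        hit = np.flatnonzero(rng.random(n) < rate)
        for i in hit:
            log(i, col, np.nan)

    ledger = pd.DataFrame(entries, columns=["row_id", "column", "original",
                                            "corrupted"])
    return df, ledger


def simulate_multi_country(params_list: Sequence[CountrySimParams], seed: int
                           ) -> tuple[pd.DataFrame, dict[str, TruthLedger]]:
    """Pool several countries, each from its own independent substream.

    Records for a given country are identical whether it is generated alone
    or with others; duplicate country codes are rejected.
    """
    names = [p.country for p in params_list]
    if len(set(names)) != len(names):
        raise ValueError("duplicate country codes in params list")
    if not params_list:
        raise ValueError("need at least one country")
    frames, ledgers = [], {}
    offset = 0
    for p in params_list:
        raw, ledger = simulate_country(p, seed)
        raw = raw.copy()
        raw["row_id"] = raw["row_id"] + offset
        ledger.truth = ledger.truth.copy()
        ledger.truth["row_id"] = ledger.truth["row_id"] + offset
        if len(ledger.corruption):
            ledger.corruption = ledger.corruption.copy()
            ledger.corruption["row_id"] = ledger.corruption["row_id"] + offset
        offset += len(raw)
        frames.append(raw)
        ledgers[p.country] = ledger
    return pd.concat(frames, ignore_index=True), ledgers


def preset(country: str, **overrides) -> CountrySimParams:
    """A named preset, optionally with overridden fields."""
    if country not in PRESETS:
        raise KeyError(f"no preset for {country!r}; "
                       f"available: {sorted(PRESETS)}")
    return replace(PRESETS[country], **overrides)
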