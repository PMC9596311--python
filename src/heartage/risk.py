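"""Framingham 10-year general-CVD risk: sex-specific Cox-type equations.

Two published variants are supported:

* ``non_lab`` — the office-based score using age, SBP (with separate weights
  for treated and untreated blood pressure), BMI, current smoking and
  diabetes.  This is the variant used for the primary heart-age analysis,
  because HDL cholesterol is not measured in many national surveys.
* ``lab`` — the laboratory score in which total and HDL cholesterol replace
  BMI.

For either variant the 10-year risk is

    risk = 1 - S0 ** exp(LP - mean_LP)

where ``LP`` is the linear predictor (a weighted sum of log-transformed
continuous predictors and 0/1 indicators), ``S0`` the sex-specific baseline
10-year survival and ``mean_LP`` the cohort mean of the linear predictor.
Risk is carried as a fraction in (0, 1) throughout; formatting as percent is
left to the reporting layer.

The calculator only accepts SBP in [90, 200] mmHg and BMI in [15, 50] kg/m^2;
:func:`clamp_calculator_inputs` applies that clamping and records whether it
occurred.  Coefficient values live in ``data/framingham.yaml`` (see the
provenance note there), never in code.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

NON_LAB = "non_lab"
LAB = "lab"
MALE = "male"
FEMALE = "female"

VARIANTS = (NON_LAB, LAB)
SEXES = (MALE, FEMALE)

#: calculator input ranges (clamped, not dropped)
SBP_CALC_RANGE = (90.0, 200.0)
BMI_CALC_RANGE = (15.0, 50.0)

_REQUIRED_TERMS = {
    NON_LAB: {"ln_age", "ln_sbp_untreated", "ln_sbp_treated", "ln_bmi",
              "smoker", "diabetes"},
    LAB: {"ln_age", "ln_sbp_untreated", "ln_sbp_treated", "ln_total_chol",
          "ln_hdl", "smoker", "diabetes"},
}

#: the ideal reference profile anchoring heart-age inversion
IDEAL_REFERENCE = {
    "sbp": 125.0,
    "bmi": 22.5,
    "total_chol": 180.0,
    "hdl": 45.0,
    "on_bp_treatment": False,
    "smoker": False,
    "diabetes": False,
}


class CoefficientError(ValueError):
    """Raised when a coefficient file fails schema validation."""


@dataclass(frozen=True)
class CoefficientSet:
    """Equation constants for one (variant, sex) cell.

    ``weights`` maps predictor terms to regression coefficients;
    ``baseline_survival_10y`` is S0(10); ``mean_linear_predictor`` the mean
    risk-factor sum; ``ideal_reference`` the risk-factor profile used as the
    heart-age anchor.
    """

    model_variant: str
    sex: str
    weights: Mapping[str, float]
    baseline_survival_10y: float
    mean_linear_predictor: float
    ideal_reference: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.model_variant not in VARIANTS:
            raise CoefficientError(f"unknown model variant {self.model_variant!r}")
        if self.sex not in SEXES:
            raise CoefficientError(f"unknown sex {self.sex!r}")
        missing = _REQUIRED_TERMS[self.model_variant] - set(self.weights)
        if missing:
            raise CoefficientError(
                f"{self.model_variant}/{self.sex}: missing terms {sorted(missing)}")
        if self.weights["ln_age"] <= 0:
            raise CoefficientError("ln_age weight must be positive "
                                   "(risk must be monotone in age)")
        if not 0.0 < self.baseline_survival_10y < 1.0:
            raise CoefficientError("baseline_survival_10y must be in (0,1)")


@dataclass(frozen=True)
class RiskProfile:
    """One person's risk-factor inputs.

    ``bmi`` is required for the non-lab variant; ``total_cholesterol`` and
    ``hdl_cholesterol`` (mg/dl) only for the lab variant.  Age must already
    be inside the score's validity window [30, 74] years (fractional ages
    are allowed and used as supplied).
    """

    sex: str
    age: float
    sbp: float
    on_bp_treatment: bool
    smoker: bool
    diabetes: bool
    bmi: float | None = None
    total_cholesterol: float | None = None
    hdl_cholesterol: float | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 30.0 <= float(self.age) <= 74.0:
            raise ValueError(f"age {self.age} outside the score's range [30, 74]")
        if self.sbp is None or not self.sbp > 0:
            raise ValueError("sbp must be positive")
        if self.bmi is not None and not self.bmi > 0:
            raise ValueError("bmi must be positive when present")


def load_coefficients(path=None) -> dict[tuple[str, str], CoefficientSet]:
    """Load and schema-validate the shipped (or a user-supplied) coefficient file.

    Returns a mapping ``(variant, sex) -> CoefficientSet``.
    """
    if path is None:
        ref = importlib.resources.files("heartage").joinpath("data/framingham.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    ideal = raw.get("ideal_reference")
    if ideal is None:
        raise CoefficientError("coefficient file lacks ideal_reference block")
    for key, val in IDEAL_REFERENCE.items():
        if ideal.get(key) != val and key in ("sbp", "bmi", "on_bp_treatment",
                                             "smoker", "diabetes"):
            raise CoefficientError(
                f"ideal_reference.{key} must be {val!r}, got {ideal.get(key)!r}")
    out: dict[tuple[str, str], CoefficientSet] = {}
    for variant in VARIANTS:
        block = raw.get(variant)
        if block is None:
            raise CoefficientError(f"coefficient file lacks {variant!r} block")
        for sex in SEXES:
            cell = block.get(sex)
            if cell is None:
                raise CoefficientError(f"coefficient file lacks {variant}/{sex}")
            out[(variant, sex)] = CoefficientSet(
                model_variant=variant,
                sex=sex,
                weights={k: float(v) for k, v in cell["weights"].items()},
                baseline_survival_10y=float(cell["baseline_survival_10y"]),
                mean_linear_predictor=float(cell["mean_linear_predictor"]),
                ideal_reference=dict(ideal),
            )
    return out


# ---------------------------------------------------------------------------
# input clamping

def clamp_calculator_inputs(profile: RiskProfile) -> RiskProfile:
    """Clamp SBP into [90, 200] and (when present) BMI into [15, 50].

    All other fields are unchanged; the returned profile's ``clamped`` flag
    records whether any clamping occurred.
    """
    if profile.sbp is None:
        raise ValueError("profile is missing sbp")
    sbp = min(max(profile.sbp, SBP_CALC_RANGE[0]), SBP_CALC_RANGE[1])
    changed = sbp != profile.sbp
    bmi = profile.bmi
    if bmi is not None:
        bmi_clamped = min(max(bmi, BMI_CALC_RANGE[0]), BMI_CALC_RANGE[1])
        changed = changed or bmi_clamped != bmi
        bmi = bmi_clamped
    return replace(profile, sbp=sbp, bmi=bmi, clamped=profile.clamped or changed)


# ---------------------------------------------------------------------------
# linear predictor and risk

def _require_match(profile: RiskProfile, coeffs: CoefficientSet) -> None:
    if profile.sex != coeffs.sex:
        raise ValueError(
            f"profile sex {profile.sex!r} does not match coefficient sex "
            f"{coeffs.sex!r}")
    if coeffs.model_variant == NON_LAB and profile.bmi is None:
        raise ValueError("non-lab variant requires bmi")
    if coeffs.model_variant == LAB and (
            profile.total_cholesterol is None or profile.hdl_cholesterol is None):
        raise ValueError("lab variant requires total_cholesterol and hdl_cholesterol")


def linear_predictor(profile: RiskProfile, coeffs: CoefficientSet) -> float:
    """Weighted sum of log-transformed predictors and 0/1 indicators."""
    _require_match(profile, coeffs)
    w = coeffs.weights
    sbp_term = "ln_sbp_treated" if profile.on_bp_treatment else "ln_sbp_untreated"
    lp = w["ln_age"] * math.log(profile.age) + w[sbp_term] * math.log(profile.sbp)
    if coeffs.model_variant == NON_LAB:
        lp += w["ln_bmi"] * math.log(profile.bmi)
    else:
        lp += w["ln_total_chol"] * math.log(profile.total_cholesterol)
        lp += w["ln_hdl"] * math.log(profile.hdl_cholesterol)
    if profile.smoker:
        lp += w["smoker"]
    if profile.diabetes:
        lp += w["diabetes"]
    return lp


@dataclass(frozen=True)
class RiskResult:
    linear_predictor: float
    risk_10y: float


def risk_from_linear_predictor(lp, coeffs: CoefficientSet):
    """1 - S0 ** exp(lp - mean_lp); accepts scalars or arrays."""
    return 1.0 - coeffs.baseline_survival_10y ** np.exp(
        np.asarray(lp, dtype=float) - coeffs.mean_linear_predictor)


def risk_10y(profile: RiskProfile, coeffs: CoefficientSet) -> RiskResult:
    """10-year CVD risk on the probability (fraction) scale."""
    lp = linear_predictor(profile, coeffs)
    return RiskResult(linear_predictor=lp,
                      risk_10y=float(risk_from_linear_predictor(lp, coeffs)))


# ---------------------------------------------------------------------------
# vectorized scoring over a cleaned table

def score_dataframe(df: pd.DataFrame,
                    coeffs: Mapping[tuple[str, str], CoefficientSet],
                    variant: str = NON_LAB) -> pd.DataFrame:
    """Append ``clamped``, ``linear_predictor`` and ``risk_10y`` columns.

    Expects cleaned columns ``sex`` ('male'/'female'), ``age``, ``sbp``,
    ``on_bp_treatment``, ``smoker``, ``diabetes`` and, per variant, ``bmi``
    or ``total_chol``+``hdl``.  The input frame is not mutated.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    need = ["sex", "age", "sbp", "on_bp_treatment", "smoker", "diabetes"]
    need += ["bmi"] if variant == NON_LAB else ["total_chol", "hdl"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"scoring requires columns {missing}")
    if df[need].isna().any().any():
        bad = [c for c in need if df[c].isna().any()]
        raise ValueError(f"scoring input contains missing values in {bad}")

    out = df.copy()
    sbp = df["sbp"].to_numpy(float)
    sbp_c = np.clip(sbp, *SBP_CALC_RANGE)
    clamped = sbp_c != sbp
    if variant == NON_LAB:
        bmi = df["bmi"].to_numpy(float)
        bmi_c = np.clip(bmi, *BMI_CALC_RANGE)
        clamped = clamped | (bmi_c != bmi)
    out["clamped"] = clamped

    lp = np.empty(len(df), dtype=float)
    risk = np.empty(len(df), dtype=float)
    treated = df["on_bp_treatment"].to_numpy(bool)
    smoker = df["smoker"].to_numpy(bool)
    diabetes = df["diabetes"].to_numpy(bool)
    age = df["age"].to_numpy(float)
    for sex in SEXES:
        m = (df["sex"] == sex).to_numpy()
        if not m.any():
            continue
        c = coeffs[(variant, sex)]
        w = c.weights
        sbp_w = np.where(treated[m], w["ln_sbp_treated"], w["ln_sbp_untreated"])
        lp_m = (w["ln_age"] * np.log(age[m]) + sbp_w * np.log(sbp_c[m])
                + w["smoker"] * smoker[m] + w["diabetes"] * diabetes[m])
        if variant == NON_LAB:
            lp_m = lp_m + w["ln_bmi"] * np.log(bmi_c[m])
        else:
            lp_m = lp_m + w["ln_total_chol"] * np.log(df["total_chol"].to_numpy(float)[m])
            lp_m = lp_m + w["ln_hdl"] * np.log(df["hdl"].to_numpy(float)[m])
        lp[m] = lp_m
        risk[m] = risk_from_linear_predictor(lp_m, c)
    out["linear_predictor"] = lp
    out["risk_10y"] = risk
    return out


# ---------------------------------------------------------------------------
# paired lab vs non-lab comparison

@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test summary for two risk (or heart-age) series."""

    n: int
    mean_first: float
    mean_second: float
    mean_difference: float
    t_statistic: float
    p_value: float
    degenerate: bool  # all differences identical (zero variance): t/p undefined


def compare_lab_nonlab(paired_values: Sequence[tuple[float, float]] | Iterable
                       ) -> PairedComparison:
    """Paired t-test on element-wise differences (first - second member).

    Mirrors the sensitivity analysis contrasting risk/heart age computed from
    the laboratory vs the non-laboratory score on the same people.  When all
    differences are identical the t statistic is undefined and the result is
    flagged ``degenerate`` with NaN t and p.
    """
    arr = np.asarray(list(paired_values), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (first, second) pairs")
    if arr.shape[0] < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if not np.isfinite(arr).all():
        raise ValueError("paired values must be finite")
    diff = arr[:, 0] - arr[:, 1]
    n = len(diff)
    mean_d = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return PairedComparison(n, float(arr[:, 0].mean()), float(arr[:, 1].mean()),
                                mean_d, float("nan"), float("nan"), True)
    t = mean_d / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedComparison(n, float(arr[:, 0].mean()), float(arr[:, 1].mean()),
                            mean_d, t, p, False)
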