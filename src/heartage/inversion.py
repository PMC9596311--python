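"""Heart-age inversion, censoring and gap classification.

Predicted heart age (PHA) is the chronological age of a hypothetical person
whose modifiable risk factors sit at their ideal levels (SBP 125 mmHg,
untreated; BMI 22.5 kg/m^2; non-smoker; non-diabetic) and whose predicted
10-year CVD risk equals the subject's.  Because risk is a strictly monotone
function of the linear predictor, matching risks is the same as matching
linear predictors and the inversion has the closed form

    pha = exp((LP_subject - C_ideal) / w_ln_age)

where ``C_ideal`` is the sum of the non-age terms evaluated at the ideal
reference profile.  The upstream calculator reports heart age numerically
only inside [30, 80] years: values rounding below 30 are censored to the
sentinel "<30" and above 80 to ">80".  Continuous PHA is rounded to the
nearest integer year (half away from zero) *before* censoring, so 29.6
becomes 30, not "<30".

The PHA - chronological-age gap is classified as ``low`` (gap < 0),
``equal`` (gap = 0), ``high`` (1-4 years) or ``very_high`` (>= 5 years);
``high`` and ``very_high`` together constitute *excess* PHA.  Censored
values classify by a bound argument: for study ages 30-74 a ">80" PHA
always implies a gap >= 7 (very_high) and a "<30" PHA a gap <= -1 (low),
so sentinels never leave the classification undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .risk import (LAB, NON_LAB, SEXES, CoefficientSet, RiskProfile,
                   linear_predictor, _require_match)

UNDER_30 = "<30"
OVER_80 = ">80"

GAP_CLASSES = ("low", "equal", "high", "very_high")

#: 5-year band edges for both chronological age and coded PHA
_BAND_LO = 30
_BAND_HI = 80


@dataclass(frozen=True)
class HeartAgeResult:
    pha_continuous: float
    pha_coded: int | str
    gap_class: str
    excess: bool


def _ideal_constant(coeffs: CoefficientSet) -> float:
    """Sum of the non-age linear-predictor terms at the ideal reference."""
    w = coeffs.weights
    ref = coeffs.ideal_reference
    c = w["ln_sbp_untreated"] * math.log(ref["sbp"])
    if coeffs.model_variant == NON_LAB:
        c += w["ln_bmi"] * math.log(ref["bmi"])
    else:
        c += w["ln_total_chol"] * math.log(ref["total_chol"])
        c += w["ln_hdl"] * math.log(ref["hdl"])
    # smoker/diabetes/treatment are false at ideal: no contribution
    return c


def heart_age_from_lp(lp, coeffs: CoefficientSet):
    """Closed-form inversion of the linear predictor to heart age (years).

    Accepts scalars or arrays.  Raises if the age weight is not positive
    (the inversion requires risk monotone in age).
    """
    w_age = coeffs.weights["ln_age"]
    if w_age <= 0:
        raise ValueError("ln_age weight must be positive to invert to heart age")
    return np.exp((np.asarray(lp, dtype=float) - _ideal_constant(coeffs)) / w_age)


def heart_age(profile: RiskProfile, coeffs: CoefficientSet) -> float:
    """Continuous (pre-censoring) predicted heart age for one subject."""
    _require_match(profile, coeffs)
    return float(heart_age_from_lp(linear_predictor(profile, coeffs), coeffs))


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def censor_code(pha_continuous: float) -> int | str:
    """Round to integer years and apply the calculator's reporting window.

    Rounded values below 30 are returned as the sentinel "<30", above 80 as
    ">80", otherwise the integer itself.
    """
    if not np.isfinite(pha_continuous) or pha_continuous <= 0:
        raise ValueError(f"pha_continuous must be finite and positive, "
                         f"got {pha_continuous!r}")
    coded = round_half_away(float(pha_continuous))
    if coded < 30:
        return UNDER_30
    if coded > 80:
        return OVER_80
    return coded


def classify_gap(age: int, coded_pha: int | str) -> str:
    """Classify the coded-PHA minus chronological-age gap.

    ``age`` must be an integer year in [30, 74].  Sentinel PHAs classify by
    bounds: "<30" implies gap <= 29 - age <= -1 (low); ">80" implies
    gap >= 81 - age >= 7 (very_high).
    """
    age = int(age)
    if not 30 <= age <= 74:
        raise ValueError(f"age {age} outside [30, 74]")
    if coded_pha == UNDER_30:
        return "low"
    if coded_pha == OVER_80:
        return "very_high"
    gap = int(coded_pha) - age
    if gap < 0:
        return "low"
    if gap == 0:
        return "equal"
    if gap <= 4:
        return "high"
    return "very_high"


def pha_age_group(value: int | str) -> str:
    """5-year band label for a coded PHA or a chronological age.

    Bands run 30-34, 35-39, ..., 75-79 with open terminal bands "<30" and
    ">=80".
    """
    if value == UNDER_30:
        return "<30"
    if value == OVER_80:
        return ">=80"
    v = int(value)
    if v < _BAND_LO:
        return "<30"
    if v >= _BAND_HI:
        return ">=80"
    lo = _BAND_LO + 5 * ((v - _BAND_LO) // 5)
    return f"{lo}-{lo + 4}"


def heart_age_result(profile: RiskProfile, coeffs: CoefficientSet,
                     age: int | None = None) -> HeartAgeResult:
    """Full per-subject heart-age outcome (continuous, coded, gap class)."""
    cont = heart_age(profile, coeffs)
    coded = censor_code(cont)
    cls = classify_gap(int(round(profile.age)) if age is None else age, coded)
    return HeartAgeResult(cont, coded, cls, cls in ("high", "very_high"))


# ---------------------------------------------------------------------------
# vectorized over a scored table

def heartage_dataframe(df: pd.DataFrame,
                       coeffs: Mapping[tuple[str, str], CoefficientSet],
                       variant: str = NON_LAB,
                       prefix: str = "") -> pd.DataFrame:
    """Append pha_continuous, pha_coded, gap_class and excess columns.

    Expects a frame already scored by :func:`heartage.risk.score_dataframe`
    (columns ``sex``, ``age``, ``linear_predictor``).  ``prefix`` lets the
    lab-variant sensitivity run coexist with the primary columns.  Sentinels
    are stored literally as "<30" and ">80".
    """
    if "linear_predictor" not in df.columns:
        raise ValueError("heartage_dataframe needs a scored frame "
                         "(run score_dataframe first)")
    out = df.copy()
    lp = df["linear_predictor"].to_numpy(float)
    cont = np.empty(len(df), dtype=float)
    for sex in SEXES:
        m = (df["sex"] == sex).to_numpy()
        if m.any():
            cont[m] = heart_age_from_lp(lp[m], coeffs[(variant, sex)])
    coded = [censor_code(v) for v in cont]
    ages = df["age"].to_numpy()
    cls = [classify_gap(int(round(a)), c) for a, c in zip(ages, coded)]
    out[prefix + "pha_continuous"] = cont
    out[prefix + "pha_coded"] = coded
    out[prefix + "gap_class"] = cls
    out[prefix + "excess"] = [c in ("high", "very_high") for c in cls]
    return out
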