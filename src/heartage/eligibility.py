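"""WHO HEARTS treatment-eligibility rules.

Antihypertensive treatment is indicated for any of (in priority order):

1. ``risk10_bp140`` — 10-year CVD risk in [10%, 20%) with SBP >= 140 or
   DBP >= 90 mmHg;
2. ``risk20_bp130`` — risk >= 20% with SBP >= 130 or DBP >= 80 mmHg;
3. ``bp160_any``    — SBP >= 160 or DBP >= 100 mmHg regardless of risk.

Lipid-lowering treatment is indicated for:

1. ``risk20``          — risk >= 20%;
2. ``diabetes_40plus`` — age >= 40 years with diabetes.

The guideline's "10%-19%" band is implemented as the half-open interval
[0.10, 0.20) so the two risk bands partition [0.10, inf).  Risk enters as
an exact fraction (no rounding to whole percent).  Blood pressures are the
cleaned means of the 2nd and 3rd measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AHT_RULES = ("risk10_bp140", "risk20_bp130", "bp160_any", "none")
LLT_RULES = ("risk20", "diabetes_40plus", "none")


@dataclass(frozen=True)
class EligibilityResult:
    antihypertensive: bool
    antihypertensive_rule: str
    lipid_lowering: bool
    lipid_lowering_rule: str


def _check_risk(risk_10y: float) -> None:
    if not 0.0 <= risk_10y <= 1.0:
        raise ValueError(f"risk_10y must be a fraction in [0, 1], got {risk_10y}")


def antihypertensive_eligible(risk_10y: float, sbp: float, dbp: float
                              ) -> tuple[bool, str]:
    """(eligible, triggering rule) for antihypertensive treatment."""
    _check_risk(risk_10y)
    if 0.10 <= risk_10y < 0.20 and (sbp >= 140 or dbp >= 90):
        return True, "risk10_bp140"
    if risk_10y >= 0.20 and (sbp >= 130 or dbp >= 80):
        return True, "risk20_bp130"
    if sbp >= 160 or dbp >= 100:
        return True, "bp160_any"
    return False, "none"


def lipid_lowering_eligible(risk_10y: float, age: float, diabetes: bool
                            ) -> tuple[bool, str]:
    """(eligible, triggering rule) for lipid-lowering treatment."""
    _check_risk(risk_10y)
    if risk_10y >= 0.20:
        return True, "risk20"
    if age >= 40 and diabetes:
        return True, "diabetes_40plus"
    return False, "none"


def eligibility(risk_10y: float, sbp: float, dbp: float, age: float,
                diabetes: bool) -> EligibilityResult:
    aht, aht_rule = antihypertensive_eligible(risk_10y, sbp, dbp)
    llt, llt_rule = lipid_lowering_eligible(risk_10y, age, diabetes)
    return EligibilityResult(aht, aht_rule, llt, llt_rule)


def eligibility_dataframe(df: pd.DataFrame) -> pd.DataFrame:
    """Append elig_aht, elig_aht_rule, elig_llt, elig_llt_rule columns.

    Expects a scored frame with ``risk_10y``, ``sbp``, ``dbp``, ``age`` and
    ``diabetes`` columns; the input is not mutated.
    """
    need = ["risk_10y", "sbp", "dbp", "age", "diabetes"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"eligibility requires columns {missing}")
    risk = df["risk_10y"].to_numpy(float)
    if np.any((risk < 0) | (risk > 1)):
        raise ValueError("risk_10y values outside [0, 1]")
    sbp = df["sbp"].to_numpy(float)
    dbp = df["dbp"].to_numpy(float)
    age = df["age"].to_numpy(float)
    dia = df["diabetes"].to_numpy(bool)

    bp140 = (sbp >= 140) | (dbp >= 90)
    bp130 = (sbp >= 130) | (dbp >= 80)
    bp160 = (sbp >= 160) | (dbp >= 100)
    r1 = (risk >= 0.10) & (risk < 0.20) & bp140
    r2 = (risk >= 0.20) & bp130
    r3 = bp160
    aht_rule = np.select([r1, r2, r3], ["risk10_bp140", "risk20_bp130", "bp160_any"],
                         default="none")
    l1 = risk >= 0.20
    l2 = (age >= 40) & dia
    llt_rule = np.select([l1, l2], ["risk20", "diabetes_40plus"], default="none")

    out = df.copy()
    out["elig_aht"] = aht_rule != "none"
    out["elig_aht_rule"] = aht_rule
    out["elig_llt"] = llt_rule != "none"
    out["elig_llt_rule"] = llt_rule
    return out
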