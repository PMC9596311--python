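"""Design-aware prevalence estimation and aggregate summary tables.

National risk-factor surveys use stratified multistage cluster sampling;
point estimates are weighted means and variances come from the standard
stratified between-PSU Taylor linearization of the ratio estimator

    p = sum(w*y) / sum(w),   z_i = w_i * (y_i - p) / sum(w),

    Var(p) = sum_h  n_h/(n_h - 1) * sum_a (z_{ha} - zbar_h)^2,

where ``z_{ha}`` are linearized totals per PSU ``a`` in stratum ``h``.
Strata with a single PSU contribute their squared deviation from the grand
mean of PSU totals (the "centered at the grand mean" lonely-PSU rule).
95% CIs are normal-approximation on the proportion scale, truncated to
[0, 1].  Domain (subpopulation) estimates keep the full design and zero
out the linearized values outside the domain, as survey software does.

Aggregate summaries built on this estimator: the PHA-category composition
by country and sex, treatment eligibility among people with excess PHA
(at gap thresholds >= 1, 5, 10 and 20 years), PHA-category prevalence
within country-level weighted quintiles of absolute risk, the
chronological-band x PHA-band flow table (unweighted, as the divergence
description does not use the design), and one-way ANOVA comparing
country-level prevalences across regions or income groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inversion import OVER_80, UNDER_30, GAP_CLASSES, pha_age_group

Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class PrevalenceEstimate:
    proportion: float
    standard_error: float
    ci_lo: float
    ci_hi: float
    n_unweighted: int


def weighted_prevalence(y, weights, psu=None, stratum=None, domain=None
                        ) -> PrevalenceEstimate:
    """Design-based proportion of a 0/1 indicator with linearized SE.

    ``psu`` defaults to one PSU per record and ``stratum`` to a single
    stratum (an SRS-with-replacement design).  ``domain`` restricts the
    estimate to a subpopulation without collapsing the design.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with a positive sum")
    n = len(y)
    psu = np.arange(n) if psu is None else np.asarray(psu)
    stratum = np.zeros(n, dtype=int) if stratum is None else np.asarray(stratum)
    dom = np.ones(n, dtype=bool) if domain is None else np.asarray(domain, dtype=bool)
    if not dom.any():
        raise ValueError("empty domain")
    wd = np.where(dom, w, 0.0)
    W = wd.sum()
    if W <= 0:
        raise ValueError("all weights in the domain are zero")
    p = float((wd * y).sum() / W)

    z = wd * (np.where(dom, y, 0.0) - p) / W
    # PSU totals within strata
    frame = pd.DataFrame({"z": z, "psu": psu, "stratum": stratum})
    tot = frame.groupby(["stratum", "psu"], sort=False)["z"].sum()
    var = 0.0
    lonely = []
    grand_mean = float(tot.mean())
    for _, zh in tot.groupby(level="stratum", sort=False):
        nh = len(zh)
        if nh >= 2:
            var += nh / (nh - 1) * float(((zh - zh.mean()) ** 2).sum())
        else:
            lonely.append(float(((zh - grand_mean) ** 2).sum()))
    var += sum(lonely)
    se = float(np.sqrt(var))
    lo = max(0.0, p - Z95 * se)
    hi = min(1.0, p + Z95 * se)
    return PrevalenceEstimate(p, se, lo, hi, int(dom.sum()))


def _estimate_rows(df: pd.DataFrame, indicator: np.ndarray, by: Sequence[str],
                   domain: np.ndarray | None = None) -> list[dict]:
    """Domain prevalence of ``indicator`` for each group of ``by`` columns."""
    rows = []
    base = np.ones(len(df), dtype=bool) if domain is None else domain
    for keys, idx in df.groupby(list(by), sort=True, observed=True).groups.items():
        if not isinstance(keys, tuple):
            keys = (keys,)
        mask = np.zeros(len(df), dtype=bool)
        mask[df.index.get_indexer(idx)] = True
        dom = mask & base
        row = dict(zip(by, keys))
        if not dom.any():
            row.update(proportion=np.nan, standard_error=np.nan,
                       ci_lo=np.nan, ci_hi=np.nan, n_unweighted=0,
                       empty_domain=True)
        else:
            est = weighted_prevalence(indicator, df["weight"], df["psu"],
                                      df["stratum"], domain=dom)
            row.update(proportion=est.proportion,
                       standard_error=est.standard_error,
                       ci_lo=est.ci_lo, ci_hi=est.ci_hi,
                       n_unweighted=est.n_unweighted, empty_domain=False)
        rows.append(row)
    return rows


def category_prevalence_table(df: pd.DataFrame,
                              by: Sequence[str] = ("country", "sex"),
                              class_col: str = "gap_class") -> pd.DataFrame:
    """Weighted proportion of each PHA gap category per domain.

    The four proportions sum to 1 within every domain because the gap
    classification is exhaustive and mutually exclusive.
    """
    rows = []
    for cat in GAP_CLASSES:
        ind = (df[class_col] == cat).to_numpy(dtype=float)
        for row in _estimate_rows(df, ind, by):
            row["category"] = cat
            rows.append(row)
    out = pd.DataFrame(rows)
    return out[[*by, "category", "proportion", "standard_error",
                "ci_lo", "ci_hi", "n_unweighted", "empty_domain"]]


def gap_lower_bound(df: pd.DataFrame, coded_col: str = "pha_coded") -> np.ndarray:
    """Numeric PHA-age gap; sentinels take their sharp bound (29 or 81)."""
    age = df["age"].to_numpy(int)
    coded = df[coded_col].to_numpy(object)
    out = np.empty(len(df), dtype=float)
    for i, (c, a) in enumerate(zip(coded, age)):
        if c == OVER_80:
            out[i] = 81 - a
        elif c == UNDER_30:
            out[i] = 29 - a
        else:
            out[i] = int(c) - a
    return out


def eligibility_among_excess(df: pd.DataFrame,
                             by: Sequence[str] = ("country", "sex"),
                             thresholds: Sequence[int] = (1, 5, 10, 20)
                             ) -> pd.DataFrame:
    """Weighted share eligible for each therapy among people with excess PHA.

    Denominator: records with PHA exceeding chronological age by at least
    the threshold (1 year = any excess).  Domains with an empty denominator
    are flagged, not dropped.
    """
    gap = gap_lower_bound(df)
    rows = []
    for thr in thresholds:
        dom = gap >= thr
        for therapy, col in (("antihypertensive", "elig_aht"),
                             ("lipid_lowering", "elig_llt")):
            ind = df[col].to_numpy(dtype=float)
            for row in _estimate_rows(df, ind, by, domain=dom):
                row["therapy"] = therapy
                row["gap_threshold"] = thr
                rows.append(row)
    out = pd.DataFrame(rows)
    return out[[*by, "therapy", "gap_threshold", "proportion",
                "standard_error", "ci_lo", "ci_hi", "n_unweighted",
                "empty_domain"]]


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Smallest value whose weighted CDF reaches q (inverse-CDF definition)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cdf = np.cumsum(w) / w.sum()
    return np.array([v[np.searchsorted(cdf, qi - 1e-12, side="left")]
                     for qi in np.atleast_1d(q)])


def risk_quintile_strata(df: pd.DataFrame, by: str = "country") -> pd.DataFrame:
    """PHA-category composition within country-level weighted risk quintiles.

    Quintile cut points come from each country's weighted distribution of
    absolute 10-year risk; a value equal to a cut point falls in the lower
    quintile, so fully tied risks all land in Q1.
    """
    rows = []
    for country, sub in df.groupby(by, sort=True):
        cuts = weighted_quantile(sub["risk_10y"], sub["weight"],
                                 [0.2, 0.4, 0.6, 0.8])
        qidx = np.searchsorted(cuts, sub["risk_10y"].to_numpy(float),
                               side="left")
        sub = sub.copy()
        sub["risk_quintile"] = [f"Q{i + 1}" for i in qidx]
        for cat in GAP_CLASSES:
            ind = (sub["gap_class"] == cat).to_numpy(dtype=float)
            for row in _estimate_rows(sub.reset_index(drop=True), ind,
                                      ["risk_quintile"]):
                row[by] = country
                row["category"] = cat
                rows.append(row)
    out = pd.DataFrame(rows)
    return out[[by, "risk_quintile", "category", "proportion",
                "standard_error", "ci_lo", "ci_hi", "n_unweighted",
                "empty_domain"]]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    groups_used: tuple
    groups_excluded: tuple


def group_anova(values, groups) -> AnovaResult:
    """Classic one-way ANOVA on country-level prevalences across groups.

    Groups with fewer than 2 countries are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    used, excluded, samples = [], [], []
    for g in pd.unique(groups):
        vals = values[groups == g]
        if len(vals) >= 2:
            used.append(g)
            samples.append(vals)
        else:
            excluded.append(g)
    if excluded:
        warnings.warn(f"excluding groups with <2 countries: {excluded}",
                      stacklevel=2)
    if len(used) < 2:
        raise ValueError("one-way ANOVA needs >=2 groups with >=2 countries")
    k = len(samples)
    n_tot = sum(len(s) for s in samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n_tot - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = float(ms_b / ms_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f, p, df_b, df_w, tuple(used), tuple(excluded))


def sankey_flow_table(df: pd.DataFrame) -> pd.DataFrame:
    """Unweighted counts of chronological 5-year band x PHA band, by sex."""
    age_band = [pha_age_group(int(a)) for a in df["age"]]
    pha_band = [pha_age_group(c) for c in df["pha_coded"]]
    out = (pd.DataFrame({"sex": df["sex"].to_numpy(),
                         "age_band": age_band, "pha_band": pha_band})
           .value_counts(["sex", "age_band", "pha_band"])
           .rename("count").reset_index()
           .sort_values(["sex", "age_band", "pha_band"])
           .reset_index(drop=True))
    return out
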