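"""Mixed-effects logistic models for excess PHA and treatment eligibility.

Outcomes are modelled as Bernoulli with a logit link,

    logit P(y_ij = 1) = x_ij' beta + u_region(ij) + v_country(ij),

with independent Gaussian random intercepts for world region and for
country nested within region.  Survey weights are deliberately *not* used
(the design parameters are not consistently available across surveys, and
the models describe associations, not national totals) — the fitter has no
weight argument by construction.

Estimation is maximum likelihood under the Laplace approximation: for
fixed variance parameters the joint penalized log-likelihood is maximized
over (beta, b) by Newton iterations (penalized IRLS with step halving),
and the profiled Laplace criterion

    l(beta^, b^) - b^' D^-1 b^ / 2 - log det(I + Z'WZ D) / 2

is optimized over the two log standard deviations by L-BFGS-B.  This is
the same approximation lme4's glmer uses at nAGQ=1.  Wald standard errors
come from the fixed-effect block of the inverse joint penalized Hessian at
the optimum; fixed effects are reported as odds ratios with 95% CIs and
Wald z p values.  The fitter either converges (gradient and step tolerance
met) or reports an explicit non-convergence status; coefficients driven to
extreme magnitudes are flagged as probable complete separation.

Reference levels follow the descriptive tables: education 'none', normal
waist, normal cholesterol, marital 'single', work 'unemployed',
non-smoker, no diabetes.  Diabetes is excluded from the lipid-lowering
eligibility model because adults >=40 with diabetes are eligible by
definition (it is part of the outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: categorical fixed effects: column -> (reference level, modelled levels)
CATEGORICAL_TERMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "education4": ("none", ("primary", "secondary_high", "university")),
    "marital3": ("single", ("married_cohab", "div_sep_wid")),
    "work5": ("unemployed", ("employed_paid", "employed_unpaid",
                             "student", "homemaker")),
}
BINARY_TERMS = ("abdominal_obesity", "high_cholesterol", "smoker", "diabetes")

DEFAULT_FIXED_EFFECTS = ("education4", "abdominal_obesity", "high_cholesterol",
                         "marital3", "work5", "smoker", "diabetes")

_OUTCOME_COLUMNS = {"excess_pha": "excess", "elig_aht": "elig_aht",
                    "elig_llt": "elig_llt"}

_SEP_LOGODDS = 10.0  # |log-odds| beyond this flags probable separation

_LOG_SD_BOUNDS = (-7.0, 2.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome to model and with which fixed effects.

    ``elig_llt`` drops diabetes from the covariates (it defines part of the
    outcome); the constructor enforces this.
    """

    outcome: str
    fixed_effects: tuple[str, ...] = DEFAULT_FIXED_EFFECTS

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOME_COLUMNS:
            raise ValueError(f"outcome must be one of {sorted(_OUTCOME_COLUMNS)}")
        fe = tuple(self.fixed_effects)
        if self.outcome == "elig_llt" and "diabetes" in fe:
            fe = tuple(t for t in fe if t != "diabetes")
        object.__setattr__(self, "fixed_effects", fe)

    @property
    def outcome_column(self) -> str:
        return _OUTCOME_COLUMNS[self.outcome]


@dataclass
class GLMMResult:
    table: pd.DataFrame            # term, estimate, std_error, OR, CI, p, separation
    variance_region: float
    variance_country: float
    converged: bool
    n_obs: int
    n_regions: int
    n_countries: int
    log_likelihood: float
    spec: ModelSpec = field(repr=False, default=None)


def build_design(df: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Outcome vector and fixed-effects matrix with named columns."""
    ycol = spec.outcome_column
    y = df[ycol].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in spec.fixed_effects:
        if term in CATEGORICAL_TERMS:
            ref, levels = CATEGORICAL_TERMS[term]
            obs = set(df[term].dropna().unique()) - {ref}
            for lv in levels:
                if lv in obs:
                    cols.append((df[term] == lv).to_numpy(dtype=float))
                    names.append(f"{term}[{lv}]")
        else:
            cols.append(df[term].to_numpy(dtype=float))
            names.append(term)
    return y, np.column_stack(cols), names


def _penalized_newton(y, A, p, prior_prec, gamma0, max_iter=60, tol=1e-9):
    """Maximize the penalized Bernoulli log-likelihood over (beta, b).

    ``A`` stacks fixed and random-effect columns; ``prior_prec`` is the
    diagonal penalty (zeros on the fixed block).  Returns the mode, the
    penalized Hessian, the unpenalized log-likelihood at the mode and a
    convergence flag.
    """
    gamma = gamma0.copy()
    eta = A @ gamma

    def objective(eta_, gamma_):
        # log-lik with stable log(1+e^eta)
        ll = float(y @ eta_ - np.logaddexp(0.0, eta_).sum())
        return ll - 0.5 * float(gamma_ @ (prior_prec * gamma_))

    obj = objective(eta, gamma)
    converged = False
    H = None
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = A.T @ (y - mu) - prior_prec * gamma
        H = (A * w[:, None]).T @ A
        H[np.diag_indices_from(H)] += prior_prec
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = 1.0
        for _half in range(30):
            cand = gamma + step * delta
            eta_c = A @ cand
            obj_c = objective(eta_c, cand)
            if obj_c >= obj - 1e-12:
                break
            step *= 0.5
        gamma, eta, new_obj = cand, eta_c, obj_c
        if max(np.abs(grad).max(), np.abs(step * delta).max()) < tol or \
                abs(new_obj - obj) < 1e-12:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = (A * w[:, None]).T @ A
    H[np.diag_indices_from(H)] += prior_prec
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return gamma, H, ll, converged


def fit_glmm(df: pd.DataFrame, spec: ModelSpec,
             region_col: str = "region", country_col: str = "country"
             ) -> GLMMResult:
    """Fit the nested-random-intercepts logistic model for one outcome.

    Rows with missing covariates or outcome are excluded (regression-only
    complete case).  Eligibility outcomes are fitted among records with
    excess PHA, as the descriptive analysis defines them.
    """
    data = df
    if spec.outcome in ("elig_aht", "elig_llt"):
        if "excess" not in data.columns:
            raise ValueError("eligibility models need the 'excess' column")
        data = data[data["excess"].astype(bool)]
    need = [spec.outcome_column, region_col, country_col, *spec.fixed_effects]
    data = data.dropna(subset=[c for c in need if c in data.columns])
    missing = [c for c in need if c not in data.columns]
    if missing:
        raise ValueError(f"model requires columns {missing}")
    if len(data) == 0:
        raise ValueError("no complete-covariate rows to fit on")

    y, X, names = build_design(data, spec)
    if y.min() == y.max():
        raise ValueError(f"degenerate outcome: all values are {y[0]:g}")

    regions = pd.Categorical(data[region_col])
    countries = pd.Categorical(data[country_col])
    n, p = X.shape
    qr, qc = len(regions.categories), len(countries.categories)
    Zr = np.zeros((n, qr))
    Zr[np.arange(n), regions.codes] = 1.0
    Zc = np.zeros((n, qc))
    Zc[np.arange(n), countries.codes] = 1.0
    A = np.column_stack([X, Zr, Zc])

    state = {"gamma": np.zeros(p + qr + qc)}

    def neg_laplace(theta):
        var = np.exp(2.0 * theta)  # (sigma_r^2, sigma_c^2)
        prior_prec = np.concatenate([np.zeros(p),
                                     np.full(qr, 1.0 / var[0]),
                                     np.full(qc, 1.0 / var[1])])
        gamma, H, ll, _ = _penalized_newton(y, A, p, prior_prec, state["gamma"])
        state["gamma"] = gamma
        b = gamma[p:]
        pen = 0.5 * float(b @ (prior_prec[p:] * b))
        Hbb = H[p:, p:]
        sign, logdet_Hbb = np.linalg.slogdet(Hbb)
        # log det(I + Z'WZ D) = log det(Hbb) + log det(D)
        logdet = logdet_Hbb + float(np.sum(np.log(var[0]) * np.ones(qr))) \
            + float(np.sum(np.log(var[1]) * np.ones(qc)))
        return -(ll - pen - 0.5 * logdet)

    x0 = np.log([0.3, 0.3])
    res = optimize.minimize(neg_laplace, x0, method="L-BFGS-B",
                            bounds=[_LOG_SD_BOUNDS] * 2,
                            options={"maxiter": 60, "ftol": 1e-10})
    theta = res.x
    var = np.exp(2.0 * theta)
    prior_prec = np.concatenate([np.zeros(p), np.full(qr, 1.0 / var[0]),
                                 np.full(qc, 1.0 / var[1])])
    gamma, H, ll, inner_ok = _penalized_newton(y, A, p, prior_prec,
                                               state["gamma"])
    cov = np.linalg.inv(H)[:p, :p]
    beta = gamma[:p]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    sep = (np.abs(beta) > _SEP_LOGODDS) | (se > 50.0) | ~np.isfinite(se)
    with np.errstate(over="ignore"):  # separated terms overflow to inf CIs
        table = pd.DataFrame({
            "term": names,
            "estimate": beta,
            "std_error": se,
            "odds_ratio": np.exp(beta),
            "or_ci_lo": np.exp(beta - 1.959963984540054 * se),
            "or_ci_hi": np.exp(beta + 1.959963984540054 * se),
            "p_value": pval,
            "separation": sep,
        })
    return GLMMResult(table=table,
                      variance_region=float(var[0]),
                      variance_country=float(var[1]),
                      converged=bool(res.success and inner_ok),
                      n_obs=n, n_regions=qr, n_countries=qc,
                      log_likelihood=ll, spec=spec)


def or_table_csv(result: GLMMResult) -> pd.DataFrame:
    """Tidy OR table with variance-component rows appended (report layout)."""
    rows = result.table.copy()
    extra = pd.DataFrame({
        "term": ["var_country_in_region", "var_region"],
        "estimate": [result.variance_country, result.variance_region],
        "std_error": [np.nan, np.nan], "odds_ratio": [np.nan, np.nan],
        "or_ci_lo": [np.nan, np.nan], "or_ci_hi": [np.nan, np.nan],
        "p_value": [np.nan, np.nan], "separation": [False, False],
    })
    return pd.concat([rows, extra], ignore_index=True)
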