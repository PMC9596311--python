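"""End-to-end orchestration: simulate/load -> clean -> score -> heart age
-> eligibility -> summaries -> (optional) correlate models.

A run is fully described by a :class:`RunConfig`; re-running the same
config and seed reproduces byte-identical outputs, and the emitted
manifest records the config hash, seed, package version, per-stage row
counts and a checksum for every output file.  CSV is the interchange
format throughout; no stage mutates its input files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cleaning import clean_dataframe
from .correlates import ModelSpec, fit_glmm, or_table_csv
from .eligibility import eligibility_dataframe
from .inversion import heartage_dataframe
from .risk import LAB, NON_LAB, compare_lab_nonlab, load_coefficients, score_dataframe
from .simulate import PRESETS, preset, simulate_multi_country
from .survey import (category_prevalence_table, eligibility_among_excess,
                     group_anova, risk_quintile_strata, sankey_flow_table)


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Either ``countries`` (preset names to simulate, each at ``n_records``)
    or ``input_csv`` must be given.  ``variant`` selects the primary risk
    model; ``lab`` requires lipid columns.  ``with_models`` toggles the
    (slower) mixed-model stage; ``with_lab_sensitivity`` adds the paired
    lab-vs-non-lab comparison on records with HDL.
    """

    out_dir: str
    seed: int = 0
    countries: list[str] | None = None
    n_records: int | None = None
    input_csv: str | None = None
    column_map: dict = field(default_factory=dict)
    variant: str = NON_LAB
    ranges: dict | None = None
    error_rates: dict = field(default_factory=dict)
    missing_rates: dict = field(default_factory=dict)
    with_models: bool = False
    with_lab_sensitivity: bool = False

    def validate(self) -> None:
        if (self.countries is None) == (self.input_csv is None):
            raise ValueError("specify exactly one of countries / input_csv")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ValueError(f"input_csv {self.input_csv!r} does not exist")
        if self.variant not in (NON_LAB, LAB):
            raise ValueError(f"variant must be {NON_LAB!r} or {LAB!r}")
        if self.countries is not None:
            unknown = [c for c in self.countries if c not in PRESETS]
            if unknown:
                raise ValueError(f"unknown country presets: {unknown}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: RunConfig) -> str:
    """Hash of the analytic configuration (output location excluded)."""
    d = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, n_rows: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed after {n_rows} rows: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    files: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write(df, path)
        files[name] = _sha256(path)

    # --- input -----------------------------------------------------------
    if config.countries is not None:
        overrides = {}
        if config.n_records is not None:
            overrides["n_records"] = config.n_records
        params = [preset(c, **overrides,
                         error_rates=dict(config.error_rates),
                         missing_rates=dict(config.missing_rates))
                  for c in config.countries]
        raw, ledgers = simulate_multi_country(params, config.seed)
        emit("raw.csv", raw)
        corr = pd.concat([l.corruption for l in ledgers.values()],
                         ignore_index=True)
        emit("corruption_ledger.csv", corr)
    else:
        raw = pd.read_csv(config.input_csv)
    counts["raw"] = len(raw)

    # validate before any computation: lab variant needs lipids
    mapped_cols = {config.column_map.get(c, c) for c in raw.columns}
    if config.variant == LAB and not {"total_chol", "hdl"} <= mapped_cols:
        raise ValueError("variant=lab requires total_chol and hdl columns")

    # --- clean -----------------------------------------------------------
    clean, drop_ledger, report = clean_dataframe(raw, ranges=config.ranges,
                                                 column_map=config.column_map)
    if config.variant == LAB and clean["hdl"].isna().all():
        raise ValueError("variant=lab but no usable HDL values after cleaning")
    counts["clean"] = len(clean)
    emit("clean.csv", clean)
    emit("drop_ledger.csv", drop_ledger)
    emit("cleaning_report.csv", report)

    # --- score + heart age + eligibility ---------------------------------
    coeffs = load_coefficients()
    if config.variant == LAB:
        clean = clean[clean["hdl"].notna()].reset_index(drop=True)
    scored = score_dataframe(clean, coeffs, variant=config.variant)
    scored = heartage_dataframe(scored, coeffs, variant=config.variant)
    scored = eligibility_dataframe(scored)
    counts["scored"] = len(scored)
    emit("scored.csv", scored)

    # --- summaries -------------------------------------------------------
    cat = category_prevalence_table(scored)
    emit("category_prevalence.csv", cat)
    emit("eligibility_among_excess.csv", eligibility_among_excess(scored))
    emit("risk_quintiles.csv", risk_quintile_strata(scored))
    emit("sankey_flow.csv", sankey_flow_table(scored))
    counts["summary_domains"] = int(cat[["country", "sex"]].drop_duplicates().shape[0])

    # country-level very-high prevalence compared across regions / incomes
    vh = cat[cat["category"] == "very_high"]
    country_prev = (vh.groupby("country", as_index=False)
                    .agg(prevalence=("proportion", "mean")))
    meta = scored[["country", "region", "income"]].drop_duplicates("country")
    country_prev = country_prev.merge(meta, on="country", how="left")
    emit("country_very_high.csv", country_prev)
    anova_rows = []
    for grouping in ("region", "income"):
        labelled = country_prev.dropna(subset=[grouping])
        sizes = labelled[grouping].value_counts()
        if (sizes >= 2).sum() >= 2:
            res = group_anova(labelled["prevalence"], labelled[grouping])
            anova_rows.append({"grouping": grouping,
                               "f_statistic": res.f_statistic,
                               "p_value": res.p_value,
                               "df_between": res.df_between,
                               "df_within": res.df_within,
                               "groups_excluded": ";".join(map(str, res.groups_excluded))})
        else:
            anova_rows.append({"grouping": grouping, "f_statistic": float("nan"),
                               "p_value": float("nan"), "df_between": 0,
                               "df_within": 0,
                               "groups_excluded": "insufficient groups"})
    emit("anova.csv", pd.DataFrame(anova_rows))

    # --- lab vs non-lab sensitivity --------------------------------------
    if config.with_lab_sensitivity and config.variant == NON_LAB:
        sub = scored[scored["hdl"].notna()].reset_index(drop=True)
        if len(sub) >= 2:
            lab = score_dataframe(sub, coeffs, variant=LAB)
            lab = heartage_dataframe(lab, coeffs, variant=LAB, prefix="lab_")
            cmp_risk = compare_lab_nonlab(
                list(zip(lab["risk_10y"], sub["risk_10y"])))
            cmp_pha = compare_lab_nonlab(
                list(zip(lab["lab_pha_continuous"], sub["pha_continuous"])))
            sens = pd.DataFrame([
                {"quantity": "risk_10y", **dataclasses.asdict(cmp_risk)},
                {"quantity": "pha_continuous", **dataclasses.asdict(cmp_pha)},
            ])
            emit("lab_sensitivity.csv", sens)
            counts["lab_sensitivity_pairs"] = cmp_risk.n

    # --- correlate models -------------------------------------------------
    if config.with_models:
        for outcome, fname in (("excess_pha", "or_excess_pha.csv"),
                               ("elig_aht", "or_elig_aht.csv"),
                               ("elig_llt", "or_elig_llt.csv")):
            try:
                res = fit_glmm(scored, ModelSpec(outcome=outcome))
            except ValueError as exc:
                raise StageError(f"model:{outcome}", len(scored), exc) from exc
            emit(fname, or_table_csv(res))
            counts[f"model_{outcome}_n"] = res.n_obs

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "row_counts": counts,
        "outputs": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=str))
    return manifest
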