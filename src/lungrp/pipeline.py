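"""End-to-end cohort analysis and phantom demonstration.

``run_analysis`` consumes a cohort CSV (schema in :mod:`lungrp.synthetic_data`)
and emits the full comparison of the three normal-lung definitions:

* ``report_table1.csv`` — clinical covariates vs RP2, 2x2 odds ratios;
* ``report_table2.csv`` — paired mean differences of V5/V20/MLD between
  definitions with 95% CIs, plus the within-subject ANOVA per metric;
* ``report_table3.csv`` — median/range of each metric by RP2 status with
  Mann-Whitney p;
* ``report_table4.csv`` — univariate logistic ORs per unit of each metric;
* ``roc_comparison.csv`` — AUCs and DeLong paired comparisons across
  definitions;
* ``ntcp_fits.json`` / ``ntcp_curves.csv`` — Lyman fits per definition,
  iso-risk MLD cutoffs at the target complication probability, and the
  dose-response curves;
* ``run_log.txt`` / ``config_echo.json`` — a trace of every operation with its
  inputs, and the configuration actually used.

Everything is deterministic given the input table and configuration (no
timestamps in outputs), so re-running produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import dvh as dvh_mod
from . import ntcp as ntcp_mod
from . import roc as roc_mod
from . import stats as stats_mod
from .geometry import LungDefinition, StructureMask, normal_lung_mask
from .synthetic_data import COHORT_COLUMNS, PhantomConfig, generate_phantom

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "run_phantom_demo",
           "validate_cohort"]

DEFINITIONS = ["lungptv", "lungpgtv", "total"]
DEF_LABELS = {"lungptv": "Lung-PTV", "lungpgtv": "Lung-PGTV", "total": "Total Lung"}
METRICS = ["v5", "v20", "mld"]
#: ordered pairs: larger-volume definition minus smaller, per the reporting convention
PAIRS = [("lungpgtv", "lungptv"), ("total", "lungptv"), ("total", "lungpgtv")]


class AnalysisConfig(BaseModel):
    """Configuration of a cohort analysis run."""

    definitions: list[str] = Field(default_factory=lambda: list(DEFINITIONS), min_length=1)
    p_target: float = Field(0.20, gt=0.0, lt=1.0)
    dvh_bin_width_gy: float = Field(0.1, gt=0)
    curve_max_dose_gy: float = Field(30.0, gt=0)
    seed: int = 0


@dataclass
class AnalysisReport:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    roc_comparison: pd.DataFrame
    ntcp_fits: dict
    ntcp_curves: pd.DataFrame | None
    notices: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in [
            ("report_table1.csv", self.table1), ("report_table2.csv", self.table2),
            ("report_table3.csv", self.table3), ("report_table4.csv", self.table4),
            ("roc_comparison.csv", self.roc_comparison),
        ]:
            df.to_csv(outdir / name, index=False)
        (outdir / "ntcp_fits.json").write_text(json.dumps(self.ntcp_fits, indent=2, sort_keys=True))
        if self.ntcp_curves is not None:
            self.ntcp_curves.to_csv(outdir / "ntcp_curves.csv", index=False)
        (outdir / "run_log.txt").write_text("\n".join(self.log) + "\n")


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Return a list of schema violations ('' if none), with row/column detail."""
    problems = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
        return problems
    if len(df) == 0:
        problems.append("cohort is empty")
        return problems
    if not df["rp2"].isin([0, 1]).all():
        bad = df.index[~df["rp2"].isin([0, 1])].tolist()
        problems.append(f"column rp2: non-binary values at rows {bad}")
    for col in [c for c in COHORT_COLUMNS if c.startswith(("v5_", "v20_", "mld_"))]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0)].tolist()
        if bad:
            problems.append(f"column {col}: missing/negative values at rows {bad}")
    for defn in DEFINITIONS:
        bad = df.index[df[f"v20_{defn}"] > df[f"v5_{defn}"] + 1e-9].tolist()
        if bad:
            problems.append(f"definition {defn}: V20 > V5 at rows {bad}")
    return problems


def _covariate_splits(df: pd.DataFrame):
    """Yield (factor, level, exposed-indicator) comparisons for the covariate table.

    Continuous covariates are dichotomized at <= median vs > median;
    categorical ones compare each level against its reference category.
    """
    for col in ["age", "pgtv_volume_cm3", "ptv_volume_cm3", "pgtv_rx_gy", "ptv_rx_gy"]:
        med = df[col].median()
        yield col, f"> {med:g} (median)", (df[col] > med).to_numpy()
    yield "gender", "female vs male", (df["gender"] == "female").to_numpy()
    for level in ["current", "former"]:
        sub = df["smoking"].isin(["never", level])
        yield "smoking", f"{level} vs never", sub, (df["smoking"] == level)
    for level in ["adenocarcinoma", "small_cell", "other"]:
        sub = df["pathology"].isin(["squamous", level])
        yield "pathology", f"{level} vs squamous", sub, (df["pathology"] == level)
    for level in ["I/II", "IV"]:
        sub = df["stage"].isin(["III", level])
        yield "stage", f"{level} vs III", sub, (df["stage"] == level)
    yield "chemo", "yes vs no", (df["chemo"] == 1).to_numpy()
    yield "surgery", "yes vs no", (df["surgery"] == 1).to_numpy()


def _table1(df: pd.DataFrame, log: list[str]) -> pd.DataFrame:
    rows = []
    y = df["rp2"].to_numpy().astype(bool)
    for item in _covariate_splits(df):
        if len(item) == 4:  # categorical level vs reference on a row subset
            factor, level, subset, exposed = item
            mask = subset.to_numpy()
            tab = stats_mod.TwoByTwoTable.from_arrays(exposed.to_numpy()[mask], y[mask])
        else:
            factor, level, exposed = item
            tab = stats_mod.TwoByTwoTable.from_arrays(exposed, y)
        res = stats_mod.odds_ratio(tab)
        log.append(f"odds_ratio factor={factor} level={level} "
                   f"table=({tab.a},{tab.b},{tab.c},{tab.d})")
        rows.append({
            "factor": factor, "level": level,
            "n_exposed": tab.a + tab.b, "events_exposed": tab.a,
            "odds_ratio": res.odds_ratio, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value, "estimable": res.estimable,
        })
    return pd.DataFrame(rows)


def _table2(df: pd.DataFrame, log: list[str]) -> pd.DataFrame:
    rows = []
    for metric in METRICS:
        cols = df[[f"{metric}_{d}" for d in DEFINITIONS]].to_numpy()
        try:
            anova = stats_mod.repeated_measures_anova(cols)
            anova_p, anova_f = anova.p_value, anova.f
        except ValueError as exc:
            anova_p = anova_f = float("nan")
            log.append(f"repeated_measures_anova metric={metric} failed: {exc}")
        else:
            log.append(f"repeated_measures_anova metric={metric} F={anova.f:.4g}")
        for hi, lo in PAIRS:
            cmp = stats_mod.paired_mean_difference(df[f"{metric}_{hi}"], df[f"{metric}_{lo}"])
            log.append(f"paired_mean_difference metric={metric} pair={hi}-{lo}")
            rows.append({
                "metric": metric,
                "comparison": f"{DEF_LABELS[lo]} vs. {DEF_LABELS[hi]}",
                "mean_difference": cmp.mean_difference,
                "ci_low": cmp.ci_low, "ci_high": cmp.ci_high,
                "p_paired": cmp.p_value, "anova_f": anova_f, "anova_p": anova_p,
                "degenerate": cmp.degenerate,
            })
    return pd.DataFrame(rows)


def _table3(df: pd.DataFrame, log: list[str]) -> pd.DataFrame:
    rows = []
    y = df["rp2"].to_numpy().astype(bool)
    two_class = 0 < y.sum() < y.size
    for defn in DEFINITIONS:
        for metric in METRICS:
            vals = df[f"{metric}_{defn}"].to_numpy(dtype=float)
            ev, nev = vals[y], vals[~y]
            if two_class:
                mwu = stats_mod.mann_whitney_u(ev, nev)
                p, method = mwu.p_value, mwu.method
                log.append(f"mann_whitney_u metric={metric} defn={defn} U={mwu.u}")
            else:
                p, method = float("nan"), "unavailable"
            rows.append({
                "definition": DEF_LABELS[defn], "metric": metric,
                "median_non_rp2": float(np.median(nev)) if nev.size else float("nan"),
                "range_non_rp2": f"{nev.min():.1f}-{nev.max():.1f}" if nev.size else "",
                "median_rp2": float(np.median(ev)) if ev.size else float("nan"),
                "range_rp2": f"{ev.min():.1f}-{ev.max():.1f}" if ev.size else "",
                "p_mann_whitney": p, "method": method,
            })
    return pd.DataFrame(rows)


def _table4(df: pd.DataFrame, log: list[str], notices: list[str]) -> pd.DataFrame:
    rows = []
    y = df["rp2"].to_numpy(dtype=float)
    for defn in DEFINITIONS:
        for metric in METRICS:
            try:
                fit = stats_mod.logistic_fit_univariate(df[f"{metric}_{defn}"].to_numpy(float), y)
            except ValueError as exc:
                notices.append(f"logistic {metric}_{defn}: {exc}")
                fit = None
            log.append(f"logistic_fit_univariate metric={metric} defn={defn}")
            rows.append({
                "definition": DEF_LABELS[defn], "metric": metric,
                "odds_ratio": fit.or_per_unit if fit else float("nan"),
                "ci_low": fit.ci_low if fit else float("nan"),
                "ci_high": fit.ci_high if fit else float("nan"),
                "p_value": fit.p_wald if fit else float("nan"),
                "converged": bool(fit and fit.converged),
            })
    return pd.DataFrame(rows)


def _roc_table(df: pd.DataFrame, log: list[str]) -> pd.DataFrame:
    rows = []
    y = df["rp2"].to_numpy().astype(int)
    for metric in METRICS:
        aucs = {}
        for defn in DEFINITIONS:
            res = roc_mod.auc_mann_whitney(df[f"{metric}_{defn}"].to_numpy(float), y)
            aucs[defn] = res.auc
            log.append(f"auc_mann_whitney metric={metric} defn={defn} auc={res.auc:.4f}")
        for d1, d2 in [("lungptv", "lungpgtv"), ("lungptv", "total"), ("lungpgtv", "total")]:
            t = roc_mod.delong_paired_test(
                df[f"{metric}_{d1}"].to_numpy(float), df[f"{metric}_{d2}"].to_numpy(float), y)
            log.append(f"delong_paired_test metric={metric} pair={d1}-{d2} p={t.p_value:.4g}")
            rows.append({
                "metric": metric,
                "definition_1": DEF_LABELS[d1], "definition_2": DEF_LABELS[d2],
                "auc_1": t.auc1, "auc_2": t.auc2, "auc_difference": t.difference,
                "z": t.z, "p_delong": t.p_value,
            })
    return pd.DataFrame(rows)


def _ntcp_section(df: pd.DataFrame, cfg: AnalysisConfig, log: list[str]):
    y = df["rp2"].to_numpy(dtype=float)
    fits, params = {}, {}
    for defn in DEFINITIONS:
        fit = ntcp_mod.fit_lyman_mle(df[f"mld_{defn}"].to_numpy(float), y)
        cutoff = ntcp_mod.cutoff_dose(fit.params, cfg.p_target)
        fits[defn] = {**fit.to_dict(), f"cutoff_mld_gy_at_{cfg.p_target:g}": cutoff}
        params[defn] = fit.params
        log.append(f"fit_lyman_mle defn={defn} td50={fit.params.td50:.3f} m={fit.params.m:.4f} "
                   f"cutoff({cfg.p_target:g})={cutoff:.2f}")
    doses = np.round(np.arange(0.0, cfg.curve_max_dose_gy + 1e-9, 0.1), 1)
    curves = ntcp_mod.compare_definitions_ntcp(params, doses)
    # probability table at the per-definition cutoffs (the clinically used rows)
    cutpoints = sorted({round(f[f"cutoff_mld_gy_at_{cfg.p_target:g}"], 1) for f in fits.values()})
    cutpoints = [d for d in cutpoints if d >= 0]
    at_cutoffs = ntcp_mod.compare_definitions_ntcp(params, cutpoints) if cutpoints else None
    return fits, curves, at_cutoffs


def run_analysis(cohort: pd.DataFrame | str | Path, config: AnalysisConfig | None = None,
                 outdir: str | Path | None = None) -> AnalysisReport:
    """Full definition-comparison analysis of one cohort table.

    ``cohort`` is a DataFrame or a path to a CSV in the cohort schema.  With a
    single-class outcome the inferential tables are downgraded to descriptives
    with an explicit notice rather than failing.  When ``outdir`` is given all
    report files are written there.
    """
    cfg = config or AnalysisConfig()
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    problems = validate_cohort(cohort)
    if problems:
        raise ValueError("cohort schema violations:\n  " + "\n  ".join(problems))

    log = [f"config {cfg.model_dump_json()}",
           f"cohort n={len(cohort)} events={int(cohort['rp2'].sum())} "
           f"incidence={100.0 * cohort['rp2'].mean():.1f}%"]
    notices: list[str] = []
    n_events = int(cohort["rp2"].sum())
    two_class = 0 < n_events < len(cohort)
    if not two_class:
        notices.append("single-class outcome: inferential tables downgraded to descriptives")
    if two_class and (n_events < 5 or len(cohort) - n_events < 5):
        notices.append("fewer than 5 events or non-events: inferential results unstable")

    if two_class:
        table1 = _table1(cohort, log)
    else:
        table1 = pd.DataFrame(columns=["factor", "level", "n_exposed", "events_exposed",
                                       "odds_ratio", "ci_low", "ci_high", "p_value", "estimable"])
    table2 = _table2(cohort, log)
    table3 = _table3(cohort, log)
    if two_class:
        table4 = _table4(cohort, log, notices)
        roc_table = _roc_table(cohort, log)
        try:
            fits, curves, at_cutoffs = _ntcp_section(cohort, cfg, log)
        except ValueError as exc:
            notices.append(f"ntcp fitting unavailable: {exc}")
            fits, curves, at_cutoffs = {}, None, None
    else:
        table4 = pd.DataFrame(columns=["definition", "metric", "odds_ratio", "ci_low",
                                       "ci_high", "p_value", "converged"])
        roc_table = pd.DataFrame(columns=["metric", "definition_1", "definition_2",
                                          "auc_1", "auc_2", "auc_difference", "z", "p_delong"])
        fits, curves, at_cutoffs = {}, None, None

    ntcp_fits = {"p_target": cfg.p_target, "fits": fits}
    if at_cutoffs is not None:
        ntcp_fits["at_cutoffs"] = at_cutoffs.to_dict(orient="records")
    for notice in notices:
        log.append(f"NOTICE {notice}")

    report = AnalysisReport(table1, table2, table3, table4, roc_table,
                            ntcp_fits, curves, notices, log)
    if outdir is not None:
        report.write(outdir)
        cfg_echo = {"analysis": cfg.model_dump(), "n_patients": len(cohort),
                    "n_events": n_events}
        (Path(outdir) / "config_echo.json").write_text(json.dumps(cfg_echo, indent=2, sort_keys=True))
    return report


def run_phantom_demo(config: PhantomConfig | None = None, seed: int = 0,
                     outdir: str | Path | None = None,
                     bin_width_gy: float = 0.1) -> dict[str, dvh_mod.DoseMetrics]:
    """Generate the phantom and report V5/V20/MLD under all three definitions.

    Demonstrates the ordering Lung-PTV <= Lung-PGTV <= Total Lung on every
    metric; optionally writes one cumulative-DVH CSV per definition.
    """
    dose, masks = generate_phantom(config, seed=seed)
    lungs = masks["LUNGS"]
    defn_masks = {
        LungDefinition.TOTAL_LUNG: normal_lung_mask(lungs, LungDefinition.TOTAL_LUNG),
        LungDefinition.LUNG_MINUS_PGTV: normal_lung_mask(
            lungs, LungDefinition.LUNG_MINUS_PGTV, masks["PGTV"]),
        LungDefinition.LUNG_MINUS_PTV: normal_lung_mask(
            lungs, LungDefinition.LUNG_MINUS_PTV, masks["PTV"]),
    }
    metrics = {}
    for defn, mask in defn_masks.items():
        metrics[defn.value] = dvh_mod.compute_metrics(dose, mask, defn)
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            dvh_mod.compute_dvh(dose, mask, bin_width_gy).to_csv(
                Path(outdir) / f"dvh_{defn.value}.csv")
    return metrics
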