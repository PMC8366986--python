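"""End-to-end study pipeline: fixtures → metrics → index screen →
Youden cut-off → adjusted logistic model → machine-readable report.

Stage order mirrors the screening study design: descriptive group
comparison of the cohort covariates, per-index discrimination screen
(group comparison + ROC/AUC over all sway indexes), optimal cut-off for
the top index, then a multiple logistic model for the endpoint adjusted
for sex, age and BMI.  Every stage is a pure function of (inputs,
config, seed); the JSON report is schema-versioned.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, cop_metrics, risk_model, roc_analysis, synthetic_cohort

__all__ = ["PipelineConfig", "StudyReport", "screen_indexes", "run_pipeline",
           "write_report", "read_report"]

logger = logging.getLogger("copstab")

REPORT_SCHEMA_VERSION = 1
REPORT_REQUIRED_KEYS = ("schema_version", "seed", "n_subjects", "table1",
                        "screen", "cutoff", "model")

StudyReport = dict


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full pipeline run.

    ``input_dir`` points at a study directory (cohort.csv plus
    ``<subject>_<OE|CE>.csv`` recordings); when None a synthetic study is
    generated from ``generator``.  All analysis thresholds live here.
    """

    input_dir: str | Path | None = None
    generator: synthetic_cohort.GeneratorConfig = field(
        default_factory=synthetic_cohort.GeneratorConfig)
    duration: float = cop_metrics.NOMINAL_DURATION
    use_ce: bool = True  # eyes-closed condition computed only when present
    spectral: cop_metrics.SpectralConfig = field(default_factory=cop_metrics.SpectralConfig)
    screening_test: str = "auto"
    cutoff_method: str = "youden"
    covariates: tuple[str, ...] = ("sex_woman", "age", "bmi")
    hl_groups: int = 10
    output_dir: str | Path | None = None
    seed: int = 0


def _load_study(cfg: PipelineConfig) -> tuple[pd.DataFrame, dict[str, dict[str, cop_metrics.CoPRecording]]]:
    if cfg.input_dir is None:
        gen = replace(cfg.generator, seed=cfg.seed)
        logger.info("generating synthetic study: n=%d, seed=%d", gen.n_subjects, cfg.seed)
        return synthetic_cohort.generate_study(gen, duration=cfg.duration,
                                               write_ce=cfg.use_ce)
    input_dir = Path(cfg.input_dir)
    cohort = pd.read_csv(input_dir / "cohort.csv")
    recordings: dict[str, dict[str, cop_metrics.CoPRecording]] = {}
    for sid in cohort["subject_id"]:
        recs = {}
        for cond in cop_metrics.CONDITIONS:
            f = input_dir / f"{sid}_{cond}.csv"
            if f.exists():
                recs[cond] = cop_metrics.read_recording_csv(f)
        if not recs:
            logger.info("excluding %s: no recordings found", sid)
            continue
        recordings[sid] = recs
    n_excluded = len(cohort) - len(recordings)
    if n_excluded:
        logger.info("excluded %d subjects without recordings", n_excluded)
        cohort = cohort[cohort["subject_id"].isin(recordings)].reset_index(drop=True)
    return cohort, recordings


def compute_metric_table(recordings: dict[str, dict[str, cop_metrics.CoPRecording]],
                         spectral: cop_metrics.SpectralConfig | None = None) -> pd.DataFrame:
    """Wide per-subject metric table (one suffixed index per column)."""
    per_subject = {
        sid: cop_metrics.compute_all_metrics(recs.get("OE"), recs.get("CE"), spectral)
        for sid, recs in recordings.items()
    }
    return cop_metrics.metrics_to_wide(per_subject)


def screen_indexes(metrics: pd.DataFrame, endpoint: pd.Series,
                   test: str = "auto", multiplicity: str = "none") -> pd.DataFrame:
    """Per-index screening report, sorted by AUC descending.

    Columns: index, per-group mean ± SD, test, p_value, auc, auc CI.
    Indexes that are missing or constant for every subject are skipped.
    Raw p-values are the default; ``multiplicity="bh"`` adds a
    Benjamini–Hochberg ``p_adjusted`` column as an explicit extension
    (no adjustment is applied to anything downstream).
    """
    endpoint = endpoint.astype(bool)
    y = endpoint.to_numpy().astype(int)
    rows = []
    for name in metrics.columns:
        col = metrics[name]
        if col.isna().any() or col.nunique() <= 1:
            continue
        gc = cohort_stats.compare_groups(col, endpoint, test=test, name=name)
        with warnings.catch_warnings():
            # the screen scans every index; sub-0.5 AUCs are expected here
            warnings.simplefilter("ignore", UserWarning)
            roc = roc_analysis.roc_curve(col.to_numpy(), y)
            lo, hi = roc_analysis.auc_ci(col.to_numpy(), y)
        rows.append({"index": name, "no_alteration": gc.group0,
                     "alteration": gc.group1, "test": gc.test,
                     "p_value": gc.p_value, "auc": roc.auc,
                     "auc_ci_low": lo, "auc_ci_high": hi})
    out = pd.DataFrame(rows)
    if multiplicity == "bh":
        from statsmodels.stats.multitest import multipletests
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    elif multiplicity != "none":
        raise ValueError(f"unknown multiplicity option {multiplicity!r}")
    # AUC descending; exact ties (e.g. an index and its fixed-duration
    # rescaling) resolved alphabetically for determinism
    return out.sort_values(["auc", "index"],
                           ascending=[False, True]).reset_index(drop=True)


def run_pipeline(cfg: PipelineConfig) -> StudyReport:
    """Run every stage and return the study report (also written to
    ``cfg.output_dir`` when set, together with the per-stage CSVs)."""
    out_dir = Path(cfg.output_dir) if cfg.output_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        cohort, recordings = _load_study(cfg)
        endpoint = cohort.set_index("subject_id")["balance_alteration"].astype(bool)

        stage = "metrics"
        metrics = compute_metric_table(recordings, cfg.spectral).loc[endpoint.index]
        if out_dir is not None:
            metrics.to_csv(out_dir / "metrics_wide.csv")

        stage = "table1"
        t1 = cohort_stats.table_one(
            cohort.drop(columns=list(synthetic_cohort.VELOCITY_COLUMNS),
                        errors="ignore"))
        if out_dir is not None:
            t1.to_csv(out_dir / "table1.csv", index=False)

        stage = "screen"
        screen = screen_indexes(metrics, endpoint, test=cfg.screening_test)
        if out_dir is not None:
            screen.to_csv(out_dir / "screen.csv", index=False)

        stage = "cutoff"
        best = str(screen.iloc[0]["index"])
        scores = metrics[best].to_numpy()
        y = endpoint.to_numpy().astype(int)
        roc = roc_analysis.roc_curve(scores, y)
        cut = roc_analysis.youden_cutoff(roc, scores, y)

        stage = "model"
        dic = roc_analysis.dichotomize(scores, cut.cutoff).astype(float)
        design = pd.DataFrame({"mvelap_dic": dic}, index=endpoint.index)
        cov_source = cohort.set_index("subject_id")
        for cov in cfg.covariates:
            if cov == "sex_woman":
                design[cov] = (cov_source["sex"] == "woman").astype(float)
            else:
                design[cov] = cov_source[cov].astype(float)
        fit = risk_model.fit_logistic(design, endpoint.to_numpy())
        hl_chi2, hl_df, hl_p = risk_model.hosmer_lemeshow(
            fit.fitted, fit.endpoint, g=cfg.hl_groups)
        mroc = risk_model.model_auc(fit)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    report: StudyReport = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "n_subjects": int(len(cohort)),
        "table1": t1.to_dict(orient="records"),
        "screen": screen.head(10).to_dict(orient="records"),
        "cutoff": {
            "index": best, "cutoff": cut.cutoff, "youden_j": cut.youden_j,
            "tp": cut.tp, "fp": cut.fp, "tn": cut.tn, "fn": cut.fn,
            "sensitivity": cut.sensitivity, "specificity": cut.specificity,
            "ppv": cut.ppv, "npv": cut.npv,
            "index_auc": float(screen.iloc[0]["auc"]),
        },
        "model": {
            "covariates": list(fit.names),
            "beta": fit.beta.tolist(),
            "se": fit.se.tolist(),
            "p_values": fit.p_values.tolist(),
            "odds_ratios": fit.odds_ratios.tolist(),
            "or_ci_low": fit.or_ci_low.tolist(),
            "or_ci_high": fit.or_ci_high.tolist(),
            "n_used": fit.n_used,
            "hosmer_lemeshow": {"chi2": hl_chi2, "df": hl_df, "p": hl_p},
            "auc": mroc.auc,
        },
    }
    if out_dir is not None:
        write_report(report, out_dir / "report.json")
    return report


def _validate_report(report: StudyReport) -> None:
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"invalid study report: missing keys {missing}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema {report['schema_version']}")


def write_report(report: StudyReport, path: str | Path) -> None:
    _validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> StudyReport:
    report = json.loads(Path(path).read_text())
    _validate_report(report)
    return report
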