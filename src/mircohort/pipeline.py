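"""End-to-end orchestration: config -> tables, figures and a run report.

Stage order: acquire (parse or simulate) -> clinical derivation ->
detection filter -> global-mean normalization -> relative quantification
-> two- and three-group differential statistics -> clinical/miRNA partial
correlations -> MetS ROC panel.  Every emitted table carries the config
hash and seed in a leading comment line, so identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import clinical as clin
from . import panel as pnl
from . import qpcr
from . import stats as cst
from .config import PipelineConfig, config_hash
from .simulate import generate_cohort

logger = logging.getLogger(__name__)

CORRELATION_VARIABLES = [
    "total_t", "free_t", "shbg", "dheas", "androstenedione",
    "fasting_glucose", "fasting_insulin", "homa_ir",
    "hdl", "triglycerides",
]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    config: dict
    stage_counts: dict = field(default_factory=dict)
    tables: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "config": self.config,
                    "stage_counts": self.stage_counts,
                    "tables": self.tables,
                    "warnings": self.warnings,
                },
                fh,
                indent=1,
                default=str,
            )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_table(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    header = f"# mircohort config_hash={report.config_hash} seed={report.seed}\n"
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", na_rep="NA")
    report.tables.append(str(path))


def _differential_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "assay_id": r.assay_id,
            "test": r.test,
            "fold_change": r.fold_change,
            "p_value": r.p_value,
            "separation": r.separation,
            "notes": ";".join(r.notes),
        }
        if isinstance(r.adjusted_or, dict):
            for g, v in r.adjusted_or.items():
                row[f"or_{g}"] = v
                lo, hi = r.or_ci[g]
                row[f"or_{g}_ci_low"], row[f"or_{g}_ci_high"] = lo, hi
                row[f"or_{g}_p"] = r.or_p[g]
        elif r.adjusted_or is not None:
            row["adjusted_or"] = r.adjusted_or
            row["or_ci_low"], row["or_ci_high"] = r.or_ci
            row["or_p"] = r.or_p
        if r.tukey_p:
            for (g1, g2), p in r.tukey_p.items():
                row[f"tukey_{g1}_vs_{g2}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("assay_id")


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis; returns the run report (also written)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config_hash(cfg), seed=cfg.seed, config=cfg.echo())
    rng = np.random.default_rng(cfg.seed)

    # -- acquire ------------------------------------------------------------
    stage = "acquire"
    try:
        if cfg.synthetic is not None:
            matrix, clinical_raw, truth = generate_cohort(cfg.cohort_config())
            truth.to_json(outdir / "ground_truth.json")
        else:
            matrix = qpcr.parse_ct_table(
                cfg.input["ct_table"],
                dialect=cfg.input.get("dialect", "long"),
                detection_limit=cfg.preprocess["detection_limit"],
            )
            clinical_raw = pd.read_csv(
                cfg.input["clinical_table"], sep="\t", index_col="subject_id", comment="#"
            )
        report.stage_counts[stage] = {
            "assays": matrix.n_assays, "samples": matrix.n_samples,
            "subjects": len(clinical_raw),
        }
        logger.info("acquire: %d assays x %d samples", matrix.n_assays, matrix.n_samples)
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise PipelineError(stage, exc) from exc

    # -- clinical derivation ------------------------------------------------
    stage = "clinical"
    try:
        clinical = clin.derive_clinical_table(clinical_raw)
        _write_table(clinical, outdir / "clinical_derived.tsv", report)
        strata = clinical["androgen_stratum"]
        mets_counts = {
            s: f"{int(clinical.loc[strata == s, 'mets'].sum())}"
            f"/{int((strata == s).sum())}"
            for s in strata.unique()
        }
        report.stage_counts[stage] = {
            "subjects": len(clinical),
            "strata": strata.value_counts().to_dict(),
            "mets_by_stratum": mets_counts,
        }
        logger.info("clinical: strata %s, MetS %s",
                    report.stage_counts[stage]["strata"], mets_counts)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- detection filter ---------------------------------------------------
    stage = "filter"
    try:
        filtered, det_report = qpcr.detection_filter(
            matrix,
            min_samples=cfg.preprocess["min_samples"],
            min_fraction=cfg.preprocess["min_fraction"],
        )
        assert det_report.n_retained + det_report.n_removed == det_report.n_input
        _write_table(
            pd.DataFrame(
                {"detected_in": det_report.detected_counts,
                 "retained": det_report.detected_counts.index.isin(det_report.retained)}
            ).rename_axis("assay_id"),
            outdir / "detection_report.tsv",
            report,
        )
        report.stage_counts[stage] = {
            "input": det_report.n_input,
            "retained": det_report.n_retained,
            "removed": det_report.n_removed,
            "threshold": det_report.threshold,
            "pct_retained": det_report.pct_retained,
        }
        logger.info("filter: in=%d retained=%d removed=%d",
                    det_report.n_input, det_report.n_retained, det_report.n_removed)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- normalize / quantify ----------------------------------------------
    stage = "normalize"
    try:
        nm = qpcr.global_mean_normalize(filtered, mean_basis=cfg.preprocess["mean_basis"])
        control_samples = list(clinical.index[clinical["group"] == "control"])
        control_samples = [s for s in control_samples if s in nm.sample_ids]
        em = qpcr.relative_quantity(nm, control_samples)
        _write_table(nm.dct.rename_axis("assay_id"), outdir / "dct_matrix.tsv", report)
        report.stage_counts[stage] = {
            "assays": len(nm.assay_ids), "samples": len(nm.sample_ids),
            "reference_samples": len(control_samples),
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    alpha = cfg.stats["alpha"]
    covariate_names = cfg.stats["adjust_covariates"]
    covariates = clinical[covariate_names] if covariate_names else None

    # -- two-group differential --------------------------------------------
    stage = "differential_2group"
    try:
        labels2 = clinical["group"].map({"pcos": "case", "control": "control"})
        res2 = cst.two_group_differential(
            em, labels2, covariates=covariates,
            equal_var=cfg.stats["equal_var"], fdr=cfg.stats["fdr"],
        )
        frame2 = _differential_frame(res2)
        _write_table(frame2, outdir / "differential_pcos_vs_control.tsv", report)
        volcano = cst.volcano_table(res2, alpha=alpha)
        _write_table(volcano, outdir / "volcano.tsv", report)
        _volcano_plot(volcano, alpha, outdir / "volcano.png")
        report.stage_counts[stage] = {
            "assays_tested": len(res2),
            "significant": int(volcano["significant"].sum()),
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- three-group differential ------------------------------------------
    stage = "differential_3group"
    try:
        res3 = cst.three_group_differential(
            em, strata, covariates=covariates, baseline="control", fdr=cfg.stats["fdr"],
        )
        frame3 = _differential_frame(res3)
        _write_table(frame3, outdir / "differential_three_group.tsv", report)
        report.stage_counts[stage] = {
            "assays_tested": len(res3),
            "significant": int((frame3["p_value"] < alpha).sum()),
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- correlations -------------------------------------------------------
    stage = "correlations"
    try:
        sig = frame2.index[frame2["p_value"] < alpha]
        corr_targets = list(sig[:20]) if len(sig) else list(frame2.index[:10])
        log2rq = em.log2()
        rows = []
        for var in CORRELATION_VARIABLES:
            if var not in clinical.columns:
                continue
            for aid in corr_targets:
                x = clinical[var]
                y = log2rq.loc[aid].reindex(clinical.index)
                try:
                    cr = cst.partial_correlation(
                        x.rename(var), y.rename(aid), covariates=covariates,
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "variable": var, "assay_id": aid, "n": cr.n,
                        "r": cr.r, "p": cr.p,
                        "r_adjusted": cr.r_adjusted, "p_adjusted": cr.p_adjusted,
                    }
                )
        corr_frame = pd.DataFrame(rows).set_index(["variable", "assay_id"])
        _write_table(corr_frame, outdir / "correlations.tsv", report)
        report.stage_counts[stage] = {"pairs": len(corr_frame)}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- panel --------------------------------------------------------------
    stage = "panel"
    try:
        panel_report = _panel_stage(cfg, em, clinical, outdir, report, rng)
        report.stage_counts[stage] = panel_report
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    report.to_json(outdir / "run_report.json")
    return report


def _panel_stage(cfg, em, clinical, outdir: Path, report: RunReport, rng) -> dict:
    within = cfg.panel["within_group"]
    outcome_col = cfg.panel["outcome"]
    subjects = clinical.index if within in (None, "all") else clinical.index[clinical["group"] == within]
    subjects = [s for s in subjects if s in em.sample_ids]
    outcome = clinical.loc[subjects, outcome_col].astype(float)

    if outcome.nunique() < 2:
        report.warnings.append(
            f"panel skipped: outcome {outcome_col!r} has one class within {within!r}"
        )
        return {"skipped": True}

    sub_em = qpcr.ExpressionMatrix(
        rq=em.rq[subjects], reference_samples=em.reference_samples
    )

    markers = cfg.panel["markers"]
    if not markers:
        # rank candidates by single-marker AUC, take the top 3
        aucs = {}
        for aid in sub_em.assay_ids:
            scores = np.log2(sub_em.rq.loc[aid]).to_numpy(dtype=float)
            if np.isnan(scores).all() or pd.Series(scores).nunique() < 2:
                continue
            ok = ~np.isnan(scores)
            if outcome[ok].nunique() < 2:
                continue
            auc = pnl._auc_mann_whitney(scores[ok], outcome.to_numpy()[ok].astype(int))
            aucs[aid] = max(auc, 1 - auc)
        markers = [a for a, _ in sorted(aucs.items(), key=lambda kv: -kv[1])[:3]]

    model = pnl.fit_panel(sub_em, markers, outcome)
    roc_rows = []
    for aid in markers:
        scores = np.log2(sub_em.rq.loc[aid, model.scores.index])
        roc = pnl.roc_curve(scores, outcome[model.scores.index], ci=cfg.panel["ci"])
        roc_rows.append({"marker": aid, "auc": roc.auc,
                         "ci_low": roc.auc_ci[0], "ci_high": roc.auc_ci[1]})
    panel_roc = pnl.roc_curve(model.scores, outcome[model.scores.index], ci=cfg.panel["ci"])
    roc_rows.append({"marker": "panel", "auc": panel_roc.auc,
                     "ci_low": panel_roc.auc_ci[0], "ci_high": panel_roc.auc_ci[1]})
    op = pnl.operating_point(panel_roc, rule="youden")

    if cfg.panel["cv"] == "loo":
        cv_scores = pnl.loo_scores(sub_em, markers, outcome)
        ok = cv_scores.dropna().index
        if outcome[ok].nunique() == 2:
            cv_roc = pnl.roc_curve(cv_scores[ok], outcome[ok], ci=cfg.panel["ci"])
            roc_rows.append({"marker": "panel_loo", "auc": cv_roc.auc,
                             "ci_low": cv_roc.auc_ci[0], "ci_high": cv_roc.auc_ci[1]})

    free_t_delong = None
    if "free_t" in clinical.columns:
        ft = clinical.loc[model.scores.index, "free_t"]
        ft_roc = pnl.roc_curve(ft, outcome[model.scores.index], ci=cfg.panel["ci"])
        roc_rows.append({"marker": "free_t", "auc": ft_roc.auc,
                         "ci_low": ft_roc.auc_ci[0], "ci_high": ft_roc.auc_ci[1]})
        diff, p = pnl.delong_test(model.scores, ft, outcome[model.scores.index])
        free_t_delong = {"auc_difference_panel_minus_free_t": diff, "p": p}

    auc_frame = pd.DataFrame(roc_rows).set_index("marker")
    _write_table(auc_frame, outdir / "panel_auc.tsv", report)
    _write_table(panel_roc.to_frame().set_index("threshold"),
                 outdir / "panel_roc_coords.tsv", report)
    _roc_plot(panel_roc, outdir / "panel_roc.png")
    with open(outdir / "panel_model.json", "wt", encoding="utf-8") as fh:
        json.dump(
            {
                "markers": model.marker_ids,
                "coefficients": list(map(float, model.coefficients)),
                "intercept": model.intercept,
                "converged": model.converged,
                "separation": model.separation,
                "seed": report.seed,
                "config_hash": report.config_hash,
                "operating_point": {
                    "rule": op.rule, "threshold": op.threshold,
                    "sensitivity": op.sensitivity, "specificity": op.specificity,
                    "tp": op.tp, "fp": op.fp, "tn": op.tn, "fn": op.fn,
                },
                "free_t_comparison": free_t_delong,
            },
            fh,
            indent=1,
        )
    if model.separation:
        report.warnings.append("panel logistic fit separated; scores remain rank-valid")
    return {
        "markers": markers,
        "n_subjects": len(model.scores),
        "n_cases": int(outcome[model.scores.index].sum()),
        "panel_auc": panel_roc.auc,
    }


def _volcano_plot(volcano: pd.DataFrame, alpha: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano["significant"]
    finite = volcano.replace([np.inf, -np.inf], np.nan).dropna()
    ax.scatter(finite.loc[~sig.reindex(finite.index, fill_value=False), "log2_fold_change"],
               finite.loc[~sig.reindex(finite.index, fill_value=False), "neg_log10_p"],
               s=8, c="grey", alpha=0.6)
    ax.scatter(finite.loc[sig.reindex(finite.index, fill_value=False), "log2_fold_change"],
               finite.loc[sig.reindex(finite.index, fill_value=False), "neg_log10_p"],
               s=10, facecolors="none", edgecolors="crimson")
    ax.axhline(-np.log10(alpha), ls=":", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _roc_plot(roc, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 4))
    fpr = np.concatenate([[1.0], 1.0 - roc.specificity, [0.0]])
    tpr = np.concatenate([[1.0], roc.sensitivity, [0.0]])
    order = np.argsort(fpr)
    ax.plot(fpr[order], tpr[order], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
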