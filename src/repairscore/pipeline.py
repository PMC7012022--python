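"""End-to-end synthetic-study pipeline.

Runs simulate -> score -> stratify -> associate -> crossval -> roc ->
risk-update -> expression per the config's stage toggles, writing every
artifact plus a manifest (config echo, seeds, input hashes) into the output
directory. All numbers in the run report are recomputed from the generated
data; rerunning with an identical config reproduces them exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, enrichment, io, risk, scoring, validation
from .cohort import CohortParams, generate_cohort
from .config import RunConfig
from .expression_sim import ExpressionParams, generate_expression, generate_gene_sets

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _negated(scores):
    return -np.asarray(scores, dtype=float)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}

    cohort = scores = strata = None
    if "simulate" in config.stages:
        logger.info("stage simulate")
        cp = CohortParams(**config.cohort, seed=config.seeds["simulate"])
        cohort = generate_cohort(cp)
        io.write_cohort(cohort, out / "cohort.csv")
        io.write_manifest(out / "cohort.manifest.json", params=cp.to_dict(),
                          seeds={"simulate": cp.seed})
        report["simulate"] = {"n_controls": int((cohort["case_status"] == "control").sum()),
                              "n_cases": int((cohort["case_status"] == "case").sum())}

    if "score" in config.stages:
        logger.info("stage score")
        model = scoring.fit_score_model(cohort)
        scores = scoring.compute_scores(cohort, model)
        strata = scoring.stratify_scores(scores, cohort)
        pd.DataFrame({"id": scores.index, "score": scores.to_numpy(),
                      "tertile": strata.labels.to_numpy()}).to_csv(out / "scores.csv", index=False)
        with open(out / "score_model.json", "w", encoding="utf-8") as fh:
            json.dump({"weights": model.weights, "intercept": model.intercept,
                       "adjust_coefs": model.adjust_coefs, "converged": model.converged,
                       "llf": model.llf}, fh, indent=2)
        report["score"] = {"weights": model.weights,
                           "control_sd": strata.control_sd,
                           "tertile_cuts": [strata.lower_cut, strata.upper_cut]}

    if "associate" in config.stages:
        logger.info("stage associate")
        per_sd = association.fit_adjusted_logistic(cohort, scores, strata, "per_sd_decrease")
        tert = association.fit_adjusted_logistic(cohort, scores, strata, "tertile")
        means = association.adjusted_group_means(scores, cohort, "case_status")
        tables = pd.concat([per_sd.table.assign(form="per_sd_decrease"),
                            tert.table.assign(form="tertile")])
        tables.to_csv(out / "association.csv", index=False)
        report["associate"] = {
            "or_per_sd_decrease": per_sd.odds_ratio("score_per_sd_decrease"),
            "or_tertile_lowest": tert.odds_ratio("tertile_lowest"),
            "or_tertile_middle": tert.odds_ratio("tertile_middle"),
            "adjusted_means": means.table.to_dict(orient="records"),
        }

    cv = None
    if "crossval" in config.stages:
        logger.info("stage crossval")
        cv = validation.loocv_scores(cohort)
        cv.scores.to_frame().assign(converged=cv.converged).to_csv(out / "cv_scores.csv")
        report["crossval"] = {"cv_control_sd": cv.control_sd,
                              "cv_tertile_cuts": [cv.lower_cut, cv.upper_cut],
                              "n_nonconverged": int((~cv.converged).sum())}

    if "roc" in config.stages:
        logger.info("stage roc")
        y = (cohort["case_status"] == "case").to_numpy(dtype=float)
        curves = {}
        curves["score_only"] = validation.roc_analysis(
            _negated(scores), y, config.target_specificities, marker_kind="score_only")
        combined = association.fit_adjusted_logistic(cohort, scores, strata, "per_sd_decrease")
        curves["combined"] = validation.roc_analysis(
            combined.linear_predictor(), y, config.target_specificities, marker_kind="combined")
        if cv is not None:
            ok = cv.converged.to_numpy()
            curves["score_only_cv"] = validation.roc_analysis(
                _negated(cv.scores)[ok], y[ok], config.target_specificities,
                marker_kind="score_only", cv=True)
            lp = validation.loocv_linear_predictors(cohort, scores)
            fin = np.isfinite(lp)
            curves["combined_cv"] = validation.roc_analysis(
                lp[fin], y[fin], config.target_specificities, marker_kind="combined", cv=True)

        def score_marker(df):
            return _negated(scoring.compute_scores(df, scoring.fit_score_model(df))), \
                (df["case_status"] == "case").to_numpy(dtype=float)

        inference = validation.bootstrap_auc_inference(
            score_marker, cohort, B=config.bootstrap_B, seed=config.seeds["roc"])
        for name, c in curves.items():
            c.points.to_csv(out / f"roc_{name}.csv", index=False)
        report["roc"] = {
            **{f"auc_{k}": c.auc for k, c in curves.items()},
            "sensitivity_at": {k: c.sensitivity_at for k, c in curves.items()},
            "score_auc_bca_ci": [inference.ci_low, inference.ci_high],
            "bootstrap_B": inference.B,
            "seed": inference.seed,
        }

    if "risk_update" in config.stages:
        logger.info("stage risk_update")
        ctrl = scores[(cohort["case_status"] == "control").to_numpy()]
        case = scores[(cohort["case_status"] == "case").to_numpy()]
        dist = risk.ScoreDistributionPair(
            control_mean=float(ctrl.mean()), control_sd=float(ctrl.std(ddof=1)),
            case_mean=float(case.mean()), case_sd=float(case.std(ddof=1)))
        updates = []
        for prior in config.risk_priors:
            for region in config.risk_regions:
                lr = risk.likelihood_ratio_for_region(dist, region)
                res = risk.update_risk(prior, lr, region=region)
                updates.append(res.__dict__)
        with open(out / "risk_updates.json", "w", encoding="utf-8") as fh:
            json.dump(updates, fh, indent=2)
        report["risk_update"] = updates

    if "expression" in config.stages:
        logger.info("stage expression")
        ep = ExpressionParams(**config.expression, seed=config.seeds["expression"])
        counts, batch = generate_expression(cohort, scores, ep)
        sets = generate_gene_sets(ep)
        io.write_counts(counts, out / "counts.tsv")
        io.write_gene_sets(sets, out / "gene_sets.gmt")
        io.write_manifest(out / "expression.manifest.json", params=ep.to_dict(),
                          seeds={"expression": ep.seed})
        expr_report = {}
        for group in ("case", "control"):
            mask = (cohort["case_status"] == group).to_numpy()
            cov = pd.DataFrame({
                "age": cohort["age"].to_numpy()[mask],
                "sex": cohort["sex"].to_numpy()[mask],
                "smoking": cohort["smoking"].to_numpy()[mask],
                "batch": batch.to_numpy()[mask],
            })
            gs = enrichment.per_gene_association(
                counts.loc[:, mask], np.asarray(scores)[mask], cov)
            res = enrichment.preranked_gsea(
                gs, sets, n_perm=config.n_perm, seed=config.seeds["expression"],
                min_size=config.min_set_size, max_size=config.max_set_size)
            res.table.to_csv(out / f"enrichment_{group}.tsv", sep="\t", index=False)
            sig = res.table[res.table["q"] <= 0.05]
            expr_report[group] = {
                grp: int((sig["group"] == grp).sum())
                for grp in ("immune", "cell_cycle", "other")
            }
        report["expression"] = expr_report

    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=io._jsonable)
    return report
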