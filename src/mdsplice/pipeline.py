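"""End-to-end orchestration of the aberrant-splicing analysis.

Stage order mirrors the study workflow: expression filter -> splicing
index -> aberrant-event calling -> per-sample scores (patients plus
donor leave-one-out) -> ROC-derived score cutoff with KM/log-rank
stratification for OS and TTLC -> clinical association tests ->
multivariate Cox -> univariate event screen -> LASSO-Cox signature with
median-cutoff stratification (applied unchanged to a validation split when
one is present).  Every artifact carries the configuration hash; pipeline
output is a pure function of (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import signature as msig
from . import splicing as msp
from . import survival as msv

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline", "STAGES"]

log = logging.getLogger("mdsplice")

STAGES = [
    "load", "expression_filter", "splicing_index", "events", "scores",
    "stratification", "associations", "multivariate_cox", "screen", "signature",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    annotation_path: str
    intensity_path: str
    clinical_path: str
    outdir: str
    annotation_format: str = "tsv"
    min_log2_expr: float = 6.0
    si_threshold: float = 2.0
    roc_label_mode: str = "event"
    landmark_months: float | None = None
    cutoff_method: str = "youden"
    tie_method: str = "breslow"
    screen_alpha: float = 0.05
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    include_junctions: bool = False
    donor_loo: bool = True

    def config_hash(self) -> str:
        # hash only analysis-relevant settings, not the output location
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, chash: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_json(obj: dict, path: Path, chash: str) -> None:
    obj = {"config_hash": chash, **obj}
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def _km_frame(curve: msv.KMCurve, group: str) -> pd.DataFrame:
    df = curve.to_frame()
    df.insert(0, "group", group)
    return df


def _stratified_km_logrank(outcomes: pd.DataFrame, groups: pd.Series):
    hi = groups == "high"
    lo = groups == "low"
    o_hi, o_lo = outcomes[hi.reindex(outcomes.index, fill_value=False)], \
        outcomes[lo.reindex(outcomes.index, fill_value=False)]
    chi2, p = msv.logrank_test(o_hi["time"], o_hi["event"], o_lo["time"], o_lo["event"])
    km_hi = msv.kaplan_meier(o_hi["time"], o_hi["event"])
    km_lo = msv.kaplan_meier(o_lo["time"], o_lo["event"])
    return km_hi, km_lo, chi2, p


def run_full_pipeline(config: PipelineConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    _write_json({"config": asdict(config)}, outdir / "pipeline_config.json", chash)

    stage = "load"
    try:
        ann = mio.load_platform_annotation(config.annotation_path,
                                           format=config.annotation_format)
        matrix = mio.load_intensity_matrix(config.intensity_path)
        clinical = mio.load_clinical_table(config.clinical_path)
        has_split = "split" in clinical.table.columns
        design = mio.design_from_clinical(clinical,
                                          split="training" if has_split else None)
        mio.validate_design(design, matrix, clinical)
        val_ids = []
        if has_split:
            t = clinical.table
            val_ids = list(t.loc[(t["cohort"] == "patient")
                                 & (t["split"] == "validation"), "sample_id"])

        stage = "expression_filter"
        expressed = mio.filter_expressed_genes(matrix, ann, design,
                                               config.min_log2_expr)
        log.info("expressed genes: %d / %d (%.1f%%)", expressed.n_expressed,
                 expressed.n_total, 100 * expressed.fraction)
        _write_tsv(pd.DataFrame({"gene_id": sorted(expressed.genes)}),
                   outdir / "expressed_genes.tsv", chash, index=False)

        stage = "splicing_index"
        si = msp.compute_splicing_index(matrix, ann, design, expressed=expressed,
                                        include_junctions=config.include_junctions)
        summary = pd.DataFrame({
            "n_analyzable": si.analyzable.sum(axis=1).astype(int),
            "mean_converted_si": si.converted.mean(axis=1),
            "min_converted_si": si.converted.min(axis=1),
            "max_converted_si": si.converted.max(axis=1),
        })
        summary.index.name = "psr_id"
        _write_tsv(summary, outdir / "si_summary.tsv", chash, index=True)

        stage = "events"
        events = msp.call_aberrant_events(si, ann, config.si_threshold)
        log.info("aberrant AS events: %d in %d genes", len(events),
                 events["gene_id"].nunique())
        _write_tsv(events, outdir / "events.tsv", chash, index=False)
        split = pd.DataFrame({
            "biotype": ["coding", "non_coding"],
            "n_events": [int((events["biotype"] == "coding").sum()),
                         int((events["biotype"] == "non_coding").sum())],
        })
        split["fraction"] = split["n_events"] / max(len(events), 1)
        _write_tsv(split, outdir / "event_split.tsv", chash, index=False)

        stage = "scores"
        pat_scores = msp.aberrant_score_table(events, design.patient_ids)
        pat_scores.insert(0, "cohort", "patient")
        if config.donor_loo:
            donor_scores = msp.donor_reference_scores(
                matrix, ann, design, threshold=config.si_threshold,
                min_log2_expr=config.min_log2_expr)
            donor_scores.insert(0, "cohort", "control")
            scores = pd.concat([pat_scores, donor_scores])
        else:
            scores = pat_scores
        _write_tsv(scores, outdir / "scores.tsv", chash, index=True)

        stage = "stratification"
        outcomes_os = clinical.outcomes(design.patient_ids, "OS")
        outcomes_ttlc = clinical.outcomes(design.patient_ids, "TTLC")
        usable = pat_scores["score"].dropna()
        roc = msv.roc_survival_cutoff(
            usable, outcomes_os.loc[usable.index, "time"],
            outcomes_os.loc[usable.index, "event"],
            label_mode=config.roc_label_mode,
            landmark_months=config.landmark_months,
            method=config.cutoff_method)
        groups = roc.classify(usable)
        km_frames, strat = [], {
            "cutoff": roc.cutoff, "youden_j": roc.youden_j,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "n_high": int((groups == "high").sum()),
            "n_low": int((groups == "low").sum()),
        }
        for name, oc in (("OS", outcomes_os), ("TTLC", outcomes_ttlc)):
            km_hi, km_lo, chi2, p = _stratified_km_logrank(oc.loc[usable.index], groups)
            strat[f"logrank_chi2_{name}"] = chi2
            strat[f"logrank_p_{name}"] = p
            strat[f"median_{name}_high"] = km_hi.median
            strat[f"median_{name}_low"] = km_lo.median
            km_frames.append(_km_frame(km_hi, f"{name}_high"))
            km_frames.append(_km_frame(km_lo, f"{name}_low"))
        _write_json(strat, outdir / "roc_stratification.json", chash)
        _write_tsv(pd.concat(km_frames, ignore_index=True),
                   outdir / "km_curves.tsv", chash, index=False)

        stage = "associations"
        assoc_rows = []
        clin_pat = clinical.table.set_index("sample_id").loc[groups.index]
        for col in clinical.covariate_columns:
            vals = clin_pat[col]
            if col == "split":
                continue
            if set(vals.dropna().unique()) <= {0, 1}:
                tab = pd.crosstab(vals, groups).reindex(
                    index=[1, 0], columns=["high", "low"], fill_value=0)
                if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                    continue
                stat, p = msv.contingency_chi2(tab.values, method="pearson")
                assoc_rows.append({"variable": col, "test": "pearson_chi2",
                                   "statistic": stat, "p": p})
            else:
                stat, p = msv.group_comparisons(vals.to_numpy(float),
                                                groups.to_numpy(), kind="anova")
                assoc_rows.append({"variable": col, "test": "anova",
                                   "statistic": stat, "p": p})
        _write_tsv(pd.DataFrame(assoc_rows), outdir / "associations.tsv",
                   chash, index=False)

        stage = "multivariate_cox"
        covars = clin_pat[[c for c in clinical.covariate_columns
                           if c != "split"]].copy()
        covars["high_score"] = (groups == "high").astype(int)
        covars = covars.apply(pd.to_numeric, errors="coerce")
        covars = covars.loc[:, covars.std() > 0].dropna()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cox = msv.cox_ph_fit(
                outcomes_os.loc[covars.index, "time"],
                outcomes_os.loc[covars.index, "event"],
                covars, tie_method=config.tie_method)
        _write_tsv(cox.summary, outdir / "cox_multivariate.tsv", chash, index=True)

        stage = "screen"
        event_psrs = events["psr_id"].unique()
        screen = msv.univariate_event_screen(
            si, outcomes_os, alpha=config.screen_alpha, psr_ids=event_psrs,
            tie_method=config.tie_method)
        log.info("screen: %d tested, %d pass Bonferroni", screen.m_tested,
                 int(screen.table["passed"].sum()))
        _write_tsv(screen.table, outdir / "screen.tsv", chash, index=True)

        stage = "signature"
        if not len(screen.passed):
            _write_json({"note": "screen pass set empty; no signature fitted"},
                        outdir / "signature.json", chash)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model, train_scores = msig.build_signature(
                    si, screen, outcomes_os, n_lambda=config.n_lambda,
                    lambda_min_ratio=config.lambda_min_ratio)
            msig.save_signature(model, outdir / "signature.json")
            train_scores.insert(0, "split", "training")
            sig_tables = [train_scores]
            sig_json: dict = {
                "n_selected": len(model.psr_ids), "lambda": model.lam,
                "cutoff": model.cutoff, "score_range": list(model.score_range),
            }
            if len(model.psr_ids):
                for name, oc in (("OS", outcomes_os), ("TTLC", outcomes_ttlc)):
                    _, _, chi2, p = _stratified_km_logrank(
                        oc.loc[train_scores.index], train_scores["risk_group"])
                    sig_json[f"training_logrank_chi2_{name}"] = chi2
                    sig_json[f"training_logrank_p_{name}"] = p
                if val_ids:
                    design_val = mio.CohortDesign(tuple(val_ids), design.control_ids)
                    si_val = msp.compute_splicing_index(
                        matrix, ann, design_val,
                        min_log2_expr=config.min_log2_expr,
                        include_junctions=config.include_junctions)
                    val_scores = msig.apply_signature(model, si_val)
                    ok = ~val_scores["flagged"]
                    oc_val = clinical.outcomes(val_scores.index[ok], "OS")
                    _, _, chi2, p = _stratified_km_logrank(
                        oc_val, val_scores.loc[ok, "risk_group"])
                    sig_json["validation_logrank_chi2_OS"] = chi2
                    sig_json["validation_logrank_p_OS"] = p
                    val_out = val_scores.drop(columns=["flagged"]).copy()
                    val_out.insert(0, "split", "validation")
                    sig_tables.append(val_out)
            _write_json(sig_json, outdir / "signature_stratification.json", chash)
            _write_tsv(pd.concat(sig_tables), outdir / "signature_scores.tsv",
                       chash, index=True)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc
    return outdir
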