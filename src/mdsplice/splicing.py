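"""Splicing-index computation and aberrant-event calling.

The splicing index (SI) of a probe-selection region (PSR) compares the
PSR's gene-expression-normalized intensity in one patient against the
normal-donor reference::

    linear_ratio = (I_patient[psr] / gene_level_patient)
                   / (mean_donor_I[psr] / gene_level_donors)

Ratios below 1 are reported as the negative reciprocal (a ratio of 1/4
becomes an SI of -4), so |SI| >= 1 wherever it is defined.  A (patient, PSR)
cell is an **aberrant AS event** when SI < -2 or SI > 2 (strict).  A gene
with at least one event in a patient is an **aberrant AS gene**, and the
per-patient **aberrant AS score** is total events divided by total aberrant
genes (>= 1 whenever any event exists).

Gene expression levels are arithmetic means of the gene's exon-PSR linear
intensities (group mean across donors for the reference, the patient's own
profile for the numerator); the estimator is configurable to the median.
Cells with a zero denominator anywhere in the chain, or in genes failing the
expression filter, are masked as non-analyzable rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    CohortDesign,
    ConfigError,
    ExpressedGeneSet,
    IntensityMatrix,
    PlatformAnnotation,
    ValidationError,
    filter_expressed_genes,
)

__all__ = [
    "GeneExpressionSummary",
    "SplicingIndexMatrix",
    "summarize_gene_expression",
    "compute_splicing_index",
    "splicing_index",
    "convert_ratio",
    "call_aberrant_events",
    "aberrant_as_score",
    "aberrant_score_table",
    "donor_reference_scores",
    "log2_si",
    "write_events",
    "write_scores",
]

EVENT_COLUMNS = ["patient_id", "psr_id", "gene_id", "converted_si", "direction", "biotype"]


@dataclass(frozen=True)
class GeneExpressionSummary:
    gene_id: str
    group: str            # 'patient_single' or 'control_group'
    level: float          # mean linear intensity over the gene's exon PSRs


def summarize_gene_expression(
    m: IntensityMatrix,
    ann: PlatformAnnotation,
    gene_id: str,
    sample_ids: Sequence[str],
    estimator: str = "mean",
) -> GeneExpressionSummary:
    """Gene expression level: mean over exon PSRs of per-PSR sample means."""
    if not len(sample_ids):
        raise ValidationError("sample_set must be non-empty")
    psrs = ann.psrs_for_gene(gene_id, exon_only=True)
    if not psrs:
        raise ValidationError(f"gene {gene_id!r} has no exon PSRs")
    per_psr = m.values.loc[psrs, list(sample_ids)].mean(axis=1)
    if estimator == "mean":
        level = float(per_psr.mean())
    elif estimator == "median":
        level = float(per_psr.median())
    else:
        raise ConfigError(f"unknown gene-level estimator {estimator!r}")
    group = "patient_single" if len(sample_ids) == 1 else "control_group"
    return GeneExpressionSummary(gene_id=gene_id, group=group, level=level)


def convert_ratio(ratio):
    """Negative-reciprocal conversion: r for r >= 1, else -1/r.

    The boundary r == 1 maps to +1 so sign(SI) agrees with sign(log2 ratio)
    for ratios above 1.
    """
    r = np.asarray(ratio, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(r >= 1.0, r, -1.0 / r)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SplicingIndexMatrix:
    """Converted SI per (PSR, patient) with analyzability mask.

    ``linear_ratio``/``converted``/``analyzable`` are PSR x patient frames;
    non-analyzable cells are NaN in the value frames and False in the mask.
    """

    linear_ratio: pd.DataFrame
    converted: pd.DataFrame
    analyzable: pd.DataFrame
    expressed: ExpressedGeneSet
    gene_of: pd.Series          # psr_id -> gene_id for the rows

    @property
    def patient_ids(self) -> pd.Index:
        return self.converted.columns

    @property
    def psr_ids(self) -> pd.Index:
        return self.converted.index


def compute_splicing_index(
    m: IntensityMatrix,
    ann: PlatformAnnotation,
    design: CohortDesign,
    expressed: ExpressedGeneSet | None = None,
    min_log2_expr: float = 6.0,
    estimator: str = "mean",
    include_junctions: bool = False,
) -> SplicingIndexMatrix:
    """Compute the SI chain for every (exon PSR, patient) cell.

    Gene levels are always summarized over exon PSRs only; junction probe
    sets get an SI of their own only when ``include_junctions`` is set.
    """
    if expressed is None:
        expressed = filter_expressed_genes(m, ann, design, min_log2_expr)
    exon = ann.exon_table
    rows = ann.table if include_junctions else exon
    psr_ids = rows["psr_id"].values
    gene_per_row = rows["gene_id"].values

    patients = list(design.patient_ids)
    controls = list(design.control_ids)

    ctrl_psr_mean = m.values[controls].mean(axis=1)  # per PSR over donors
    exon_gene = exon["gene_id"].values
    if estimator == "mean":
        ctrl_gene = ctrl_psr_mean.loc[exon["psr_id"]].groupby(exon_gene).mean()
        pat_gene = m.values.loc[exon["psr_id"], patients].groupby(exon_gene).mean()
    elif estimator == "median":
        ctrl_gene = ctrl_psr_mean.loc[exon["psr_id"]].groupby(exon_gene).median()
        pat_gene = m.values.loc[exon["psr_id"], patients].groupby(exon_gene).median()
    else:
        raise ConfigError(f"unknown gene-level estimator {estimator!r}")

    I = m.values.loc[psr_ids, patients]
    pat_gene_rows = pat_gene.reindex(gene_per_row)       # row-aligned gene levels
    pat_gene_rows.index = psr_ids
    ctrl_gene_rows = ctrl_gene.reindex(gene_per_row).values
    ctrl_psr_rows = ctrl_psr_mean.loc[psr_ids]

    with np.errstate(divide="ignore", invalid="ignore"):
        numer = I.values / pat_gene_rows.values
        denom = ctrl_psr_rows.values / ctrl_gene_rows
        ratio = numer / denom[:, None]

    gene_expressed = np.isin(gene_per_row, list(expressed.genes))
    analyzable = (
        gene_expressed[:, None]
        & (pat_gene_rows.values > 0)
        & (ctrl_gene_rows > 0)[:, None]
        & (ctrl_psr_rows.values > 0)[:, None]
        & (I.values > 0)
    )
    analyzable &= np.isfinite(ratio) & (ratio > 0)

    ratio = np.where(analyzable, ratio, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        converted = np.where(np.isnan(ratio), np.nan,
                             np.where(ratio >= 1.0, ratio, -1.0 / ratio))

    idx = pd.Index(psr_ids, name="psr_id")
    cols = pd.Index(patients, name="patient_id")
    return SplicingIndexMatrix(
        linear_ratio=pd.DataFrame(ratio, index=idx, columns=cols),
        converted=pd.DataFrame(converted, index=idx, columns=cols),
        analyzable=pd.DataFrame(analyzable, index=idx, columns=cols),
        expressed=expressed,
        gene_of=pd.Series(gene_per_row, index=idx),
    )


def splicing_index(
    m: IntensityMatrix,
    ann: PlatformAnnotation,
    design: CohortDesign,
    patient_id: str,
    psr_id: str,
    expressed: ExpressedGeneSet | None = None,
    min_log2_expr: float = 6.0,
    estimator: str = "mean",
) -> tuple[float, float]:
    """Single-cell SI: returns (linear_ratio, converted_si); NaNs if non-analyzable."""
    if expressed is None:
        expressed = filter_expressed_genes(m, ann, design, min_log2_expr)
    row = ann.table[ann.table["psr_id"] == psr_id]
    if row.empty:
        raise ValidationError(f"unknown PSR {psr_id!r}")
    gene_id = row["gene_id"].iloc[0]
    if gene_id not in expressed.genes:
        return (float("nan"), float("nan"))
    pat_level = summarize_gene_expression(m, ann, gene_id, [patient_id], estimator).level
    ctrl_level = summarize_gene_expression(m, ann, gene_id, list(design.control_ids), estimator).level
    ctrl_psr = float(m.values.loc[psr_id, list(design.control_ids)].mean())
    i_pat = float(m.values.loc[psr_id, patient_id])
    if pat_level <= 0 or ctrl_level <= 0 or ctrl_psr <= 0 or i_pat <= 0:
        return (float("nan"), float("nan"))
    ratio = (i_pat / pat_level) / (ctrl_psr / ctrl_level)
    return (ratio, convert_ratio(ratio))


def call_aberrant_events(
    si: SplicingIndexMatrix,
    ann: PlatformAnnotation,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Aberrant AS events: analyzable cells with converted SI > t or < -t (strict).

    Equivalent linear criterion at the default t=2: ratio > 2 or ratio < 1/2.
    Returns one row per event: patient_id, psr_id, gene_id, converted_si,
    direction (up/down), biotype.
    """
    if threshold <= 1.0:
        raise ConfigError("event threshold must exceed 1 (converted SI scale)")
    c = si.converted
    mask = si.analyzable.values & (np.abs(c.values) > threshold)
    psr_idx, pat_idx = np.nonzero(mask)
    biotype = ann.table.set_index("psr_id")["biotype"]
    events = pd.DataFrame({
        "patient_id": c.columns[pat_idx],
        "psr_id": c.index[psr_idx],
        "gene_id": si.gene_of.iloc[psr_idx].values,
        "converted_si": c.values[psr_idx, pat_idx],
        "direction": np.where(c.values[psr_idx, pat_idx] > 0, "up", "down"),
        "biotype": biotype.reindex(c.index[psr_idx]).values,
    }, columns=EVENT_COLUMNS)
    return events.sort_values(["patient_id", "psr_id"], kind="mergesort").reset_index(drop=True)


def aberrant_as_score(events: pd.DataFrame, sample_id: str) -> pd.Series:
    """Per-sample aberrant AS score row: n_events, n_genes, score, coding split."""
    sub = events[events["patient_id"] == sample_id]
    n_events = len(sub)
    n_genes = sub["gene_id"].nunique()
    if n_genes == 0:
        warnings.warn(f"sample {sample_id!r} has no aberrant AS events; score undefined",
                      stacklevel=2)
        score = float("nan")
    else:
        score = n_events / n_genes
    n_coding = int((sub["biotype"] == "coding").sum())
    return pd.Series({
        "n_events": n_events,
        "n_genes": n_genes,
        "score": score,
        "n_coding_events": n_coding,
        "coding_fraction": n_coding / n_events if n_events else float("nan"),
    }, name=sample_id)


def aberrant_score_table(events: pd.DataFrame, sample_ids: Iterable[str]) -> pd.DataFrame:
    """Score rows for every sample (NaN score when a sample has no events)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid in sample_ids:
            rows.append(aberrant_as_score(events, sid))
    out = pd.DataFrame(rows)
    out.index.name = "sample_id"
    for col in ("n_events", "n_genes", "n_coding_events"):
        out[col] = out[col].astype(int)
    return out


def donor_reference_scores(
    m: IntensityMatrix,
    ann: PlatformAnnotation,
    design: CohortDesign,
    threshold: float = 2.0,
    min_log2_expr: float = 6.0,
    estimator: str = "mean",
) -> pd.DataFrame:
    """Leave-one-out aberrant AS scores for the normal donors.

    Each donor is scored against the remaining donors as reference, re-running
    the full expression-filter -> SI -> event -> score chain per round.
    """
    controls = list(design.control_ids)
    if len(controls) < 3:
        raise ValidationError("donor leave-one-out needs at least 3 controls")
    rows = []
    for donor in controls:
        rest = tuple(c for c in controls if c != donor)
        loo = CohortDesign(patient_ids=(donor,), control_ids=rest)
        si = compute_splicing_index(m, ann, loo, min_log2_expr=min_log2_expr,
                                    estimator=estimator)
        events = call_aberrant_events(si, ann, threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(aberrant_as_score(events, donor))
    out = pd.DataFrame(rows)
    out.index.name = "sample_id"
    return out


def log2_si(si: SplicingIndexMatrix) -> pd.DataFrame:
    """Signed log2 SI: log2(linear_ratio) == sign(converted)*log2|converted|.

    This is the predictor scale used by the survival screen and the
    LASSO-Cox signature; non-analyzable cells stay NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return pd.DataFrame(np.log2(si.linear_ratio.values),
                            index=si.linear_ratio.index,
                            columns=si.linear_ratio.columns)


def write_events(events: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        events.to_csv(fh, sep="\t", index=False)


def write_scores(scores: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        scores.to_csv(fh, sep="\t", index=True)
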