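"""Data model and ingestion for exon-array splicing analysis.

The analysis consumes three inputs:

* a **platform annotation** mapping each probe-selection region (PSR) of the
  array to a gene, an exon index, a coding/non-coding flag and genomic
  coordinates;
* a normalized, linear-scale **intensity matrix** (PSRs x samples);
* a per-sample **clinical table** with cohort labels (patient/control),
  overall-survival and time-to-leukemic-change endpoints, and covariates.

Coordinates are stored 0-based half-open internally; GFF3 input (1-based
closed) is converted on load.  Junction probe sets are ingested and flagged
(``region_kind='junction_probe_set'``) but excluded from splicing-index
computation by default, which is defined on exon PSRs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ConfigError",
    "PlatformAnnotation",
    "IntensityMatrix",
    "ClinicalTable",
    "CohortDesign",
    "ExpressedGeneSet",
    "load_platform_annotation",
    "write_platform_annotation",
    "load_intensity_matrix",
    "write_intensity_matrix",
    "load_clinical_table",
    "write_clinical_table",
    "design_from_clinical",
    "validate_design",
    "filter_expressed_genes",
]

ANNOTATION_COLUMNS = [
    "psr_id", "gene_id", "exon_index", "biotype",
    "chrom", "start", "end", "region_kind",
]
BIOTYPES = frozenset({"coding", "non_coding"})
REGION_KINDS = frozenset({"exon_psr", "junction_probe_set"})
CLINICAL_REQUIRED = [
    "sample_id", "cohort", "os_time", "os_event", "ttlc_time", "ttlc_event",
]
COHORTS = frozenset({"patient", "control"})


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


class ConfigError(ValueError):
    """Raised when a configuration value violates a module contract."""


# ---------------------------------------------------------------------------
# Platform annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlatformAnnotation:
    """PSR -> gene/exon/biotype/coordinate map; the array-design universe.

    ``table`` has one row per PSR with columns ``psr_id, gene_id, exon_index,
    biotype, chrom, start, end, region_kind`` (start/end 0-based half-open).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        dup = t["psr_id"][t["psr_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate psr_id: {dup.iloc[0]!r}")
        no_gene = t["gene_id"].isna() | (t["gene_id"].astype(str) == "")
        if no_gene.any():
            bad = t.loc[no_gene, "psr_id"].iloc[0]
            raise ValidationError(f"PSR {bad!r} has no gene_id")
        if (t["exon_index"] < 1).any():
            raise ValidationError("exon_index must be >= 1")
        bad_bt = set(t["biotype"]) - BIOTYPES
        if bad_bt:
            raise ValidationError(f"unknown biotype values: {sorted(bad_bt)}")
        bad_rk = set(t["region_kind"]) - REGION_KINDS
        if bad_rk:
            raise ValidationError(f"unknown region_kind values: {sorted(bad_rk)}")
        if (t["end"] <= t["start"]).any():
            bad = t.loc[t["end"] <= t["start"], "psr_id"].iloc[0]
            raise ValidationError(f"PSR {bad!r}: end must exceed start")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def exon_table(self) -> pd.DataFrame:
        """Rows for exon PSRs only (the splicing-index universe)."""
        return self.table[self.table["region_kind"] == "exon_psr"]

    @property
    def gene_ids(self) -> pd.Index:
        """Genes with at least one exon PSR."""
        return pd.Index(self.exon_table["gene_id"].unique())

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def psrs_for_gene(self, gene_id: str, exon_only: bool = True) -> list[str]:
        t = self.exon_table if exon_only else self.table
        return list(t.loc[t["gene_id"] == gene_id, "psr_id"])

    def gene_of(self) -> pd.Series:
        """Series mapping psr_id -> gene_id over exon PSRs."""
        e = self.exon_table
        return pd.Series(e["gene_id"].values, index=e["psr_id"].values)


def load_platform_annotation(path: str | Path, format: str = "tsv") -> PlatformAnnotation:
    """Load a platform annotation from TSV or GFF3.

    TSV must carry the header ``psr_id gene_id exon_index biotype chrom start
    end region_kind`` with coordinates already 0-based half-open.  GFF3 rows
    must carry ``psr_id`` and ``gene_id`` attributes (plus optional
    ``exon_index``, ``biotype``, ``region_kind``); 1-based closed coordinates
    are converted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        t = pd.read_csv(path, sep="\t", comment="#", dtype={"psr_id": str, "gene_id": str})
        for col in ("exon_index", "start", "end"):
            if col in t.columns and not pd.api.types.is_integer_dtype(t[col]):
                bad = t.index[pd.to_numeric(t[col], errors="coerce").isna()]
                if len(bad):
                    raise ValidationError(
                        f"malformed {col} at line {bad[0] + 2} of {path.name}")
                t[col] = pd.to_numeric(t[col]).astype(int)
        return PlatformAnnotation(t[ANNOTATION_COLUMNS])
    if format == "gff":
        return _load_annotation_gff(path)
    raise ConfigError(f"unknown annotation format {format!r}")


def _load_annotation_gff(path: Path) -> PlatformAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValidationError(f"{path.name}:{lineno}: expected 9 GFF columns")
            chrom, _src, _type, start, end, _score, _strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValidationError(
                    f"{path.name}:{lineno}: malformed coordinates {start!r}..{end!r}")
            kv = {}
            for item in attrs.strip().split(";"):
                item = item.strip()
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    kv[k.strip()] = v.strip()
            if "psr_id" not in kv or "gene_id" not in kv:
                raise ValidationError(
                    f"{path.name}:{lineno}: GFF attributes need psr_id and gene_id")
            rows.append({
                "psr_id": kv["psr_id"],
                "gene_id": kv["gene_id"],
                "exon_index": int(kv.get("exon_index", 1)),
                "biotype": kv.get("biotype", "coding"),
                "chrom": chrom,
                "start": start_i - 1,  # 1-based closed -> 0-based half-open
                "end": end_i,
                "region_kind": kv.get("region_kind", "exon_psr"),
            })
    return PlatformAnnotation(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


def write_platform_annotation(ann: PlatformAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityMatrix:
    """Linear-scale normalized intensities, PSRs (rows) x samples (columns)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate psr_id row {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample column {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("intensity matrix contains non-numeric cells")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite intensity at PSR {v.index[i]!r}, sample {v.columns[j]!r}")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative intensity at PSR {v.index[i]!r}, sample {v.columns[j]!r}")

    @property
    def psr_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def load_intensity_matrix(path: str | Path) -> IntensityMatrix:
    """Load a PSR x sample intensity TSV (first column ``psr_id``)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    cols = header.rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for c in cols:
        if c in seen:
            raise ValidationError(f"duplicate sample column {c!r} in {path.name}")
        seen.add(c)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "psr_id"
    df.columns = [str(c) for c in cols]
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric intensity at PSR {bad[0]!r}, sample {col!r}")
    return IntensityMatrix(df.astype(float))


def write_intensity_matrix(m: IntensityMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index=True, index_label="psr_id")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample cohort labels, survival endpoints and covariates.

    Times are months from MDS diagnosis: ``os_*`` to death/last follow-up,
    ``ttlc_*`` to leukemic change (censored at death or last follow-up).
    Unknown covariate columns are carried through untouched; missing covariate
    values propagate as NaN and are never imputed.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in CLINICAL_REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"clinical table missing required columns: {missing}")
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id {dup.iloc[0]!r}")
        bad_cohort = set(t["cohort"]) - COHORTS
        if bad_cohort:
            raise ValidationError(f"unknown cohort labels: {sorted(bad_cohort)}")
        for col in ("os_event", "ttlc_event"):
            vals = set(pd.unique(t[col]))
            if not vals <= {0, 1}:
                raise ValidationError(f"{col} must be 0/1, got {sorted(vals - {0, 1})}")
        for col in ("os_time", "ttlc_time"):
            if (t[col] < 0).any():
                raise ValidationError(f"{col} must be non-negative")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in CLINICAL_REQUIRED]

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        ids = list(sample_ids)
        sub = self.table.set_index("sample_id").loc[ids].reset_index()
        return ClinicalTable(sub)

    def outcomes(self, sample_ids: Iterable[str], endpoint: str = "OS") -> pd.DataFrame:
        """Time/event frame for one endpoint, indexed by sample_id."""
        if endpoint not in ("OS", "TTLC"):
            raise ConfigError(f"unknown endpoint {endpoint!r}")
        tcol, ecol = ("os_time", "os_event") if endpoint == "OS" else ("ttlc_time", "ttlc_event")
        sub = self.table.set_index("sample_id").loc[list(sample_ids)]
        return pd.DataFrame({"time": sub[tcol].astype(float), "event": sub[ecol].astype(int)})


def load_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, comment="#", dtype={"sample_id": str, "cohort": str},
                     float_precision="round_trip")
    return ClinicalTable(df)


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Which samples are MDS patients and which are normal-donor controls."""

    patient_ids: tuple[str, ...]
    control_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.patient_ids) & set(self.control_ids)
        if overlap:
            raise ValidationError(f"samples in both groups: {sorted(overlap)[:3]}")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValidationError("duplicate patient ids in design")
        if len(set(self.control_ids)) != len(self.control_ids):
            raise ValidationError("duplicate control ids in design")
        if len(self.control_ids) < 2:
            raise ValidationError("design needs at least 2 controls")


def design_from_clinical(clin: ClinicalTable, split: str | None = None) -> CohortDesign:
    """Build a design from the cohort column (optionally one ``split`` value)."""
    t = clin.table
    if split is not None and "split" in t.columns:
        pat = t[(t["cohort"] == "patient") & (t["split"] == split)]
    else:
        pat = t[t["cohort"] == "patient"]
    ctl = t[t["cohort"] == "control"]
    return CohortDesign(tuple(pat["sample_id"]), tuple(ctl["sample_id"]))


def validate_design(design: CohortDesign, m: IntensityMatrix, clin: ClinicalTable) -> None:
    """Cross-check that every design sample exists in matrix and clinical table."""
    cols = set(m.sample_ids)
    clin_ids = set(clin.sample_ids)
    for sid in (*design.patient_ids, *design.control_ids):
        if sid not in cols:
            raise ValidationError(f"sample {sid!r} missing from intensity matrix")
        if sid not in clin_ids:
            raise ValidationError(f"sample {sid!r} missing from clinical table")


# ---------------------------------------------------------------------------
# Expressed-gene filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressedGeneSet:
    """Genes whose group-level expression clears the threshold in both cohorts."""

    genes: frozenset
    n_expressed: int
    n_total: int
    min_log2_expr: float

    @property
    def fraction(self) -> float:
        return self.n_expressed / self.n_total if self.n_total else float("nan")


def filter_expressed_genes(
    m: IntensityMatrix,
    ann: PlatformAnnotation,
    design: CohortDesign,
    min_log2_expr: float = 6.0,
) -> ExpressedGeneSet:
    """Restrict the analysis to genes expressed in BOTH cohorts.

    A gene is expressed iff log2 of its group-level expression (mean linear
    intensity over the gene's exon PSRs, donors/patients averaged as a group)
    is at least ``min_log2_expr`` in the patient group AND the control group.
    This is a configurable surrogate for the array software's proprietary
    detection-above-background call.
    """
    exon = ann.exon_table
    if exon.empty:
        raise ValidationError("annotation has no exon PSRs")
    psrs = exon["psr_id"]
    present = psrs.isin(m.psr_ids)
    if not present.all():
        missing = psrs[~present].iloc[0]
        raise ValidationError(f"annotated PSR {missing!r} missing from matrix")
    sub = m.values.loc[psrs]
    gene = exon["gene_id"].values
    ctl_level = sub[list(design.control_ids)].mean(axis=1).groupby(gene).mean()
    pat_level = sub[list(design.patient_ids)].mean(axis=1).groupby(gene).mean()
    with np.errstate(divide="ignore"):
        ok = (np.log2(ctl_level.clip(lower=0)) >= min_log2_expr) & (
            np.log2(pat_level.clip(lower=0)) >= min_log2_expr
        )
    genes = frozenset(ok.index[ok])
    result = ExpressedGeneSet(
        genes=genes,
        n_expressed=len(genes),
        n_total=int(ok.size),
        min_log2_expr=float(min_log2_expr),
    )
    if result.n_expressed == 0:
        warnings.warn("no gene passes the expression filter", stacklevel=2)
    return result
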