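"""Synthetic exon-array cohorts with planted splicing aberrations.

The generator emulates the statistical structure of a normalized exon-array
study of MDS marrow versus normal-donor marrow: per-gene baseline
intensities shared by the gene's PSRs, donor-to-donor lognormal measurement
noise, patient-specific planted fold-change aberrations, and survival times
whose hazard depends on a designated subset of planted events.  It emits
the exact file dialects the ingestion layer reads, plus a truth table, so
every downstream module is verifiable without any external download.

Planting design
---------------
Multiplying one PSR by a fold would also shift the patient's own gene-level
mean and thereby distort the splicing index of every PSR in that gene.
Plants are therefore **mean-compensated**: the planted PSR is scaled by the
fold and the gene's remaining exon PSRs absorb the complementary amount, so
the patient's gene level stays equal to the control gene level.  At zero
noise every intensity is an integer and the compensation is exact in
integer arithmetic, which makes the planted cell's splicing index equal the
*realized* fold (``round(fold * baseline) / baseline``) bitwise — including
the strict-boundary fold of exactly 2.0.  A fold is only planted where the
remaining PSRs can absorb it while staying within (0.55, 1.45) of baseline,
so compensated cells can never cross the |SI| > 2 event threshold
themselves.

Draw order under the single seeded stream: platform -> baselines ->
prognostic assignment -> per-patient severities -> background plants ->
measurement noise -> covariates -> survival times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    CohortDesign,
    ConfigError,
    IntensityMatrix,
    PlatformAnnotation,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "StudyData",
    "simulate_platform",
    "simulate_intensities",
    "simulate_survival",
    "simulate_study",
    "export_truth",
    "load_truth",
]

_MAX_COMPENSATION = 0.45   # compensated cells stay within (0.55, 1.45) x baseline


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the modeled study: 176 MDS patients, 20 normal donors
    and a 31-patient validation cohort; events-per-aberrant-gene mean 2.6
    (the patients' median aberrant AS score); 85.9% of PSRs on coding genes;
    a baseline hazard of 0.01/month (median OS near 70 months in the
    low-risk arm).  The gene count is desk-scale.
    """

    # platform
    n_genes: int = 300
    psrs_per_gene_mean: float = 9.9        # Poisson, shifted so every gene has >= 3
    junction_probe_rate: float = 0.5       # junction probe sets per exon PSR
    coding_fraction: float = 0.859
    # cohort sizes
    n_patients: int = 176
    n_controls: int = 20
    n_validation: int = 31
    # intensities
    baseline_log2_mu: float = 8.0
    baseline_log2_sigma: float = 1.5
    noise_log2_sigma: float = 0.15
    expressed_floor_log2: float = 6.5      # plants restricted to clearly expressed genes
    # aberration planting
    aberrant_gene_rate: float = 0.1        # per (patient, eligible gene)
    events_per_aberrant_gene_mean: float = 2.6
    patient_severity_sigma: float = 0.5    # lognormal multiplier on rate & multiplicity
    fold_change_set: tuple[float, ...] = (4.0, 3.0, 1 / 3, 1 / 4)
    nonconforming_fold_set: tuple[float, ...] = (1.8, 2.0)
    nonconforming_rate: float = 0.05       # boundary folds, for threshold tests
    # prognostic structure
    n_prognostic_events: int = 13
    prognostic_log_hr: float = 0.8         # |log-HR| per SD of log2 SI
    prognostic_carrier_rate: float = 0.5
    prognostic_fold: float = 0.25          # down-direction keeps compensation mild
    prognostic_carrier_assoc: float = 1.0  # carrier-prob tilt per SD of latent burden
    # survival
    baseline_hazard_per_month: float = 0.01
    ttlc_hazard_per_month: float = 0.004
    ttlc_effect_scale: float = 1.5
    censoring_horizon_months: float = 120.0
    # covariates
    male_rate: float = 0.69
    age_mean: float = 68.0
    age_sd: float = 13.0
    covariate_score_association: bool = True
    mutation_rates: dict = field(default_factory=lambda: {
        "SF3B1": 0.165, "U2AF1": 0.080, "SRSF2": 0.136, "ZRSR2": 0.085,
        "TET2": 0.125, "ASXL1": 0.205, "TP53": 0.068,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_controls < 2:
            raise ConfigError("n_controls must be >= 2")
        for name in ("psrs_per_gene_mean", "baseline_log2_sigma", "noise_log2_sigma",
                     "aberrant_gene_rate", "nonconforming_rate",
                     "patient_severity_sigma", "junction_probe_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if any(f <= 0 for f in self.fold_change_set + self.nonconforming_fold_set):
            raise ConfigError("fold changes must be positive")
        if self.censoring_horizon_months <= 0:
            raise ConfigError("censoring horizon must be positive")
        if not 0 <= self.prognostic_carrier_rate <= 1:
            raise ConfigError("prognostic_carrier_rate must be in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for every planted aberration and the survival model.

    ``events``: one row per planted (patient, PSR) cell with the requested
    fold, the realized fold actually emitted (bitwise equal to the zero-noise
    splicing index), whether it crosses the |SI|>2 threshold, and whether the
    PSR is prognostic.  ``prognostic``: the designated events and their true
    log hazard ratios per SD.  ``patients``: severity, planted tallies and
    the true linear predictor per patient.
    """

    events: pd.DataFrame
    prognostic: pd.DataFrame
    patients: pd.DataFrame

    def super_threshold_set(self, threshold: float = 2.0) -> set[tuple[str, str]]:
        e = self.events
        mask = (e["realized_fold"] > threshold) | (e["realized_fold"] < 1.0 / threshold)
        return set(zip(e.loc[mask, "patient_id"], e.loc[mask, "psr_id"]))


@dataclass(frozen=True)
class StudyData:
    config: SimulationConfig
    annotation: PlatformAnnotation
    intensities: IntensityMatrix
    clinical: ClinicalTable
    truth: PlantedTruth
    design: CohortDesign                   # training patients vs controls
    design_validation: CohortDesign | None


# ---------------------------------------------------------------------------
# Platform
# ---------------------------------------------------------------------------

def simulate_platform(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Synthetic array design: genes with >= 3 exon PSRs plus junction sets."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shift = max(config.psrs_per_gene_mean - 3.0, 0.0)
    rows = []
    for gi in range(config.n_genes):
        gene = f"G{gi + 1:05d}"
        k = 3 + int(rng.poisson(shift))
        coding = "coding" if rng.random() < config.coding_fraction else "non_coding"
        n_junc = int(rng.poisson(config.junction_probe_rate * k))
        chrom = f"chr{(gi % 22) + 1}"
        offset = 100_000 + gi * 50_000
        for e in range(k):
            start = offset + e * 400
            rows.append((f"{gene}_PSR{e + 1:02d}", gene, e + 1, coding,
                         chrom, start, start + 150, "exon_psr"))
        for j in range(n_junc):
            ei = int(rng.integers(1, k))   # spans exon ei / ei+1 boundary
            start = offset + (ei - 1) * 400 + 150
            rows.append((f"{gene}_JUC{j + 1:02d}", gene, ei, coding,
                         chrom, start, start + 100, "junction_probe_set"))
    table = pd.DataFrame(rows, columns=[
        "psr_id", "gene_id", "exon_index", "biotype",
        "chrom", "start", "end", "region_kind"])
    return PlatformAnnotation(table)


# ---------------------------------------------------------------------------
# Intensities with planted aberrations
# ---------------------------------------------------------------------------

def _feasible(fold: float, units_deficit: float, k: int, m: int) -> bool:
    """Can this gene absorb one more plant of ``fold`` via compensation?"""
    new_m = m + 1
    if k - new_m < 2:
        return False
    new_deficit = units_deficit + (fold - 1.0)
    return abs(new_deficit) <= _MAX_COMPENSATION * (k - new_m)


def _plant_gene(values: np.ndarray, exon_rows: np.ndarray, baseline: int,
                plant_rows: list[int], folds: list[float]):
    """Integer mean-compensated plant; returns realized folds.

    ``values`` is the patient's column (modified in place); ``exon_rows``
    the row indices of the gene's exon PSRs.  The gene's sum is preserved
    exactly, so the patient gene level stays bitwise equal to baseline at
    zero noise.
    """
    b = int(baseline)
    planted_vals = [int(round(f * b)) for f in folds]
    deficit = sum(planted_vals) - b * len(planted_vals)
    others = [r for r in exon_rows if r not in plant_rows]
    q, rem = divmod(deficit, len(others))
    comp = [b - q - (1 if i < rem else 0) for i in range(len(others))]
    if min(comp) <= 0:
        raise RuntimeError("infeasible compensation; planting invariant violated")
    for r, v in zip(plant_rows, planted_vals):
        values[r] = float(v)
    for r, v in zip(others, comp):
        values[r] = float(v)
    return [v / float(b) for v in planted_vals]


def simulate_intensities(config: SimulationConfig, ann: PlatformAnnotation,
                         rng: np.random.Generator | None = None):
    """Emit the intensity matrix and planted truth for controls + patients.

    Controls are per-PSR baselines times lognormal noise; training and
    validation patients additionally carry mean-compensated planted folds.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    table = ann.table
    n_rows = len(table)
    gene_ids = table["gene_id"].unique()
    row_of = {p: i for i, p in enumerate(table["psr_id"])}
    exon_rows_of = {
        g: sub.index.to_numpy()
        for g, sub in table[table["region_kind"] == "exon_psr"].groupby("gene_id")
    }
    k_of = {g: len(r) for g, r in exon_rows_of.items()}

    # 1. per-gene integer baselines
    log2_b = rng.normal(config.baseline_log2_mu, config.baseline_log2_sigma,
                        size=len(gene_ids))
    baseline = {g: max(8, int(round(2.0 ** x))) for g, x in zip(gene_ids, log2_b)}
    plantable = [g for g in gene_ids
                 if np.log2(baseline[g]) >= config.expressed_floor_log2
                 and k_of.get(g, 0) >= 4]

    controls = [f"C{i + 1:02d}" for i in range(config.n_controls)]
    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    validation = [f"V{i + 1:03d}" for i in range(config.n_validation)]
    all_patients = patients + validation
    samples = controls + all_patients

    # 2. prognostic assignment: one designated PSR per chosen gene.  Carriers
    # of different prognostic events co-occur through a latent per-patient
    # burden factor (a shared prognostic splicing program), which preserves
    # marginal detectability of each event in a univariate screen.  The
    # default down-direction fold keeps compensation spillover in the gene's
    # sibling PSRs far below the |SI|>2 calling threshold.
    prog_rows = []
    fold = config.prognostic_fold
    k_min = max(4, 1 + int(np.ceil(abs(fold - 1.0) / _MAX_COMPENSATION)))
    if config.n_prognostic_events > 0:
        shuffled = [g for g in plantable if k_of[g] >= k_min]
        rng.shuffle(shuffled)
        if len(shuffled) < config.n_prognostic_events:
            raise ConfigError(
                "not enough expressed genes can host prognostic events; "
                "increase n_genes or psrs_per_gene_mean")
        log_hr = config.prognostic_log_hr if fold > 1 else -config.prognostic_log_hr
        for gene in shuffled[:config.n_prognostic_events]:
            psr_row = int(exon_rows_of[gene][0])
            prog_rows.append({
                "psr_id": table["psr_id"].iloc[psr_row],
                "gene_id": gene,
                "carrier_fold": fold,
                "log_hr": log_hr,
            })
    prognostic = pd.DataFrame(
        prog_rows, columns=["psr_id", "gene_id", "carrier_fold", "log_hr"])
    prog_genes = set(prognostic["gene_id"])
    burden = rng.normal(0.0, 1.0, size=len(all_patients))
    base_logit = (np.log(config.prognostic_carrier_rate
                         / (1 - config.prognostic_carrier_rate))
                  if 0 < config.prognostic_carrier_rate < 1 else None)
    carrier = {}
    for row in prognostic.itertuples():
        if base_logit is None:
            prob = np.full(len(all_patients), config.prognostic_carrier_rate)
        else:
            prob = 1 / (1 + np.exp(-(base_logit
                                     + config.prognostic_carrier_assoc * burden)))
        carrier[row.psr_id] = rng.random(len(all_patients)) < prob

    # 3. per-patient severity multipliers
    severity = rng.lognormal(mean=0.0, sigma=config.patient_severity_sigma,
                             size=len(all_patients))

    # base matrix: every cell at its gene baseline
    base_per_row = table["gene_id"].map(baseline).to_numpy(dtype=float)
    values = np.tile(base_per_row[:, None], (1, len(samples)))

    # 4. background plants per (patient, gene) + prognostic carrier plants
    background_pool = [g for g in plantable if g not in prog_genes]
    event_records = []
    mult_shift = max(config.events_per_aberrant_gene_mean - 1.0, 0.0)
    for pi, pid in enumerate(all_patients):
        col = len(controls) + pi
        s = severity[pi]
        rate = min(0.8, config.aberrant_gene_rate * s)
        planted_mask = rng.random(len(background_pool)) < rate
        for g in np.asarray(background_pool, dtype=object)[planted_mask]:
            k = k_of[g]
            m_target = 1 + int(rng.poisson(mult_shift * s))
            folds: list[float] = []
            deficit = 0.0
            exon_rows = exon_rows_of[g]
            for _ in range(min(m_target, k - 2)):
                boundary = rng.random() < config.nonconforming_rate
                pool = (list(config.nonconforming_fold_set) if boundary
                        else list(config.fold_change_set))
                rng.shuffle(pool)
                chosen = next((f for f in pool
                               if _feasible(f, deficit, k, len(folds))), None)
                if chosen is None and boundary:
                    chosen = next((f for f in sorted(config.fold_change_set)
                                   if _feasible(f, deficit, k, len(folds))), None)
                if chosen is None:
                    break
                folds.append(chosen)
                deficit += chosen - 1.0
            if not folds:
                continue
            plant_idx = rng.choice(len(exon_rows), size=len(folds), replace=False)
            plant_rows = [int(exon_rows[i]) for i in np.atleast_1d(plant_idx)]
            realized = _plant_gene(values[:, col], exon_rows, baseline[g],
                                   plant_rows, folds)
            for r, f, rf in zip(plant_rows, folds, realized):
                event_records.append({
                    "patient_id": pid,
                    "psr_id": table["psr_id"].iloc[r],
                    "gene_id": g,
                    "requested_fold": f,
                    "realized_fold": rf,
                    "prognostic": False,
                })
        for prow in prognostic.itertuples():
            if not carrier[prow.psr_id][pi]:
                continue
            g = prow.gene_id
            realized = _plant_gene(values[:, col], exon_rows_of[g], baseline[g],
                                   [row_of[prow.psr_id]], [prow.carrier_fold])
            event_records.append({
                "patient_id": pid,
                "psr_id": prow.psr_id,
                "gene_id": g,
                "requested_fold": prow.carrier_fold,
                "realized_fold": realized[0],
                "prognostic": True,
            })

    events = pd.DataFrame(event_records, columns=[
        "patient_id", "psr_id", "gene_id", "requested_fold",
        "realized_fold", "prognostic"])
    thr_hi, thr_lo = 2.0, 0.5
    events["super_threshold"] = (events["realized_fold"] > thr_hi) | (
        events["realized_fold"] < thr_lo)

    # 5. measurement noise
    if config.noise_log2_sigma > 0:
        values = values * np.exp2(
            rng.normal(0.0, config.noise_log2_sigma, size=values.shape))

    # true linear predictor: standardized log2 realized fold of prognostic events,
    # standardization over training patients only
    lp = np.zeros(len(all_patients))
    if len(prognostic):
        n_train = len(patients)
        for prow in prognostic.itertuples():
            x = np.zeros(len(all_patients))
            sub = events[(events["psr_id"] == prow.psr_id) & events["prognostic"]]
            pos = {p: i for i, p in enumerate(all_patients)}
            for rec in sub.itertuples():
                x[pos[rec.patient_id]] = np.log2(rec.realized_fold)
            mu_t = x[:n_train].mean()
            sd_t = x[:n_train].std()
            if sd_t == 0:
                continue
            lp += prow.log_hr * (x - mu_t) / sd_t

    per_patient = (events.groupby("patient_id")
                   .agg(n_planted_events=("psr_id", "size"),
                        n_planted_genes=("gene_id", "nunique")))
    patients_df = pd.DataFrame({
        "patient_id": all_patients,
        "split": ["training"] * len(patients) + ["validation"] * len(validation),
        "severity": severity,
        "prognostic_burden": burden,
        "linear_predictor": lp,
    })
    patients_df = patients_df.merge(per_patient, left_on="patient_id",
                                    right_index=True, how="left")
    patients_df[["n_planted_events", "n_planted_genes"]] = (
        patients_df[["n_planted_events", "n_planted_genes"]].fillna(0).astype(int))

    matrix = IntensityMatrix(pd.DataFrame(
        values, index=pd.Index(table["psr_id"], name="psr_id"),
        columns=pd.Index(samples, name="sample_id")))
    truth = PlantedTruth(events=events, prognostic=prognostic, patients=patients_df)
    return matrix, truth


# ---------------------------------------------------------------------------
# Survival and covariates
# ---------------------------------------------------------------------------

def simulate_survival(config: SimulationConfig, truth: PlantedTruth,
                      rng: np.random.Generator | None = None) -> ClinicalTable:
    """Exponential survival under the planted hazards, plus covariates.

    OS hazard is ``h0 * exp(lp)`` with administrative censoring at the
    horizon; leukemic change has its own baseline hazard and effect scale
    and is censored at death.  Sex and the U2AF1 flag can be tilted toward
    high event loads to emulate the reported clinical associations.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.censoring_horizon_months <= 0:
        raise ConfigError("censoring horizon must be positive")
    pats = truth.patients
    n = len(pats)
    lp = pats["linear_predictor"].to_numpy()
    H = config.censoring_horizon_months

    t_death = rng.exponential(1.0 / (config.baseline_hazard_per_month * np.exp(lp)))
    os_time = np.minimum(t_death, H)
    os_event = (t_death <= H).astype(int)
    t_lc = rng.exponential(
        1.0 / (config.ttlc_hazard_per_month * np.exp(config.ttlc_effect_scale * lp)))
    ttlc_time = np.minimum.reduce([t_lc, t_death, np.full(n, H)])
    ttlc_event = ((t_lc < t_death) & (t_lc <= H)).astype(int)

    load = pats["n_planted_events"].to_numpy(dtype=float)
    z_load = (load - load.mean()) / load.std() if load.std() > 0 else np.zeros(n)

    def _tilted_bernoulli(base_rate: float, coef: float) -> np.ndarray:
        logit = np.log(base_rate / (1 - base_rate))
        if config.covariate_score_association:
            logit = logit + coef * z_load
        return (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)

    sex_male = _tilted_bernoulli(config.male_rate, 0.5)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 19, 94).round(1)
    mut_cols = {}
    for gene, rate in config.mutation_rates.items():
        coef = 0.8 if gene == "U2AF1" else 0.0
        mut_cols[f"mut_{gene}"] = _tilted_bernoulli(rate, coef)

    rows = pd.DataFrame({
        "sample_id": pats["patient_id"],
        "cohort": "patient",
        "os_time": np.round(os_time, 4),
        "os_event": os_event,
        "ttlc_time": np.round(ttlc_time, 4),
        "ttlc_event": ttlc_event,
        "split": pats["split"].to_numpy(),
        "sex_male": sex_male,
        "age": age,
        **mut_cols,
    })
    n_ctl = config.n_controls
    ctl = pd.DataFrame({
        "sample_id": [f"C{i + 1:02d}" for i in range(n_ctl)],
        "cohort": "control",
        "os_time": H,
        "os_event": 0,
        "ttlc_time": H,
        "ttlc_event": 0,
        "split": "control",
        "sex_male": (rng.random(n_ctl) < 0.5).astype(int),
        "age": np.clip(rng.normal(40, 10, size=n_ctl), 18, 70).round(1),
        **{c: 0 for c in mut_cols},
    })
    return ClinicalTable(pd.concat([ctl, rows], ignore_index=True))


# ---------------------------------------------------------------------------
# Orchestration & truth round-trip
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> StudyData:
    """Full deterministic study: platform, intensities, truth, clinical."""
    rng = np.random.default_rng(config.seed)
    ann = simulate_platform(config, rng)
    matrix, truth = simulate_intensities(config, ann, rng)
    clinical = simulate_survival(config, truth, rng)
    train = tuple(truth.patients.loc[truth.patients["split"] == "training",
                                     "patient_id"])
    val = tuple(truth.patients.loc[truth.patients["split"] == "validation",
                                   "patient_id"])
    controls = tuple(f"C{i + 1:02d}" for i in range(config.n_controls))
    design = CohortDesign(patient_ids=train, control_ids=controls)
    design_val = CohortDesign(patient_ids=val, control_ids=controls) if val else None
    return StudyData(config=config, annotation=ann, intensities=matrix,
                     clinical=clinical, truth=truth, design=design,
                     design_validation=design_val)


def export_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Write the planted-event table as TSV (lossless float round-trip)."""
    truth.events.to_csv(path, sep="\t", index=False)


def load_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"patient_id": str, "psr_id": str, "gene_id": str})
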