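# Methods

## The statistic

`mdsplice` analyzes normalized, linear-scale exon-array intensities from a
patient cohort against a reference group of normal donors.  The array
quantifies each gene at multiple probe-selection regions (PSRs), one or more
per exon, so a change in one PSR's normalized signal relative to the rest of
its gene indicates differential exon usage — alternative splicing — rather
than a change in overall expression.

For patient *p*, PSR *a* in gene *A*:

```
linear_ratio(p, a) = [ I_p(a) / geneLevel_p(A) ] / [ I_ref(a) / geneLevel_ref(A) ]
```

where `I_ref(a)` is the mean intensity of PSR *a* across the donors and the
gene level is the arithmetic mean of the gene's exon-PSR intensities (the
patient's own profile in the numerator, the donor group in the denominator;
a median estimator is available via `estimator="median"`).  Ratios below 1
are reported as the negative reciprocal — a ratio of 1/4 becomes a splicing
index (SI) of −4 — so |SI| ≥ 1 wherever defined, and the boundary ratio of
exactly 1 maps to +1.  A (patient, PSR) cell is an **aberrant AS event**
when SI > 2 or SI < −2, with strict inequalities: an SI of exactly ±2 is
not an event.  On the linear scale this is ratio > 2 or ratio < 1/2.

A gene with at least one event in a patient is an aberrant AS gene for that
patient, and the per-patient **aberrant AS score** is total events divided
by total aberrant genes.  It is ≥ 1 whenever any event exists and measures
events per affected gene, i.e. the depth rather than breadth of splicing
disruption.  Donors are scored by leave-one-out: each donor's SI chain is
recomputed with the remaining donors as reference.

Cells are **non-analyzable** — masked, never imputed — when the gene fails
the expression filter, any gene level or the reference PSR mean is zero, or
the patient's own PSR intensity is zero (the ratio would be 0, outside the
positive domain of the conversion).  Junction probe sets are ingested and
flagged but excluded from SI computation by default, since the index is
defined on exon PSRs; gene levels are always summarized over exon PSRs only.

### Expression filter

The array software's detection-above-background call is proprietary, so
"expressed" is approximated by a configurable rule: a gene is analyzable iff
log2 of its group-mean expression is ≥ `min_log2_expr` (default 6.0) in
*both* the patient group and the donor group.  The published fraction of
expressed genes on real arrays is not expected to be reproduced by this
surrogate; all downstream guarantees are relative to whichever gene universe
the filter yields.

## Survival machinery

* **Kaplan–Meier / log-rank** are delegated to `lifelines`; the median is
  the smallest time with S(t) ≤ 0.5 (infinite when never reached).
* **Cox proportional hazards** is implemented in-package: Newton–Raphson
  with step halving on the partial likelihood, converging at gradient
  sup-norm < 1e-8, with Wald confidence intervals.  Ties use the Breslow
  convention by default (matching the major commercial statistics packages)
  with Efron available via `tie_method="efron"`.  Monotone likelihood
  (perfect separation) is flagged and the coefficient capped at |β| = 40
  instead of diverging.
* **ROC cutoff**: a per-patient score is dichotomized for survival
  prediction by scanning midpoints of adjacent sorted unique scores and
  maximizing the Youden index (sensitivity + specificity − 1); ties break
  toward the smaller threshold.  The default label is vital status at end
  of follow-up; a landmark variant (death by T months, dropping patients
  censored before T) and a log-rank-minimization scan are provided because
  the labeling behind a published cutoff of this kind is rarely stated.
* **Univariate event screen**: each candidate event PSR's signed log2 SI —
  `log2(linear_ratio)`, identically `sign(SI)·log2|SI|` — is tested in a
  univariate Cox model against overall survival, with Bonferroni correction
  over the number of events actually tested.  Zero-variance predictors are
  untestable and are excluded from both testing and the correction burden
  M; samples with a non-analyzable SI at a PSR are dropped from that PSR's
  fit.
* **Association tests** (high- vs low-score groups): Pearson χ² without
  continuity correction for 2×2 tables (this convention reproduces the
  published sex-association p = 0.024 from its printed counts exactly;
  Fisher's exact is available for sparse tables), one-way ANOVA for
  continuous variables, Pearson correlation for paired vectors.

The time-to-leukemic-change endpoint is treated as a censored time-to-event
outcome with death censoring transformation (no competing-risks model),
matching how such endpoints are usually reported with KM curves.

## The prognostic signature

Events passing the Bonferroni screen enter an ℓ1-penalized Cox regression:

minimize  −(1/n)·logPL(β) + λ‖β‖₁  (Breslow ties).

The solver is proximal Newton: the partial likelihood is expanded to second
order at the current iterate and the penalized quadratic is solved by
cyclic coordinate descent, with step halving on the true objective;
convergence tolerance 1e-7 on the coefficient step.  Predictors are
standardized internally so the penalty is scale-equitable, and coefficients
are returned on the original log2-SI scale.  Correctness is enforced in the
test suite by three independent oracles: the λ = 0 solution must match the
unpenalized Newton fit, every solution must satisfy the subgradient KKT
conditions, and the ℓ1 norm must shrink monotonically along the λ path.

λ is chosen by leave-one-out cross-validated partial likelihood
(Verweij–van Houwelingen: the full-data log partial likelihood at the
held-out fit minus the training-fold log partial likelihood, summed over
folds) over a descending geometric grid from λ_max (the smallest penalty
with an all-zero solution) to 0.01·λ_max, 50 points by default.  LOO makes
the selection deterministic — no fold randomness exists.  Ties resolve to
the larger (sparser) λ.  Folds whose training split has no events are
skipped with a warning.

The signature score is the weighted sum of the selected events' log2 SI
values; the reported score range of the modeled study is consistent with
either the converted SI or its log2, and log2 is used for coherence with
the screen.  Patients are stratified at the median training score
(lower-interpolation median for even n); the cutoff is *never* re-estimated
on a validation cohort.  The screen→LASSO two-stage order is applied once
on the full training cohort, with no re-screening inside CV folds — a known
source of optimism that mirrors the original procedure rather than
correcting it.

## Synthetic cohorts

The generator emulates the structure of an exon-array case/control study:

* **Platform**: genes with 3 + Poisson exon PSRs (mean 9.9 per gene, the
  PSR-per-gene density of the modeled array class), 85.9 % flagged coding,
  plus junction probe sets at 0.5 per exon PSR that are never planted.
* **Intensities**: one integer baseline per gene, log2-normal across genes
  (mean 8, sd 1.5); every PSR of a gene shares it.  Measurement noise is a
  per-cell log2-normal factor (default sd 0.15).
* **Planted aberrations**: multiplying a single PSR by a fold would also
  shift the patient's own gene mean and distort every SI in the gene, so
  plants are *mean-compensated*: the planted PSR takes
  `round(fold·baseline)` and the gene's remaining exon PSRs absorb the
  complement in integer amounts, keeping the patient gene level bitwise
  equal to the donor gene level at zero noise.  Planted-cell SI therefore
  equals the realized fold (`round(fold·b)/b`) exactly, including a
  boundary fold of exactly 2.0, which makes strict-threshold behavior
  testable in floating point.  A fold is only planted where compensated
  siblings stay within (0.55, 1.45)× baseline, so they can never cross the
  event threshold themselves; folds are drawn per gene from the feasible
  subset of the configured set (default {4, 3, 1/3, 1/4}, plus optional
  boundary folds {1.8, 2.0} for threshold tests).  Plants are restricted to
  genes clearly above the expression floor so every planted cell is
  analyzable.
* **Heterogeneity**: a per-patient lognormal severity multiplier scales
  both the aberrant-gene rate and the events-per-gene mean (default 2.6,
  the patients' median score in the modeled study).  Without it the score
  (events per gene) would be nearly uncorrelated with total events; with
  it, and with enough aberrant genes per patient to average out
  multiplicity noise (hundreds of genes at rate ≈ 0.1), the score–events
  correlation exceeds 0.9, qualitatively mirroring the reported r = 0.964.
* **Prognostic structure**: a configurable number of designated PSRs
  (default 13, the published signature size) carry a fold of 1/4 in
  carrier patients; carrier probability is tilted by a latent per-patient
  prognostic burden (logistic coefficient 1.0 per SD), so prognostic events
  co-occur the way a shared upstream splicing lesion would make them.  This
  correlation is what keeps each event marginally detectable in a
  univariate screen; with fully independent events, each one's marginal
  effect is diluted by the others and a Bonferroni screen at realistic n
  has little power.  The down-direction default keeps compensation
  spillover in sibling PSRs far from the calling threshold.  Survival is
  exponential with hazard `h0·exp(Σ βe·ze)` where `ze` is the standardized
  (over training patients) log2 SI of event *e* and |βe| defaults to 0.8
  per SD; OS uses h0 = 0.01/month (median ≈ 69 months at lp = 0, matching
  the low-risk arm of the modeled study), leukemic change has its own
  baseline (0.004/month) and effect scale, is censored at death, and both
  are administratively censored at 120 months.  Sex and one mutation flag
  can be tilted toward high event loads to emulate the reported clinical
  associations; all other covariates are independent.
* Cohort sizes default to the modeled study: 176 training patients, 20
  donors, 31 validation patients.  The gene count (300) is a desk-scale
  choice; tests and the acceptance script size their own simulations.

Everything derives from one `numpy` Generator seeded by `SimulationConfig.seed`
with a documented draw order (platform → baselines → prognostic assignment →
severities → background plants → noise → covariates → survival), so a fixed
seed reproduces byte-identical outputs.

### What the generator does not emulate

Probe-level hybridization physics, background correction, batch and spatial
artifacts, correlated noise within genes, competing risks, and informative
censoring.  Passing tests demonstrate that the *machinery* is correct under
the generative model's assumptions — they do not certify performance on
real arrays, where normalization quality and the expression filter dominate.

## Numerical choices

* SI conversion branch at ratio ≥ 1; strict inequalities for event calls.
* Non-analyzable cells masked (NaN), never imputed; event counts are over
  analyzable cells only; one PSR contributes at most one event per patient.
* Newton/coordinate-descent tolerances: 1e-8 (gradient, Cox), 1e-7
  (coefficient step, LASSO); separation cap |β| = 40.
* Median cutoffs use lower interpolation; ROC threshold ties break low.
* Missing clinical covariates propagate as NaN; models drop incomplete rows
  (the pipeline) or error (the library) rather than imputing.

## Known limitations

* The expression filter is a surrogate; published expressed-gene fractions
  are not reproducible from it.
* The donor reference is the per-PSR arithmetic mean across donors; if the
  original analysis referenced each donor separately, per-patient SIs would
  differ in noise characteristics.
* The screen's Wald p-values are asymptotic; rare events with few carriers
  can be unstable (separation is capped and flagged, and such predictors
  rarely survive Bonferroni).
* Selection optimism from screening outside the CV loop is inherited by
  design (see above).
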