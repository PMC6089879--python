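"""Survival and association machinery.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
contingency and group-comparison tests to scipy.  Cox proportional-hazards
regression is implemented here (Newton-Raphson on the partial likelihood)
because the analysis needs a switchable tie convention — Breslow by default,
Efron optionally — plus Wald confidence intervals, and the same Breslow
machinery is shared with the penalized fit in :mod:`mdsplice.signature`.

Also provided: the ROC-derived cutoff that dichotomizes a per-patient score
for survival stratification (Youden-J maximization by default, a
log-rank-scan variant optionally) and the Bonferroni-corrected univariate
Cox screen over per-event log2 splicing indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io import ConfigError, ValidationError
from .splicing import SplicingIndexMatrix, log2_si

__all__ = [
    "KMCurve",
    "CoxResult",
    "ROCCutoffResult",
    "ScreenResult",
    "kaplan_meier",
    "logrank_test",
    "cox_ph_fit",
    "roc_survival_cutoff",
    "univariate_event_screen",
    "contingency_chi2",
    "group_comparisons",
]

_COEF_CAP = 40.0  # |log-HR| beyond this flags monotone likelihood / separation


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: event times, S(t), risk table, median."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) at those times
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float              # smallest t with S(t) <= 0.5; inf if never

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "S": self.survival,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
        })


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier estimate with the events-before-censoring tie convention."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValidationError("kaplan_meier needs at least one record")
    if (time < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    s_at = surv.loc[ev.index].to_numpy()
    median = kmf.median_survival_time_
    return KMCurve(
        times=ev.index.to_numpy(dtype=float),
        survival=s_at,
        n_at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        median=float(median),
    )


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, two-sided p from chi2(1))."""
    ta, tb = np.asarray(time_a, float), np.asarray(time_b, float)
    ea, eb = np.asarray(event_a, int), np.asarray(event_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson, Breslow/Efron ties)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    """Per-covariate coefficients/HRs/CIs and model-level summaries."""

    summary: pd.DataFrame      # coef, hr, ci_low, ci_high, se, z, p per covariate
    loglik: float
    n: int
    n_events: int
    tie_method: str
    converged: bool
    separation: bool           # monotone-likelihood flag (coefficient capped)

    def coef(self) -> pd.Series:
        return self.summary["coef"]


def _sort_for_cox(time, event, X):
    order = np.argsort(time, kind="mergesort")
    return time[order], event[order], X[order]


def _cox_ll_grad_hess(beta, time, event, X, ties="breslow", want_hess=True):
    """Log partial likelihood, gradient and (optionally) Hessian.

    Inputs must be sorted by ascending time.  Risk sets are handled with
    reverse cumulative sums; tie groups share a risk set.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()          # rescale for overflow safety; PL is invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    # reverse cumulative sums: S0[i] = sum_{j >= i} w_j etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    if want_hess:
        wxx = wx[:, :, None] * X[:, None, :]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    # tie groups by unique time
    _, starts = np.unique(time, return_index=True)
    starts = np.sort(starts)
    bounds = np.append(starts, n)

    if ties == "breslow":
        dg = np.add.reduceat(event.astype(float), starts)
        keep = dg > 0
        sg = starts[keep]
        dgk = dg[keep]
        is_event = event == 1
        ll = float(eta[is_event].sum() - (dgk * np.log(S0[sg])).sum())
        u = S1[sg] / S0[sg][:, None]
        grad = X[is_event].sum(axis=0) - (dgk[:, None] * u).sum(axis=0)
        if not want_hess:
            return ll, grad, None
        hess = -(
            (dgk[:, None, None]
             * (S2[sg] / S0[sg][:, None, None]
                - np.einsum("gi,gj->gij", u, u))).sum(axis=0))
        return ll, grad, hess

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if want_hess else None
    for gi in range(len(starts)):
        s, e = bounds[gi], bounds[gi + 1]
        ev_idx = np.arange(s, e)[event[s:e] == 1]
        d = ev_idx.size
        if d == 0:
            continue
        ll += eta[ev_idx].sum()
        grad += X[ev_idx].sum(axis=0)
        if ties == "efron":
            s0d = w[ev_idx].sum()
            s1d = wx[ev_idx].sum(axis=0)
            if want_hess:
                s2d = (wx[ev_idx][:, :, None] * X[ev_idx][:, None, :]).sum(axis=0)
            for l in range(d):
                frac = l / d
                den = S0[s] - frac * s0d
                num1 = S1[s] - frac * s1d
                ll -= np.log(den)
                u = num1 / den
                grad -= u
                if want_hess:
                    hess -= (S2[s] - frac * s2d) / den - np.outer(u, u)
        else:
            raise ConfigError(f"unknown tie method {ties!r}")
    return ll, grad, hess


def cox_partial_loglik(beta, time, event, X, ties="breslow") -> float:
    """Unpenalized log partial likelihood at ``beta`` (any data order)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.asarray(X, float)
    t, e, x = _sort_for_cox(time, event, X)
    ll, _, _ = _cox_ll_grad_hess(np.asarray(beta, float), t, e, x,
                                 ties=ties, want_hess=False)
    return float(ll)


def cox_ph_fit(
    time,
    event,
    covariates: pd.DataFrame,
    tie_method: str = "breslow",
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Cox PH fit by Newton-Raphson with step halving.

    Converges when the gradient sup-norm drops below ``tol``.  Monotone
    likelihood (perfect separation) is flagged and the offending coefficient
    capped rather than diverging.
    """
    X = np.asarray(covariates, dtype=float)
    names = list(covariates.columns) if isinstance(covariates, pd.DataFrame) else [
        f"x{j}" for j in range(X.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.isfinite(X).all():
        raise ValidationError("covariates must be finite")
    if event.sum() < 1:
        raise ValidationError("Cox fit requires at least one event")
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = names[int(np.argmax(sds == 0))]
        raise ValidationError(f"constant covariate {bad!r}")

    t, e, x = _sort_for_cox(time, event, X)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(beta, t, e, x, ties=tie_method)
    converged = False
    separation = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step halving
        new_beta = beta + step
        for _half in range(30):
            new_ll, new_grad, new_hess = _cox_ll_grad_hess(new_beta, t, e, x, ties=tie_method)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
            new_beta = beta + step
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > _COEF_CAP:
            separation = True
            beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
            ll, grad, hess = _cox_ll_grad_hess(beta, t, e, x, ties=tie_method)
            warnings.warn("monotone partial likelihood: coefficient capped",
                          stacklevel=2)
            break
    if not converged and not separation and np.max(np.abs(grad)) >= tol:
        raise RuntimeError(
            f"Cox Newton-Raphson did not converge in {max_iter} iterations "
            f"(|grad|={np.max(np.abs(grad)):.2e})")

    cov = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    # monotone likelihood can also flatten out below the hard cap: a huge
    # coefficient with an se an order of magnitude larger is the signature
    flat = (np.abs(beta) > 15) & (se > 10 * np.abs(beta))
    if flat.any() and not separation:
        separation = True
        warnings.warn("monotone partial likelihood: coefficient unreliable "
                      "(flat likelihood); flagged as separation", stacklevel=2)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    summary = pd.DataFrame({
        "coef": beta,
        "hr": np.exp(beta),
        "ci_low": np.exp(beta - zcrit * se),
        "ci_high": np.exp(beta + zcrit * se),
        "se": se,
        "z": z,
        "p": pvals,
    }, index=pd.Index(names, name="covariate"))
    return CoxResult(
        summary=summary,
        loglik=float(ll),
        n=int(len(time)),
        n_events=int(event.sum()),
        tie_method=tie_method,
        converged=converged or separation,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# ROC-derived score cutoff
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCCutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    label_mode: str

    def classify(self, scores: pd.Series) -> pd.Series:
        return pd.Series(np.where(scores > self.cutoff, "high", "low"),
                         index=scores.index, name="risk_group")


def roc_survival_cutoff(
    scores,
    time,
    event,
    label_mode: str = "event",
    landmark_months: float | None = None,
    method: str = "youden",
) -> ROCCutoffResult:
    """Dichotomize a per-patient score for survival prediction.

    Labels: ``event`` uses vital status at end of follow-up; ``landmark``
    labels death within ``landmark_months`` (patients censored before the
    landmark are dropped).  Candidate thresholds are midpoints of adjacent
    sorted unique scores; ``youden`` maximizes sensitivity+specificity-1
    (ties toward the smaller threshold), ``logrank`` minimizes the two-group
    log-rank p over the same candidates.
    """
    scores = pd.Series(np.asarray(scores, float)) if not isinstance(scores, pd.Series) else scores
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if label_mode == "event":
        labels = event.astype(bool)
        keep = np.ones(len(scores), dtype=bool)
    elif label_mode == "landmark":
        if landmark_months is None or landmark_months <= 0:
            raise ConfigError("landmark mode needs landmark_months > 0")
        died_by = (event == 1) & (time <= landmark_months)
        followed = (time >= landmark_months) | (event == 1)
        keep = followed
        labels = died_by
    else:
        raise ConfigError(f"unknown label mode {label_mode!r}")
    s = scores.to_numpy()[keep]
    y = labels[keep]
    t_keep, e_keep = time[keep], event[keep]
    if method == "youden" and (y.all() or not y.any()):
        raise ValidationError("ROC cutoff needs both positive and negative labels")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValidationError("all scores identical; no candidate threshold")
    cand = (uniq[:-1] + uniq[1:]) / 2.0

    if method == "youden":
        pos, neg = y.sum(), (~y).sum()
        best = None
        for c in cand:                       # ties resolved toward smaller c
            pred = s > c
            sens = (pred & y).sum() / pos
            spec = (~pred & ~y).sum() / neg
            j = sens + spec - 1.0
            if best is None or j > best[0] + 1e-15:
                best = (j, c, sens, spec)
        j, c, sens, spec = best
        return ROCCutoffResult(float(c), float(sens), float(spec), float(j),
                               label_mode)
    if method == "logrank":
        best = None
        for c in cand:
            hi = s > c
            if hi.all() or not hi.any():
                continue
            if e_keep[hi].sum() + e_keep[~hi].sum() == 0:
                continue
            _, pval = logrank_test(t_keep[hi], e_keep[hi], t_keep[~hi], e_keep[~hi])
            if best is None or pval < best[0] - 1e-15:
                best = (pval, c)
        if best is None:
            raise ValidationError("no admissible threshold for log-rank scan")
        c = best[1]
        pred = s > c
        pos, neg = y.sum(), (~y).sum()
        sens = (pred & y).sum() / pos if pos else float("nan")
        spec = (~pred & ~y).sum() / neg if neg else float("nan")
        return ROCCutoffResult(float(c), float(sens), float(spec),
                               float(sens + spec - 1), label_mode)
    raise ConfigError(f"unknown cutoff method {method!r}")


# ---------------------------------------------------------------------------
# Univariate Cox screen over per-event log2 SI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    """Per-event univariate Cox screen with Bonferroni control.

    ``table`` rows (sorted by raw p): coef, hr, p_raw, p_bonferroni, passed,
    n_used.  ``m_tested`` counts the events actually tested; zero-variance
    predictors are excluded from testing and from the correction burden.
    """

    table: pd.DataFrame
    m_tested: int
    alpha: float

    @property
    def passed(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


def univariate_event_screen(
    si: SplicingIndexMatrix,
    outcomes: pd.DataFrame,
    alpha: float = 0.05,
    psr_ids=None,
    tie_method: str = "breslow",
) -> ScreenResult:
    """One univariate Cox fit per event PSR on signed log2 SI predictors.

    ``outcomes`` is a time/event frame indexed by patient id (see
    ``ClinicalTable.outcomes``).  ``psr_ids`` restricts the tested universe
    (e.g. to PSRs with at least one aberrant event); default: all PSRs of the
    SI matrix.  Samples whose SI is non-analyzable at a PSR are dropped from
    that PSR's fit.
    """
    preds = log2_si(si)
    if psr_ids is not None:
        preds = preds.loc[[p for p in psr_ids if p in preds.index]]
    patients = [p for p in preds.columns if p in outcomes.index]
    if not patients:
        raise ValidationError("no overlap between SI matrix and outcomes")
    preds = preds[patients]
    out = outcomes.loc[patients]
    rows = []
    for psr in preds.index:
        x = preds.loc[psr]
        use = x.notna().to_numpy()
        if use.sum() < 3:
            continue
        xv = x.to_numpy()[use]
        if np.std(xv) == 0:
            continue                       # untestable; excluded from M too
        tv = out["time"].to_numpy()[use]
        ev = out["event"].to_numpy()[use]
        if ev.sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = cox_ph_fit(tv, ev, pd.DataFrame({"log2_si": xv}),
                                 tie_method=tie_method)
            except (RuntimeError, np.linalg.LinAlgError):
                continue
        rows.append({
            "psr_id": psr,
            "coef": fit.summary["coef"].iloc[0],
            "hr": fit.summary["hr"].iloc[0],
            "p_raw": fit.summary["p"].iloc[0],
            "n_used": int(use.sum()),
            "separation": fit.separation,
        })
    if not rows:
        raise ValidationError("no analyzable events to screen")
    tbl = pd.DataFrame(rows).set_index("psr_id")
    m = len(tbl)
    tbl["p_bonferroni"] = np.minimum(1.0, tbl["p_raw"] * m)
    tbl["passed"] = tbl["p_bonferroni"] < alpha
    tbl = tbl.sort_values("p_raw", kind="mergesort")
    return ScreenResult(table=tbl, m_tested=m, alpha=alpha)


# ---------------------------------------------------------------------------
# Association tests
# ---------------------------------------------------------------------------

def contingency_chi2(table, method: str = "pearson") -> tuple[float, float]:
    """2x2 association test: Pearson chi2 (df=1, no continuity correction)
    or Fisher's exact two-sided."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("contingency table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("counts must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("zero margin in contingency table")
    if method == "pearson":
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return float(chi2), float(p)
    if method == "fisher":
        odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return float(odds), float(p)
    raise ConfigError(f"unknown contingency method {method!r}")


def group_comparisons(values, groups=None, y=None, kind: str = "anova") -> tuple[float, float]:
    """One-way ANOVA across groups, or Pearson correlation of paired vectors."""
    if kind == "anova":
        if groups is None:
            raise ConfigError("anova needs a grouping vector")
        values = np.asarray(values, float)
        groups = np.asarray(groups)
        arrays = [values[groups == g] for g in pd.unique(groups)]
        if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
            raise ValidationError("anova needs >=2 groups with >=2 values each")
        f, p = stats.f_oneway(*arrays)
        return float(f), float(p)
    if kind == "pearson_corr":
        x = np.asarray(values, float)
        yv = np.asarray(y, float)
        if x.shape != yv.shape:
            raise ValidationError("correlation vectors must have equal length")
        if np.std(x) == 0 or np.std(yv) == 0:
            raise ValidationError("constant vector in correlation")
        r, p = stats.pearsonr(x, yv)
        return float(r), float(p)
    raise ConfigError(f"unknown comparison kind {kind!r}")
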