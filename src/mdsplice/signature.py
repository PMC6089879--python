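"""LASSO-Cox prognostic signature construction and application.

The screen-passing aberrant-splicing events (signed log2 SI predictors)
enter an l1-penalized Cox regression fitted by cyclic coordinate descent on
the iteratively reweighted quadratic approximation of the Breslow partial
likelihood (the glmnet-style algorithm).  Predictors are standardized
internally for a scale-equitable penalty and coefficients returned on the
original log2-SI scale.  The penalty is chosen by leave-one-out
cross-validated partial likelihood (Verweij-van Houwelingen: full-data
log-likelihood at the held-out fit minus the training-fold log-likelihood),
which is deterministic — no fold randomness exists under LOO.

The fitted model is a weighted sum of the selected events' log2 SI values;
patients are stratified at the median training score (lower-interpolation
median for even n), and the cutoff is never re-estimated on validation data.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ConfigError, ValidationError
from .splicing import SplicingIndexMatrix, log2_si
from .survival import ScreenResult, _cox_ll_grad_hess, _sort_for_cox, cox_partial_loglik

__all__ = [
    "LassoCoxFit",
    "SignatureModel",
    "lasso_cox_fit",
    "lasso_lambda_max",
    "lasso_cox_path",
    "select_lambda_loocv",
    "build_signature",
    "apply_signature",
    "save_signature",
    "load_signature",
]


# ---------------------------------------------------------------------------
# Penalized Cox core
# ---------------------------------------------------------------------------

def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValidationError("constant predictor column in LASSO-Cox input")
    return (X - mu) / sd, mu, sd


def _soft_threshold(z, lam):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


@dataclass(frozen=True)
class LassoCoxFit:
    beta: np.ndarray          # original predictor scale
    beta_std: np.ndarray      # standardized scale (the penalized solution)
    lam: float
    n_iter: int
    converged: bool
    mean: np.ndarray
    sd: np.ndarray


def lasso_cox_fit(
    X,
    time,
    event,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 200,
    beta0: np.ndarray | None = None,
) -> LassoCoxFit:
    """Minimize -(1/n) log PL(beta) + lam * ||beta||_1 (Breslow ties).

    Proximal Newton: at each outer step the partial likelihood is replaced
    by its exact second-order expansion and the penalized quadratic is
    solved by cyclic coordinate descent, with step halving on the true
    objective.  ``beta0`` (standardized scale) warm-starts path fits.
    """
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not np.isfinite(X).all():
        raise ValidationError("LASSO-Cox predictors must be finite")
    if event.sum() < 1:
        raise ValidationError("LASSO-Cox requires at least one event")
    if lam < 0:
        raise ConfigError("lambda must be non-negative")
    n, p = X.shape
    Xs, mu, sd = _standardize(X)
    t, e, xs = _sort_for_cox(time, event, Xs)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()

    def objective(b):
        ll, _, _ = _cox_ll_grad_hess(b, t, e, xs, ties="breslow", want_hess=False)
        return -ll / n + lam * np.abs(b).sum()

    converged = False
    f_cur = None
    for outer in range(max_iter):
        ll, grad, hess = _cox_ll_grad_hess(beta, t, e, xs, ties="breslow")
        g = -grad / n
        H = -hess / n
        H[np.diag_indices_from(H)] += 1e-10     # guard exact singularity
        if f_cur is None:
            f_cur = -ll / n + lam * np.abs(beta).sum()
        # CD on the penalized quadratic model around beta
        b = beta.copy()
        Hd = np.zeros(p)                        # H @ (b - beta)
        for _sweep in range(10_000):
            max_delta = 0.0
            for j in range(p):
                qj = g[j] + Hd[j] - H[j, j] * (b[j] - beta[j])
                new_bj = _soft_threshold(H[j, j] * beta[j] - qj, lam) / H[j, j]
                if new_bj != b[j]:
                    Hd += H[:, j] * (new_bj - b[j])
                    max_delta = max(max_delta, abs(new_bj - b[j]))
                    b[j] = new_bj
            if max_delta < 0.1 * tol:
                break
        delta = b - beta
        step_max = np.max(np.abs(delta))
        if step_max < tol:
            converged = True
            break
        # step halving on the true objective
        scale = 1.0
        for _half in range(30):
            f_new = objective(beta + scale * delta)
            if f_new <= f_cur + 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * delta
        f_cur = f_new
        if scale * step_max < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"LASSO-Cox proximal Newton did not converge in {max_iter} "
            f"iterations (lambda={lam:.4g}, p={p}, n={n})")
    return LassoCoxFit(beta=beta / sd, beta_std=beta.copy(), lam=float(lam),
                       n_iter=outer + 1, converged=converged, mean=mu, sd=sd)


def lasso_lambda_max(X, time, event) -> float:
    """Smallest penalty at which the all-zero solution is optimal."""
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = X.shape[0]
    Xs, _, _ = _standardize(X)
    t, e, xs = _sort_for_cox(time, event, Xs)
    _, grad, _ = _cox_ll_grad_hess(np.zeros(X.shape[1]), t, e, xs,
                                   ties="breslow", want_hess=False)
    return float(np.max(np.abs(grad)) / n)


def default_lambda_grid(X, time, event, n_lambda: int = 50,
                        lambda_min_ratio: float = 0.01) -> np.ndarray:
    lmax = lasso_lambda_max(X, time, event)
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


def lasso_cox_path(X, time, event, lambdas) -> list[LassoCoxFit]:
    """Warm-started fits along a descending lambda grid."""
    lambdas = np.asarray(lambdas, float)
    if not (np.diff(lambdas) <= 1e-12).all():
        raise ConfigError("lambda grid must be descending")
    fits = []
    beta0 = None
    for lam in lambdas:
        fit = lasso_cox_fit(X, time, event, lam, beta0=beta0)
        beta0 = fit.beta_std
        fits.append(fit)
    return fits


def lasso_kkt_residuals(fit: LassoCoxFit, X, time, event) -> np.ndarray:
    """Subgradient optimality residuals on the standardized scale.

    For each j: G_j + lam*sign(beta_j) for active coefficients, and
    max(|G_j| - lam, 0) for zero ones, where G is the gradient of the
    -(1/n) log PL.  All entries are ~0 at an exact solution.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    Xs = (X - fit.mean) / fit.sd
    t, e, xs = _sort_for_cox(np.asarray(time, float), np.asarray(event, int), Xs)
    _, grad, _ = _cox_ll_grad_hess(fit.beta_std, t, e, xs, ties="breslow",
                                   want_hess=False)
    G = -grad / n
    res = np.empty_like(fit.beta_std)
    active = fit.beta_std != 0
    res[active] = G[active] + fit.lam * np.sign(fit.beta_std[active])
    res[~active] = np.maximum(np.abs(G[~active]) - fit.lam, 0.0)
    return res


# ---------------------------------------------------------------------------
# Leave-one-out penalty selection
# ---------------------------------------------------------------------------

def select_lambda_loocv(
    X,
    time,
    event,
    lambdas=None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
) -> tuple[float, pd.DataFrame]:
    """Pick lambda maximizing the LOO cross-validated partial likelihood.

    CV(lam) = sum_i [ logPL(beta_{-i}; all data) - logPL(beta_{-i}; data
    without i) ].  Folds whose training split has no events are skipped with
    a warning.  Deterministic given data and grid; ties resolve to the
    largest (sparsest) lambda because the grid is scanned descending.
    """
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = X.shape[0]
    if n < 10:
        raise ValidationError("leave-one-out penalty selection needs n >= 10")
    if lambdas is None:
        lambdas = default_lambda_grid(X, time, event, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, float)
    cv = np.zeros(len(lambdas))
    full_path = lasso_cox_path(X, time, event, lambdas)  # warm starts for folds
    n_folds_used = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if event[keep].sum() == 0:
            warnings.warn(f"fold {i}: no events in training split; skipped",
                          stacklevel=2)
            continue
        n_folds_used += 1
        for k, lam in enumerate(lambdas):
            fit = lasso_cox_fit(X[keep], time[keep], event[keep], lam,
                                beta0=full_path[k].beta_std)
            ll_full = cox_partial_loglik(fit.beta, time, event, X)
            ll_train = cox_partial_loglik(fit.beta, time[keep], event[keep], X[keep])
            cv[k] += ll_full - ll_train
    if n_folds_used == 0:
        raise ValidationError("all leave-one-out folds degenerate")
    best = int(np.argmax(cv))         # first max -> largest lambda on ties
    table = pd.DataFrame({"lambda": lambdas, "cv_loglik": cv})
    return float(lambdas[best]), table


# ---------------------------------------------------------------------------
# Signature model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureModel:
    """Selected prognostic events, their weights and the training cutoff."""

    psr_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    weights: tuple[float, ...]        # log2-SI scale
    lam: float
    cutoff: float                     # median training score, lower interpolation
    score_range: tuple[float, float]
    n_training: int
    provenance: dict = field(default_factory=dict)

    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights, index=pd.Index(self.psr_ids, name="psr_id"))


def _median_lower(values: np.ndarray) -> float:
    """Median with the lower-interpolation convention for even n."""
    return float(np.quantile(np.asarray(values, float), 0.5, method="lower"))


def _signature_predictors(si: SplicingIndexMatrix, psr_ids) -> pd.DataFrame:
    """Samples x events frame of log2 SI for the given PSRs (NaN if masked)."""
    preds = log2_si(si)
    missing = [p for p in psr_ids if p not in preds.index]
    if missing:
        raise ValidationError(f"selected PSRs missing from SI matrix: {missing}")
    return preds.loc[list(psr_ids)].T


def build_signature(
    si: SplicingIndexMatrix,
    screen: ScreenResult,
    outcomes: pd.DataFrame,
    lambdas=None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
) -> tuple[SignatureModel, pd.DataFrame]:
    """Screen pass set -> LOOCV penalty -> LASSO-Cox -> median-cutoff model.

    Returns the model plus the training score table (sample_id, score,
    risk_group).  Samples with a non-analyzable SI at any candidate event are
    dropped from training with a warning.
    """
    passed = list(screen.passed)
    if not passed:
        raise ValidationError("screen pass set is empty; no signature to build")
    Xf = _signature_predictors(si, passed)
    patients = [p for p in Xf.index if p in outcomes.index]
    Xf = Xf.loc[patients]
    complete = Xf.notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"{(~complete).sum()} sample(s) dropped from signature "
                      "training: non-analyzable SI at candidate events",
                      stacklevel=2)
    Xf = Xf[complete]
    out = outcomes.loc[Xf.index]
    X = Xf.to_numpy()
    t = out["time"].to_numpy()
    e = out["event"].to_numpy()

    lam, _cv = select_lambda_loocv(X, t, e, lambdas=lambdas, n_lambda=n_lambda,
                                   lambda_min_ratio=lambda_min_ratio)
    fit = lasso_cox_fit(X, t, e, lam)
    nz = np.flatnonzero(fit.beta != 0)
    sel_psrs = [passed[j] for j in nz]
    sel_genes = [str(si.gene_of.get(p, "")) for p in sel_psrs]
    weights = fit.beta[nz]
    scores = Xf.to_numpy()[:, nz] @ weights if len(nz) else np.zeros(len(Xf))
    cutoff = _median_lower(scores)
    prov = {
        "data_hash": hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()[:16],
        "config_hash": hashlib.sha256(
            json.dumps({"lam": lam, "n_lambda": n_lambda,
                        "lambda_min_ratio": lambda_min_ratio}, sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    model = SignatureModel(
        psr_ids=tuple(sel_psrs),
        gene_ids=tuple(sel_genes),
        weights=tuple(float(w) for w in weights),
        lam=float(lam),
        cutoff=cutoff,
        score_range=(float(scores.min()), float(scores.max())),
        n_training=int(len(scores)),
        provenance=prov,
    )
    table = pd.DataFrame({
        "score": scores,
        "risk_group": np.where(scores > cutoff, "high", "low"),
    }, index=pd.Index(Xf.index, name="sample_id"))
    return model, table


def apply_signature(model: SignatureModel, si: SplicingIndexMatrix) -> pd.DataFrame:
    """Score a cohort with a fitted signature; cutoff comes from training.

    Samples with a non-analyzable SI at any selected event are flagged and
    excluded from stratification (risk_group NaN).
    """
    if not model.psr_ids:
        raise ValidationError("signature model has no selected events")
    Xf = _signature_predictors(si, model.psr_ids)
    w = np.asarray(model.weights)
    scores = Xf.to_numpy() @ w
    flagged = Xf.isna().any(axis=1)
    out = pd.DataFrame({
        "score": scores,
        "flagged": flagged.to_numpy(),
    }, index=pd.Index(Xf.index, name="sample_id"))
    out["risk_group"] = np.where(out["flagged"], None,
                                 np.where(out["score"] > model.cutoff, "high", "low"))
    out.loc[out["flagged"], "score"] = np.nan
    return out


def save_signature(model: SignatureModel, path: str | Path) -> None:
    payload = {
        "events": [{"psr_id": p, "gene_id": g, "weight": w}
                   for p, g, w in zip(model.psr_ids, model.gene_ids, model.weights)],
        "lambda": model.lam,
        "cutoff": model.cutoff,
        "score_range": list(model.score_range),
        "n_training": model.n_training,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_signature(path: str | Path) -> SignatureModel:
    payload = json.loads(Path(path).read_text())
    events = payload["events"]
    return SignatureModel(
        psr_ids=tuple(e["psr_id"] for e in events),
        gene_ids=tuple(e["gene_id"] for e in events),
        weights=tuple(float(e["weight"]) for e in events),
        lam=float(payload["lambda"]),
        cutoff=float(payload["cutoff"]),
        score_range=tuple(payload["score_range"]),
        n_training=int(payload["n_training"]),
        provenance=payload.get("provenance", {}),
    )
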