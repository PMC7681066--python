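"""Longevity classification from protein abundance signatures.

The classifier mirrors a two-stage design: first the candidate proteins
(e.g. the 25 tier-1 longevity proteins) are reduced by backward elimination
on the between-group Mahalanobis separation, keeping the smallest set that
separates the groups essentially as well as the full set; then logistic
regression models (age-adjusted) are fitted on *every* nonempty subset of
the reduced set and combined by Bayesian model averaging with
BIC-approximated posterior model weights, ``w_m \\propto exp(-delta BIC_m / 2)``.
Classification performance is summarised by the area under the ROC curve
(midrank Mann-Whitney estimator with a DeLong confidence band), in-sample
and optionally cross-validated.

The per-model logistic fits use a compact Newton solver (thousands of
models per run make per-fit framework overhead prohibitive); it is
cross-checked against scikit-learn in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAX_SUBSET = 16  # 2^16 model cap


@dataclass
class ModelSet:
    """All-subsets logistic fits with BMA weights."""

    subset: list[str]
    models: list[tuple[int, ...]]  # indices into subset
    coefficients: list[np.ndarray]
    bic: np.ndarray
    weights: np.ndarray
    averaged_probability: np.ndarray
    n_failed: int = 0
    feature_means: np.ndarray = field(default=None, repr=False)
    feature_sds: np.ndarray = field(default=None, repr=False)


def _logistic_newton(
    X: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-8
) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood logistic fit; returns (beta, loglik, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(np.clip(y.mean(), 1e-6, 1 - 1e-6) / np.clip(1 - y.mean(), 1e-6, 1))
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X + np.eye(p) * 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, -np.inf, False
        # dampen huge steps (quasi-separation)
        norm = np.abs(step).max()
        if norm > 10:
            step *= 10 / norm
        beta += step
        if np.abs(step).max() < tol:
            eta = np.clip(X @ beta, -35, 35)
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
            converged = np.abs(beta).max() < 50  # flag separation blow-ups
            return beta, ll, converged
    return beta, -np.inf, False


def mahalanobis_separation(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-8
) -> float:
    """Between-group Mahalanobis distance with pooled within-group covariance."""
    x1, x0 = X[y == 1], X[y == 0]
    d = x1.mean(axis=0) - x0.mean(axis=0)
    S = ((len(x1) - 1) * np.cov(x1, rowvar=False) + (len(x0) - 1) * np.cov(x0, rowvar=False)) / (
        len(X) - 2
    )
    S = np.atleast_2d(S)
    S = S + np.eye(S.shape[0]) * ridge * max(np.trace(S) / S.shape[0], 1.0)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        lam = 1e-3 * np.trace(S) / S.shape[0]
        logger.warning("singular pooled covariance; ridge lambda=%.2e", lam)
        sol = np.linalg.solve(S + np.eye(S.shape[0]) * lam, d)
    return float(np.sqrt(max(d @ sol, 0.0)))


def mahalanobis_subset(
    matrix: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    candidates: list[str],
    tol: float = 0.02,
    max_size: int | None = None,
) -> list[str]:
    """Backward elimination keeping the Mahalanobis separation within
    ``(1 - tol)`` of the full candidate set's separation.

    At each step the protein whose removal least reduces the separation is
    dropped; elimination stops when any further removal would fall below
    the threshold (or, if ``max_size`` is set, continues greedily until the
    set is no larger than ``max_size``).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate proteins")
    y = np.asarray(labels, dtype=float)
    keep = list(candidates)
    full_sep = mahalanobis_separation(matrix[keep].to_numpy(float), y)
    floor = (1.0 - tol) * full_sep
    while len(keep) > 2:
        seps = [
            (mahalanobis_separation(matrix[[p for p in keep if p != drop]].to_numpy(float), y), drop)
            for drop in keep
        ]
        best_sep, best_drop = max(seps, key=lambda t: t[0])
        over_cap = max_size is not None and len(keep) > max_size
        if best_sep >= floor or over_cap:
            keep.remove(best_drop)
        else:
            break
    return keep


def all_subsets_logistic(
    matrix: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    subset: list[str],
    age: np.ndarray | pd.Series | None = None,
    feature_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> ModelSet:
    """Fit every nonempty sub-subset by ML logistic regression and average.

    Each model is age-adjusted (when ``age`` is given) and weighted by
    ``exp(-delta BIC / 2)`` under a uniform model prior; the averaged
    probability is the weight-sum of model probabilities.  Models that fail
    to converge (e.g. separation) receive weight zero.  ``feature_stats``
    (means, sds) standardizes features with training statistics during
    cross-validation.
    """
    if len(subset) > MAX_SUBSET:
        raise ValueError(f"subset of {len(subset)} exceeds the {MAX_SUBSET}-protein model cap")
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    F = matrix[subset].to_numpy(float)
    if feature_stats is None:
        mu, sd = F.mean(axis=0), F.std(axis=0, ddof=1)
    else:
        mu, sd = feature_stats
    sd = np.where(sd > 0, sd, 1.0)
    F = (F - mu) / sd
    n = len(y)
    base_cols = [np.ones(n)]
    if age is not None:
        a = np.asarray(age, dtype=float)
        base_cols.append((a - a.mean()) / (a.std(ddof=1) or 1.0))
    base = np.column_stack(base_cols)

    models, coefs, bics, probs = [], [], [], []
    n_failed = 0
    for r in range(1, len(subset) + 1):
        for combo in itertools.combinations(range(len(subset)), r):
            X = np.hstack([base, F[:, combo]])
            beta, ll, ok = _logistic_newton(X, y)
            models.append(combo)
            coefs.append(beta)
            if not ok:
                n_failed += 1
                bics.append(np.inf)
                probs.append(np.full(n, np.nan))
                continue
            bics.append(-2.0 * ll + X.shape[1] * np.log(n))
            eta = np.clip(X @ beta, -35, 35)
            probs.append(1.0 / (1.0 + np.exp(-eta)))
    bic = np.asarray(bics)
    finite = np.isfinite(bic)
    if not finite.any():
        raise RuntimeError("every candidate model failed to converge")
    w = np.zeros_like(bic)
    w[finite] = np.exp(-(bic[finite] - bic[finite].min()) / 2.0)
    w /= w.sum()
    prob_mat = np.vstack([p for p in probs])
    avg = np.nansum(prob_mat * w[:, None], axis=0)
    if n_failed:
        logger.info("%d of %d subset models failed to converge", n_failed, len(models))
    return ModelSet(
        subset=list(subset),
        models=models,
        coefficients=coefs,
        bic=bic,
        weights=w,
        averaged_probability=avg,
        n_failed=n_failed,
        feature_means=mu,
        feature_sds=sd,
    )


def predict_model_set(
    model_set: ModelSet, matrix: pd.DataFrame, age: np.ndarray | None = None
) -> np.ndarray:
    """BMA-averaged probabilities for new participants."""
    F = matrix[model_set.subset].to_numpy(float)
    F = (F - model_set.feature_means) / model_set.feature_sds
    n = len(F)
    base_cols = [np.ones(n)]
    if age is not None:
        a = np.asarray(age, dtype=float)
        base_cols.append((a - a.mean()) / (a.std(ddof=1) or 1.0))
    base = np.column_stack(base_cols)
    avg = np.zeros(n)
    for combo, beta, w in zip(model_set.models, model_set.coefficients, model_set.weights):
        if w == 0:
            continue
        X = np.hstack([base, F[:, combo]])
        eta = np.clip(X @ beta, -35, 35)
        avg += w / (1.0 + np.exp(-eta))
    return avg


def roc_auc(
    probabilities: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """AUC by the midrank Mann-Whitney estimator with a DeLong band."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(probabilities, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (stats.rankdata(np.concatenate([pos, neg]))[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (stats.rankdata(np.concatenate([neg, pos]))[:n] - stats.rankdata(neg)) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(auc - half), float(auc + half))


def bma_cv_auc(
    matrix: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    subset: list[str],
    age: np.ndarray | pd.Series | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated AUC of the BMA classifier (pooled out-of-fold scores)."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    a = None if age is None else np.asarray(age, dtype=float)
    oof = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(np.zeros(len(y)), y):
        ms = all_subsets_logistic(
            matrix.iloc[train], y[train], subset, age=None if a is None else a[train]
        )
        oof[test] = predict_model_set(
            ms, matrix.iloc[test], age=None if a is None else a[test]
        )
    auc, _ = roc_auc(oof, y)
    return auc
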