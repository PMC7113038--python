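"""Three-step radiomic feature selection ending in a LASSO signature.

Step 1 (interobserver ICC filter) lives in :mod:`radpdl1.reliability`;
this module provides step 2 (per-feature two-sample t screen) and step 3
(L1-penalized logistic regression with repeated stratified 3-fold
cross-validation choosing the penalty that maximizes mean validation AUC),
plus the conversion of the final fit into a Rad-score signature on the raw
feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .signature import RadScoreSignature


def univariate_screen(
    features: pd.DataFrame, labels, alpha: float = 0.05, equal_var: bool = True
) -> tuple[list[str], pd.DataFrame]:
    """Two-sample t-test per feature; retain p < alpha.

    ``equal_var=True`` is the pooled-variance Student's t (the classical
    default); set False for Welch. Features with zero variance in both
    classes get p = 1 with a flag. Returns (retained names, p-value table).
    """
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    records = []
    retained = []
    for col in features.columns:
        x = features[col].values.astype(float)
        a, b = x[y == 1], x[y == 0]
        flagged = False
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0
            flagged = True
        else:
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
            if not np.isfinite(p):
                p = 1.0
                flagged = True
        keep = p < alpha
        if keep:
            retained.append(col)
        records.append({"feature": col, "p_value": p, "retained": keep, "degenerate": flagged})
    return retained, pd.DataFrame(records).set_index("feature")


@dataclass
class SelectionReport:
    """Everything the three-step selection decided, for audit and reuse."""

    step1_retained: list[str]
    step2_retained: list[str]
    step2_pvalues: pd.DataFrame
    lambda_grid: np.ndarray
    mean_auc_per_lambda: np.ndarray
    chosen_lambda: float
    best_mean_auc: float
    nonzero_features: dict[str, float]   # raw-feature-scale coefficients
    intercept: float                     # raw-feature-scale intercept
    seed: int
    warnings: list[str] = field(default_factory=list)


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambdas: int, ratio: float) -> np.ndarray:
    # smallest penalty that zeroes every coefficient, glmnet-style
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(Xs.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def _l1_logistic(Xs: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn minimizes (1/C) * ||b||_1 + sum loglik; lambda = 1 / (C * n)
    C = 1.0 / (lam * len(y))
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=5000, tol=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xs, y)
    return clf


def _l1_path(Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients along a descending penalty path, warm-started (SAGA).

    Returns (coefs with shape (len(lambdas), p), intercepts). Warm starts
    make the whole path roughly as cheap as a handful of cold fits.
    """
    n = len(y)
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0, solver="saga", max_iter=300, tol=1e-4,
        warm_start=True, random_state=0,
    )
    coefs = np.empty((len(lambdas), Xs.shape[1]))
    intercepts = np.empty(len(lambdas))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            clf.C = 1.0 / (lam * n)
            clf.fit(Xs, y)
            coefs[i] = clf.coef_.ravel()
            intercepts[i] = clf.intercept_[0]
    return coefs, intercepts


def lasso_cv_select(
    features: pd.DataFrame,
    labels,
    folds: int = 3,
    repeats: int = 100,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    alpha: float = 0.05,
    step1_retained: list[str] | None = None,
    step2_table: pd.DataFrame | None = None,
) -> SelectionReport:
    """L1-penalized logistic selection with repeated stratified CV.

    For every penalty on a log-spaced grid (from the data-derived maximal
    penalty down by ``lambda_min_ratio``), the validation AUC is computed
    in each fold of ``repeats`` stratified ``folds``-fold splits; the
    chosen penalty maximizes the mean AUC over all validation folds, ties
    broken toward the larger (sparser) penalty. The final model is refit on
    all data at the chosen penalty and its coefficients are reported on the
    raw feature scale. Deterministic given ``seed``.
    """
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        raise ValueError("need at least `folds` subjects per class")
    names = list(features.columns)
    X = features.values.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe

    lambdas = _lambda_grid(Xs, y, n_lambdas, lambda_min_ratio)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(repeats)

    auc_sum = np.zeros(len(lambdas))
    auc_count = 0
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(fold_seeds[rep] % 2 ** 31))
        for train, test in skf.split(Xs, y):
            ytr, yte = y[train], y[test]
            coefs, _ = _l1_path(Xs[train], ytr, lambdas)
            scores = Xs[test] @ coefs.T  # (n_test, n_lambdas)
            for li in range(len(lambdas)):
                s = scores[:, li]
                auc_sum[li] += 0.5 if np.ptp(s) == 0 else roc_auc_score(yte, s)
            auc_count += 1
    mean_auc = auc_sum / auc_count
    best = int(np.argmax(mean_auc))  # grid is descending, argmax -> largest lambda on ties
    chosen = float(lambdas[best])

    warnings: list[str] = []
    final = _l1_logistic(Xs, y, chosen)
    beta_s = final.coef_.ravel()
    b0_s = float(final.intercept_[0])
    nz = np.flatnonzero(beta_s != 0)
    if len(nz) == 0:
        warnings.append("no nonzero coefficient at the chosen penalty; intercept-only signature")
    # back-transform z-scored coefficients to the raw feature scale
    beta_raw = beta_s / sd_safe
    intercept_raw = b0_s - float((beta_s * mu / sd_safe).sum())
    nonzero = {names[i]: float(beta_raw[i]) for i in nz}

    return SelectionReport(
        step1_retained=list(step1_retained) if step1_retained is not None else names,
        step2_retained=names,
        step2_pvalues=step2_table if step2_table is not None else pd.DataFrame(index=names),
        lambda_grid=lambdas,
        mean_auc_per_lambda=mean_auc,
        chosen_lambda=chosen,
        best_mean_auc=float(mean_auc[best]),
        nonzero_features=nonzero,
        intercept=float(intercept_raw),
        seed=seed,
        warnings=warnings,
    )


def build_signature(report: SelectionReport, cutoff: float | None = None) -> RadScoreSignature:
    """Turn a selection report into a serializable Rad-score signature."""
    return RadScoreSignature(
        intercept=report.intercept,
        coefficients=dict(report.nonzero_features),
        cutoff=cutoff,
    )
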