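"""Logistic models, DeLong c-statistic comparison, bootstrap optimism.

Implements the clinical vs clinical+radiomic model comparison: maximum-
likelihood logistic fits with Wald odds ratios, the DeLong paired test for
correlated AUCs, and resample-refit bootstrap optimism correction of the
c-index with a percentile CI for the between-model difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .signature import auc_mann_whitney

#: design columns of the clinical model, in reporting order
CLINICAL_TERMS = ("age_leq_cutoff", "female_sex", "ever_smoker", "egfr_mutant")
RADIOMIC_TERM = "radscore_positive"


@dataclass
class ModelFit:
    """One fitted logistic model with Wald inference and ROC material."""

    terms: list[str]
    params: pd.Series                  # log-odds coefficients incl. intercept
    odds_ratios: pd.DataFrame          # OR, ci_low, ci_high, p_value per term
    linear_predictor: np.ndarray       # per-subject score for ROC use
    c_statistic: float
    c_ci: tuple[float, float]
    flags: list[str] = field(default_factory=list)


def _delong_structural(scores, labels):
    """DeLong structural components (V10, V01) and AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    # midrank-based pairwise comparison
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, p in enumerate(pos):
        v10[i] = ((p > neg).sum() + 0.5 * (p == neg).sum()) / n
    for j, q in enumerate(neg):
        v01[j] = ((pos > q).sum() + 0.5 * (pos == q).sum()) / m
    auc = v10.mean()
    return auc, v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance for one score vector."""
    auc, v10, v01 = _delong_structural(scores, labels)
    m, n = len(v10), len(v01)
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(auc), float(var)


def delong_compare(scores1, scores2, labels) -> tuple[float, float, float, float]:
    """Paired DeLong test for two correlated AUCs on the same subjects.

    Returns (auc1, auc2, delta = auc2 - auc1, two-sided p). Degenerate
    variance (e.g. identical scores) yields p = 1 by convention.
    """
    y = np.asarray(labels).astype(int)
    auc1, v10_1, v01_1 = _delong_structural(scores1, y)
    auc2, v10_2, v01_2 = _delong_structural(scores2, y)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = float(auc2 - auc1)
    if var_delta <= 0:
        return float(auc1), float(auc2), delta, 1.0
    z = delta / np.sqrt(var_delta)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(auc1), float(auc2), delta, p


def fit_logistic(design: pd.DataFrame, labels) -> ModelFit:
    """ML logistic fit with Wald ORs and 95% CIs.

    ``design`` holds the covariates (no constant column); an intercept is
    added internally. Perfect separation is flagged and the CIs suppressed;
    a singular design raises.
    """
    y = np.asarray(labels).astype(int)
    X = design.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more subjects than model terms")
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        raise ValueError(f"constant covariates in design: {const_cols}")
    Xc = sm.add_constant(X, has_constant="add")
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            separated = not res.mle_retvals.get("converged", True)
            params = res.params
            se = res.bse
            pvalues = res.pvalues
        except Exception:
            # separation or singular design: faint-ridge point estimates, no Wald inference
            clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=500)
            clf.fit(X.values, y)
            coefs = np.concatenate([[clf.intercept_[0]], clf.coef_.ravel()])
            params = pd.Series(coefs, index=Xc.columns)
            se = pd.Series(np.nan, index=Xc.columns)
            pvalues = pd.Series(np.nan, index=Xc.columns)
            separated = True
    if separated or np.abs(params.values).max() > 15:
        flags.append("possible_separation")
    terms = list(X.columns)
    rows = []
    for t in terms:
        coef = float(params[t])
        if "possible_separation" in flags:
            lo = hi = np.nan
        else:
            lo = float(np.exp(coef - 1.96 * se[t]))
            hi = float(np.exp(coef + 1.96 * se[t]))
        pv = float(pvalues[t]) if "possible_separation" not in flags else np.nan
        rows.append({"term": t, "OR": float(np.exp(coef)), "ci_low": lo, "ci_high": hi, "p_value": pv})
    or_table = pd.DataFrame(rows).set_index("term")
    linpred = np.asarray(Xc.values @ params.values, dtype=float)
    if np.ptp(linpred) == 0:
        c, var = 0.5, 0.0
    else:
        c, var = delong_variance(linpred, y)
    half = 1.96 * np.sqrt(max(var, 0.0))
    return ModelFit(
        terms=terms,
        params=params,
        odds_ratios=or_table,
        linear_predictor=linpred,
        c_statistic=c,
        c_ci=(max(0.0, c - half), min(1.0, c + half)),
        flags=flags,
    )


def _stratified_resample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = np.arange(len(y))
    out = []
    for cls in (0, 1):
        members = idx[y == cls]
        out.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(out)


def _refit_linpred(X: np.ndarray, y: np.ndarray, X_eval: np.ndarray) -> np.ndarray:
    """Near-ML logistic refit robust to separation/singular designs.

    A faint L2 ridge keeps bootstrap resamples with separated or collinear
    covariates well-posed; the linear predictor (all that the c-index
    needs) is insensitive to the regularization at this strength.
    """
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return X_eval @ clf.coef_.ravel() + clf.intercept_[0]


@dataclass
class BootstrapResult:
    corrected_c1: float
    corrected_c2: float
    apparent_c1: float
    apparent_c2: float
    optimism1: float
    optimism2: float
    delta_c_ci: tuple[float, float]
    B: int
    seed: int


def bootstrap_optimism(
    design1: pd.DataFrame,
    design2: pd.DataFrame,
    labels,
    B: int = 1000,
    seed: int = 0,
    stratified: bool = True,
) -> BootstrapResult:
    """Resample-refit optimism correction for two nested logistic models.

    Each resample refits both models; optimism is the resample-apparent
    c minus the c of that refit applied to the original data, and the
    corrected c is the full-data apparent c minus the mean optimism. The
    between-model c difference gets a percentile 95% CI from the resample
    deltas. Stratified resampling avoids single-class resamples (plain
    bootstrap redraws degenerate resamples).
    """
    y = np.asarray(labels).astype(int)
    X1 = design1.values.astype(float)
    X2 = design2.values.astype(float)
    rng = np.random.default_rng(seed)
    apparent1 = auc_mann_whitney(_refit_linpred(X1, y, X1), y)
    apparent2 = auc_mann_whitney(_refit_linpred(X2, y, X2), y)
    opt1 = np.empty(B)
    opt2 = np.empty(B)
    deltas = np.empty(B)
    b = 0
    while b < B:
        idx = _stratified_resample(y, rng) if stratified else rng.integers(0, len(y), len(y))
        yb = y[idx]
        if yb.min() == yb.max():
            continue  # redraw degenerate resample
        lp1_b = _refit_linpred(X1[idx], yb, X1[idx])
        lp1_o = _refit_linpred(X1[idx], yb, X1)
        lp2_b = _refit_linpred(X2[idx], yb, X2[idx])
        lp2_o = _refit_linpred(X2[idx], yb, X2)
        c1_b = auc_mann_whitney(lp1_b, yb)
        c2_b = auc_mann_whitney(lp2_b, yb)
        opt1[b] = c1_b - auc_mann_whitney(lp1_o, y)
        opt2[b] = c2_b - auc_mann_whitney(lp2_o, y)
        deltas[b] = c2_b - c1_b
        b += 1
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return BootstrapResult(
        corrected_c1=float(apparent1 - opt1.mean()),
        corrected_c2=float(apparent2 - opt2.mean()),
        apparent_c1=float(apparent1),
        apparent_c2=float(apparent2),
        optimism1=float(opt1.mean()),
        optimism2=float(opt2.mean()),
        delta_c_ci=(float(lo), float(hi)),
        B=B,
        seed=seed,
    )


@dataclass
class ModelComparison:
    """Clinical vs clinical+radiomic logistic comparison (report material)."""

    model1: ModelFit
    model2: ModelFit
    delta_c: float
    delong_p: float
    bootstrap: BootstrapResult

    def summary_frame(self) -> pd.DataFrame:
        """The two models' ORs side by side, report-table shaped."""
        t1 = self.model1.odds_ratios.add_prefix("model1_")
        t2 = self.model2.odds_ratios.add_prefix("model2_")
        return t1.join(t2, how="outer")


def clinical_design(cohort: pd.DataFrame, age_cutoff: float) -> pd.DataFrame:
    """Clinical covariate design: age<=cutoff, female, ever-smoker, EGFR.

    Reference levels are age above the cutoff, male sex, never-smoker, and
    EGFR wild-type.
    """
    return pd.DataFrame(
        {
            "age_leq_cutoff": (cohort["age"] <= age_cutoff).astype(int),
            "female_sex": (cohort["sex"] == "F").astype(int),
            "ever_smoker": cohort["smoking"].isin(["current", "past"]).astype(int),
            "egfr_mutant": cohort["egfr_mutant"].astype(int),
        },
        index=cohort.index,
    )


def compare_models(
    cohort: pd.DataFrame,
    age_cutoff: float,
    B: int = 1000,
    seed: int = 0,
    stratified: bool = True,
) -> ModelComparison:
    """Fit the clinical and clinical+Rad-score models and compare them.

    ``cohort`` must carry the clinical columns plus a dichotomized
    ``radscore_positive`` column. Model 1 uses the four clinical terms;
    model 2 adds the Rad-score indicator. Reports c-statistics, the paired
    DeLong p, and bootstrap optimism-corrected c-indices.
    """
    if RADIOMIC_TERM not in cohort.columns:
        raise ValueError(f"cohort lacks the dichotomized Rad-score column {RADIOMIC_TERM!r}")
    y = cohort["pdl1_positive"].astype(int).values
    d1 = clinical_design(cohort, age_cutoff)
    d2 = d1.copy()
    d2[RADIOMIC_TERM] = cohort[RADIOMIC_TERM].astype(int)
    m1 = fit_logistic(d1, y)
    m2 = fit_logistic(d2, y)
    _, _, delta, p = delong_compare(m1.linear_predictor, m2.linear_predictor, y)
    boot = bootstrap_optimism(d1, d2, y, B=B, seed=seed, stratified=stratified)
    return ModelComparison(model1=m1, model2=m2, delta_c=delta, delong_p=p, bootstrap=boot)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> float:
    """2x2 association p-value: Yates chi-square, Fisher when sparse.

    Falls back to Fisher's exact test when any expected cell count is
    below 5 (the convention behind >0.999-style p-values in sparse
    contingency tables).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    if (expected < 5).any():
        return float(stats.fisher_exact(table)[1])
    return float(stats.chi2_contingency(table, correction=True)[1])
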