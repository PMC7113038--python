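"""Interobserver agreement: ICC, weighted kappa, and the ICC > 0.75 filter.

The ICC is the two-way random-effects, absolute-agreement, single-measure
form ICC(2,1), computed from the ANOVA mean squares. Negative raw ICCs are
clamped to zero before band interpretation and filtering, matching the
common reporting convention. Band thresholds: poor < 0.5, moderate
0.5-0.75, good 0.75-0.9, excellent > 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))
KAPPA_BANDS = ((0.2, "poor"), (0.4, "fair"), (0.6, "moderate"), (0.8, "good"), (np.inf, "excellent"))


def _band(value: float, bands) -> str:
    for upper, name in bands:
        if value < upper:
            return name
    return bands[-1][1]  # pragma: no cover


@dataclass
class ICCResult:
    """Single-feature agreement between two readers."""

    icc: float           # clamped at 0
    raw_icc: float
    band: str
    n_subjects: int
    flags: list[str] = field(default_factory=list)


def icc_two_way(reader1, reader2, model: str = "absolute") -> ICCResult:
    """ICC(2,1) between two readers' continuous measurements.

    ``model='absolute'`` (default) penalizes systematic reader offsets;
    ``model='consistency'`` is ICC(3,1), which does not. Zero total variance
    (both readers constant and equal) is defined as perfect agreement with
    a flag.
    """
    x = np.asarray(reader1, dtype=float)
    y = np.asarray(reader2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("readers must be equal-length 1-D arrays with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in reader measurements")
    n, k = len(x), 2
    data = np.column_stack([x, y])
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    if np.allclose(data, grand):
        return ICCResult(1.0, 1.0, "excellent", n, flags=["zero_total_variance"])
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)          # between-subjects
    msc = ss_rater / (k - 1)         # between-raters
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("model must be 'absolute' or 'consistency'")
    raw = (msr - mse) / denom if denom != 0 else 1.0
    icc = float(np.clip(raw, 0.0, 1.0))  # negative raw clamped per convention; top clip absorbs float noise
    return ICCResult(icc, float(raw), _band(icc, ICC_BANDS), n)


def weighted_kappa(reader1, reader2, n_categories: int, weights: str = "linear") -> tuple[float, str]:
    """Linearly weighted kappa for ordinal codes in 1..R.

    Returns (kappa, band). A single category used by both readers leaves
    kappa undefined and raises ValueError.
    """
    r1 = np.asarray(reader1, dtype=int)
    r2 = np.asarray(reader2, dtype=int)
    if r1.shape != r2.shape:
        raise ValueError("readers must have equal length")
    if (r1 < 1).any() or (r1 > n_categories).any() or (r2 < 1).any() or (r2 > n_categories).any():
        raise ValueError(f"codes must lie in 1..{n_categories}")
    used = set(r1) | set(r2)
    if len(used) < 2:
        raise ValueError("kappa undefined: a single category used by both readers")
    kappa = float(
        cohen_kappa_score(r1, r2, labels=np.arange(1, n_categories + 1), weights=weights)
    )
    return kappa, _band(kappa, KAPPA_BANDS)


def reliability_filter(
    features_reader1: pd.DataFrame,
    features_reader2: pd.DataFrame,
    threshold: float = 0.75,
    model: str = "absolute",
) -> tuple[list[str], pd.DataFrame]:
    """Retain features whose clamped ICC strictly exceeds ``threshold``.

    Both frames must share subjects (index) and feature columns. Returns
    (retained feature names in input order, per-feature ICC report).
    """
    if list(features_reader1.columns) != list(features_reader2.columns):
        raise ValueError("reader feature tables have different columns")
    if not features_reader1.index.equals(features_reader2.index):
        raise ValueError("reader feature tables have different subjects")
    records = []
    retained = []
    for col in features_reader1.columns:
        res = icc_two_way(features_reader1[col].values, features_reader2[col].values, model=model)
        keep = res.icc > threshold
        if keep:
            retained.append(col)
        records.append(
            {
                "feature": col,
                "icc": res.icc,
                "raw_icc": res.raw_icc,
                "band": res.band,
                "retained": keep,
            }
        )
    return retained, pd.DataFrame(records).set_index("feature")
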