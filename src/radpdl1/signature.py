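"""Rad-score signatures, ROC/Youden cutoff analysis, and dichotomization.

A Rad-score is a linear combination of selected radiomic features weighted
by their penalized-regression coefficients. The published signature of the
study this package reproduces is shipped as a frozen fixture
(``data/published_signature.json``) with its classification cutoff -0.715:

    Rad-score = -1.59423
                - 8.49568 * Texture_GLCM_ASM
                + 3.58597 * Texture_GLRLM_RV
                - 5.01416 * Texture_GLRLM_RE
                + 0.05253 * Texture_GLRLM_SRHGE
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .catalogue import ALL_FEATURES


@dataclass
class RadScoreSignature:
    """Intercept + named feature coefficients + optional score cutoff."""

    intercept: float
    coefficients: dict[str, float]
    cutoff: float | None = None
    version: str = "unversioned"

    def __post_init__(self) -> None:
        unknown = [n for n in self.coefficients if n not in ALL_FEATURES]
        if unknown:
            raise ValueError(f"coefficients on non-catalogue features: {unknown}")
        if self.cutoff is not None and not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite when set")

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "cutoff": self.cutoff,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RadScoreSignature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            cutoff=payload.get("cutoff"),
            version=payload.get("version", "unversioned"),
        )


def published_signature() -> RadScoreSignature:
    """The frozen published signature (4 features, cutoff -0.715)."""
    with resources.files("radpdl1.data").joinpath("published_signature.json").open() as fh:
        payload = json.load(fh)
    return RadScoreSignature(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        cutoff=payload.get("cutoff"),
        version=payload.get("version", "unversioned"),
    )


def rad_score(sig: RadScoreSignature, features) -> float | np.ndarray:
    """Evaluate the signature: intercept + sum(coef * feature value).

    ``features`` may be a mapping/Series (one subject -> float) or a
    DataFrame (one row per subject -> array). Missing signature features
    raise KeyError naming the feature.
    """
    if isinstance(features, pd.DataFrame):
        missing = [n for n in sig.coefficients if n not in features.columns]
        if missing:
            raise KeyError(f"features missing from table: {missing}")
        score = np.full(len(features), sig.intercept, dtype=float)
        for name, coef in sig.coefficients.items():
            vals = features[name].values.astype(float)
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite values in feature {name!r}")
            score += coef * vals
        return score
    total = float(sig.intercept)
    for name, coef in sig.coefficients.items():
        if name not in features:
            raise KeyError(f"feature missing: {name!r}")
        v = float(features[name])
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for feature {name!r}")
        total += coef * v
    return total


def auc_mann_whitney(scores, labels) -> float:
    """Concordance AUC via midranks (handles ties)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """ROC-optimal cutoff by the Youden index.

    Candidate cutoffs are midpoints between consecutive distinct scores
    (classification rule: score > cutoff -> positive). Ties in the Youden
    index are broken toward higher specificity (the larger cutoff).
    Returns (cutoff, sensitivity, specificity, auc).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("cutoff undefined: all scores identical")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n1 = int(y.sum())
    n0 = len(y) - n1
    best = None
    for c in candidates:
        pred = s > c
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        # integer-scaled Youden index (tp/n1 + tn/n0 - 1) avoids float ties
        j_scaled = tp * n0 + tn * n1
        # on ties keep the larger cutoff (higher specificity)
        if best is None or j_scaled > best[0] or (j_scaled == best[0] and c > best[1]):
            best = (j_scaled, float(c), tp / n1, tn / n0)
    _, cutoff, sens, spec = best
    return cutoff, sens, spec, auc_mann_whitney(s, y)


def dichotomize(values, cutoff: float, direction: str = "greater") -> np.ndarray:
    """Binary indicators from a continuous variable at a fixed cutoff.

    ``direction='greater'`` encodes value > cutoff (Rad-score positivity;
    a value exactly at the cutoff is negative); ``direction='leq'`` encodes
    value <= cutoff (the "age <= cutoff years" convention).
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    if direction == "greater":
        return (v > cutoff).astype(int)
    if direction == "leq":
        return (v <= cutoff).astype(int)
    raise ValueError("direction must be 'greater' or 'leq'")
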