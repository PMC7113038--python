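"""The 58-feature radiomic catalogue computed from a segmented 3-D volume.

Categories: 15 histogram, 2 gradient, 13 GLCM, 13 GLRLM, 3 moment,
11 shape, 1 fractal. :func:`extract_all` evaluates all of them and returns
a :class:`FeatureVector` in the fixed catalogue order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..catalogue import ALL_FEATURES, CATEGORY_COUNTS
from ..volume_io import VolumeWithMask
from .intensity import gradient_features, histogram_features, moment_features
from .shape import fractal_dimension, shape_features
from .texture import (
    OFFSETS_3D,
    DiscretizedVOI,
    discretize,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    run_length_matrix,
)

__all__ = [
    "DiscretizedVOI",
    "FeatureVector",
    "OFFSETS_3D",
    "discretize",
    "extract_all",
    "fractal_dimension",
    "glcm_features",
    "glcm_matrix",
    "glrlm_features",
    "gradient_features",
    "histogram_features",
    "moment_features",
    "run_length_matrix",
    "shape_features",
]


@dataclass
class FeatureVector:
    """The 58 named feature values for one VOI, plus degeneracy flags."""

    values: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [n for n in ALL_FEATURES if n not in self.values]
        if missing:
            raise ValueError(f"feature vector missing {missing[:3]}... ({len(missing)} total)")
        self.values = {n: float(self.values[n]) for n in ALL_FEATURES}
        bad = [n for n, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def extract_all(voi: VolumeWithMask, G: int = 32) -> FeatureVector:
    """Compute all 58 catalogue features for one volume-of-interest.

    ``G`` is the number of gray levels for the texture discretization.
    Sub-computations that hit degenerate geometry contribute flags rather
    than NaNs; errors are re-raised with the failing category named.
    """
    values: dict[str, float] = {}
    flags: list[str] = []
    dvoi = discretize(voi, G)
    if dvoi.degenerate:
        flags.append("degenerate_texture")
    stages = [
        ("histogram", lambda: histogram_features(voi, dvoi)),
        ("gradient", lambda: gradient_features(voi)),
        ("glcm", lambda: glcm_features(dvoi)),
        ("glrlm", lambda: glrlm_features(dvoi)),
        ("moment", lambda: moment_features(voi)),
        ("shape", lambda: shape_features(voi)),
        ("fractal", lambda: fractal_dimension(voi)),
    ]
    for name, fn in stages:
        try:
            vals, fl = fn()
        except Exception as exc:
            raise type(exc)(f"{name} features: {exc}") from exc
        assert len(vals) == CATEGORY_COUNTS[name]
        values.update(vals)
        flags.extend(fl)
    return FeatureVector(values, flags)
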