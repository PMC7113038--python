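"""First-order (histogram), gradient, and geometric-moment features."""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..volume_io import VolumeWithMask
from .texture import DiscretizedVOI


def histogram_features(voi: VolumeWithMask, dvoi: DiscretizedVOI) -> tuple[dict, list[str]]:
    """15 first-order features.

    Location/scale/extreme statistics and percentiles are computed on the
    raw HU values (linear-interpolated percentiles); Energy and Entropy on
    the G-level discretized histogram, which makes them independent of the
    HU scale. A constant VOI returns skewness/kurtosis of 0 with a flag.
    """
    flags: list[str] = []
    x = voi.inside()
    if x.size < 2:
        raise ValueError("histogram features need at least 2 in-mask voxels")
    sd = float(np.std(x, ddof=1))
    if sd > 0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))  # excess (Fisher)
    else:
        skew = kurt = 0.0
        flags.append("histo_constant")
    lv = dvoi.levels[dvoi.mask]
    p = np.bincount(lv, minlength=dvoi.G + 1)[1:].astype(float)
    p /= p.sum()
    nz = p > 0
    energy = float((p ** 2).sum())
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    pct = np.percentile(x, [10, 25, 50, 75, 90, 95])
    values = {
        "Texture_Histo_Mean": float(x.mean()),
        "Texture_Histo_SD": sd,
        "Texture_Histo_Skewness": skew,
        "Texture_Histo_ExcessKurtosis": kurt,
        "Texture_Histo_Energy": energy,
        "Texture_Histo_Entropy": entropy,
        "Texture_Histo_Min": float(x.min()),
        "Texture_Histo_Max": float(x.max()),
        "Texture_Histo_VoxelCount": float(x.size),
        "Texture_Percentile_10": float(pct[0]),
        "Texture_Percentile_25": float(pct[1]),
        "Texture_Percentile_50": float(pct[2]),
        "Texture_Percentile_75": float(pct[3]),
        "Texture_Percentile_90": float(pct[4]),
        "Texture_Percentile_95": float(pct[5]),
    }
    return values, flags


def _masked_axis_derivative(intens: np.ndarray, mask: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Finite-difference derivative along one axis using in-mask neighbours only.

    Central differences where both neighbours are in the mask, one-sided
    where only one is, zero where neither is. Background voxels never
    contribute, so a constant VOI has exactly zero gradient.
    """
    fwd_val = np.roll(intens, -1, axis=axis)
    bwd_val = np.roll(intens, 1, axis=axis)
    fwd_ok = np.roll(mask, -1, axis=axis)
    bwd_ok = np.roll(mask, 1, axis=axis)
    # rolled-over boundary voxels are invalid
    edge = [slice(None)] * 3
    edge[axis] = slice(-1, None)
    fwd_ok[tuple(edge)] = False
    edge[axis] = slice(0, 1)
    bwd_ok[tuple(edge)] = False

    deriv = np.zeros_like(intens)
    both = fwd_ok & bwd_ok
    deriv[both] = (fwd_val[both] - bwd_val[both]) / (2.0 * h)
    fonly = fwd_ok & ~bwd_ok
    deriv[fonly] = (fwd_val[fonly] - intens[fonly]) / h
    bonly = bwd_ok & ~fwd_ok
    deriv[bonly] = (intens[bonly] - bwd_val[bonly]) / h
    return deriv


def gradient_features(voi: VolumeWithMask) -> tuple[dict, list[str]]:
    """Mean and SD of the 3-D gradient magnitude (HU/mm) over in-mask voxels.

    Differences are taken between in-mask voxels only so the tumor/background
    edge does not leak into the statistics.
    """
    mags2 = np.zeros_like(voi.intensities)
    for ax in range(3):
        d = _masked_axis_derivative(voi.intensities, voi.mask, ax, voi.spacing_mm[ax])
        mags2 += d ** 2
    g = np.sqrt(mags2[voi.mask])
    sd = float(np.std(g, ddof=1)) if g.size > 1 else 0.0
    return {"Texture_Grad_Mean": float(g.mean()), "Texture_Grad_SD": sd}, []


def moment_features(voi: VolumeWithMask) -> tuple[dict, list[str]]:
    """Rotation invariants J1-J3 of the intensity-weighted second-moment matrix.

    The matrix is the weight-normalized central covariance of in-mask voxel
    positions (physical mm coordinates), weighted by intensity. J1 = trace,
    J2 = sum of principal 2x2 minors, J3 = determinant; all invariant under
    grid rotation by construction. Non-positive HU weights are shifted to
    I - min(I) + 1 (flagged); a constant-zero weight field falls back to
    uniform weights.
    """
    flags: list[str] = []
    coords = np.argwhere(voi.mask).astype(float) * np.asarray(voi.spacing_mm)
    w = voi.inside().copy()
    if w.min() <= 0:
        w = w - w.min() + 1.0
        flags.append("moment_intensity_shift")
    total = w.sum()
    if total <= 0:  # pragma: no cover - shift above guarantees positivity
        w = np.ones_like(w)
        total = w.sum()
        flags.append("moment_uniform_weights")
    centroid = (coords * w[:, None]).sum(axis=0) / total
    dc = coords - centroid
    m = (dc.T * w) @ dc / total
    j1 = float(np.trace(m))
    j2 = float(0.5 * (np.trace(m) ** 2 - np.trace(m @ m)))
    j3 = float(np.linalg.det(m))
    return {"Texture_Moment_J1": j1, "Texture_Moment_J2": j2, "Texture_Moment_J3": j3}, flags
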