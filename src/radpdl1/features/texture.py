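"""Gray-level discretization, GLCM and GLRLM texture features.

Texture is computed on an equal-width discretization of the in-mask HU
range into G levels (default 32). Co-occurrence uses the 13 unique
distance-1 direction offsets of the 3-D 26-neighbourhood; counts are
symmetrized and pooled over directions before feature computation.
Run-length matrices are computed per direction and the 13 per-direction
feature values are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume_io import VolumeWithMask

#: the 13 unique 3-D offsets at Chebyshev distance 1 (one per +/- pair)
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(OFFSETS_3D) == 13


@dataclass
class DiscretizedVOI:
    """Integer gray levels 1..G inside the mask (0 outside)."""

    levels: np.ndarray          # int array, full grid, 0 outside mask
    G: int
    bin_edges: np.ndarray       # HU, length G+1, strictly increasing unless degenerate
    mask: np.ndarray
    degenerate: bool = False    # constant in-mask intensities


def discretize(voi: VolumeWithMask, G: int = 32) -> DiscretizedVOI:
    """Equal-width binning of in-mask HU values into levels 1..G.

    Bins cover [min, max] of the in-mask intensities; bins are half-open on
    the right except the last, so the maximum maps to level G. A constant
    VOI yields a single-level result with the ``degenerate`` flag set.
    """
    if G < 2:
        raise ValueError("G must be >= 2")
    if voi.n_voxels < 2:
        raise ValueError("mask must contain at least 2 voxels")
    inside = voi.inside()
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(voi.mask.shape, dtype=np.int32)
    if hi <= lo:
        levels[voi.mask] = 1
        edges = np.linspace(lo, lo + 1.0, G + 1)
        return DiscretizedVOI(levels, G, edges, voi.mask, degenerate=True)
    width = (hi - lo) / G
    lv = np.floor((inside - lo) / width).astype(np.int32) + 1
    np.clip(lv, 1, G, out=lv)
    levels[voi.mask] = lv
    edges = np.linspace(lo, hi, G + 1)
    return DiscretizedVOI(levels, G, edges, voi.mask)


def _pair_counts(levels: np.ndarray, G: int, offset) -> np.ndarray:
    """Raw (unsymmetrized) co-occurrence counts for one offset."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        if d > 0:
            src[ax], dst[ax] = slice(None, -d), slice(d, None)
        elif d < 0:
            src[ax], dst[ax] = slice(-d, None), slice(None, d)
    a = levels[tuple(src)]
    b = levels[tuple(dst)]
    valid = (a > 0) & (b > 0)
    ai = a[valid] - 1
    bi = b[valid] - 1
    counts = np.bincount(ai * G + bi, minlength=G * G)
    return counts.reshape(G, G).astype(float)


def glcm_matrix(dvoi: DiscretizedVOI, offsets=OFFSETS_3D) -> np.ndarray:
    """Symmetrized, direction-pooled, normalized co-occurrence matrix."""
    G = dvoi.G
    total = np.zeros((G, G))
    for off in offsets:
        c = _pair_counts(dvoi.levels, G, off)
        total += c + c.T
    s = total.sum()
    if s > 0:
        total /= s
    return total


def glcm_features(dvoi: DiscretizedVOI, offsets=OFFSETS_3D) -> tuple[dict, list[str]]:
    """The 13 GLCM features from the pooled co-occurrence matrix.

    Returns (feature dict, flags). A degenerate (single-level) VOI yields
    the constant-texture values (ASM=1, entropies/contrast 0) with a flag;
    zero marginal variance defines Correlation as 0 with a flag.
    """
    flags: list[str] = []
    G = dvoi.G
    p = glcm_matrix(dvoi, offsets)
    if dvoi.degenerate:
        flags.append("glcm_degenerate")
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    nz = p > 0
    asm = float((p ** 2).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    homog = float((p / (1.0 + np.abs(ii - jj))).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var > 0:
        corr = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    else:
        corr = 0.0
        flags.append("glcm_zero_variance")
    autocor = float((ii * jj * p).sum())
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    dev = ii + jj - 2.0 * mu
    cp = float((dev ** 4 * p).sum())
    cs = float((dev ** 3 * p).sum())
    ct = float((dev ** 2 * p).sum())

    # p_{x+y}: distribution of i+j (2..2G); p_{|x-y|}: of |i-j| (0..G-1)
    ssum = np.zeros(2 * G + 1)
    np.add.at(ssum, (ii + jj).ravel(), p.ravel())
    snz = ssum > 0
    sum_entropy = float(-(ssum[snz] * np.log2(ssum[snz])).sum())
    d = np.zeros(G)
    np.add.at(d, np.abs(ii - jj).ravel(), p.ravel())
    dnz = d > 0
    k = np.arange(G)
    diff_average = float((k * d).sum())
    diff_entropy = float(-(d[dnz] * np.log2(d[dnz])).sum())

    values = {
        "Texture_GLCM_ASM": asm,
        "Texture_GLCM_IDM": idm,
        "Texture_GLCM_Homogeneity": homog,
        "Texture_GLCM_Contrast": contrast,
        "Texture_GLCM_Correlation": corr,
        "Texture_GLCM_Autocor": autocor,
        "Texture_GLCM_Entropy": entropy,
        "Texture_GLCM_CP": cp,
        "Texture_GLCM_CS": cs,
        "Texture_GLCM_CT": ct,
        "Texture_GLCM_SumEntropy": sum_entropy,
        "Texture_GLCM_DiffAverage": diff_average,
        "Texture_GLCM_DiffEntropy": diff_entropy,
    }
    return values, flags


def run_length_matrix(dvoi: DiscretizedVOI, offset) -> np.ndarray:
    """Run-length matrix r(i, j) for one direction.

    r[i-1, j-1] counts maximal runs of in-mask voxels with level i and
    length j along ``offset``; out-of-mask voxels break runs.
    """
    levels = dvoi.levels
    coords = np.argwhere(levels > 0)
    lv = levels[levels > 0]
    d = np.asarray(offset)
    ax0 = int(np.flatnonzero(d)[0])
    # position along the line: increments by exactly 1 per step of `d`
    k = coords[:, ax0] * d[ax0]
    base = coords - k[:, None] * d
    order = np.lexsort((k, base[:, 2], base[:, 1], base[:, 0]))
    ks, bs, ls = k[order], base[order], lv[order]
    n = len(ks)
    new_run = np.ones(n, dtype=bool)
    if n > 1:
        same_line = (bs[1:] == bs[:-1]).all(axis=1)
        new_run[1:] = ~(same_line & (ks[1:] == ks[:-1] + 1) & (ls[1:] == ls[:-1]))
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, n))
    run_levels = ls[starts]
    max_len = int(lengths.max())
    r = np.zeros((dvoi.G, max_len))
    np.add.at(r, (run_levels - 1, lengths - 1), 1.0)
    return r


def _glrlm_single(r: np.ndarray, n_voxels: int) -> dict:
    G, L = r.shape
    i = np.arange(1, G + 1, dtype=float)[:, None]
    j = np.arange(1, L + 1, dtype=float)[None, :]
    n_runs = r.sum()
    ri = r.sum(axis=1)   # runs per gray level
    rj = r.sum(axis=0)   # runs per length
    jv = np.arange(1, L + 1, dtype=float)
    p = r / n_runs
    mean_j = float((p.sum(axis=0) * jv).sum())
    nz = p > 0
    return {
        "Texture_GLRLM_SRE": float((r / j ** 2).sum() / n_runs),
        "Texture_GLRLM_LRE": float((r * j ** 2).sum() / n_runs),
        "Texture_GLRLM_LGRE": float((r / i ** 2).sum() / n_runs),
        "Texture_GLRLM_HGRE": float((r * i ** 2).sum() / n_runs),
        "Texture_GLRLM_SRLGE": float((r / (i ** 2 * j ** 2)).sum() / n_runs),
        "Texture_GLRLM_SRHGE": float((r * i ** 2 / j ** 2).sum() / n_runs),
        "Texture_GLRLM_LRLGE": float((r * j ** 2 / i ** 2).sum() / n_runs),
        "Texture_GLRLM_LRHGE": float((r * i ** 2 * j ** 2).sum() / n_runs),
        "Texture_GLRLM_GNUN": float((ri ** 2).sum() / n_runs ** 2),
        "Texture_GLRLM_RLNUN": float((rj ** 2).sum() / n_runs ** 2),
        "Texture_GLRLM_RP": float(n_runs / n_voxels),
        "Texture_GLRLM_RV": float((p.sum(axis=0) * (jv - mean_j) ** 2).sum()),
        "Texture_GLRLM_RE": float(-(p[nz] * np.log2(p[nz])).sum()),
    }


def glrlm_features(dvoi: DiscretizedVOI, offsets=OFFSETS_3D) -> tuple[dict, list[str]]:
    """The 13 GLRLM features, averaged over the per-direction matrices."""
    flags: list[str] = []
    if dvoi.degenerate:
        flags.append("glrlm_degenerate")
    n_voxels = int((dvoi.levels > 0).sum())
    acc: dict[str, float] = {}
    for off in offsets:
        r = run_length_matrix(dvoi, off)
        vals = _glrlm_single(r, n_voxels)
        for k, v in vals.items():
            acc[k] = acc.get(k, 0.0) + v
    return {k: v / len(offsets) for k, v in acc.items()}, flags
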