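"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit Python loops,
no shared code with the package) so it can serve as an oracle for the
vectorized implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def glcm_matrix_bruteforce(levels: np.ndarray, G: int, offsets=None) -> np.ndarray:
    """Symmetrized pooled co-occurrence probabilities by explicit voxel loops."""
    offsets = offsets or OFFSETS
    p = np.zeros((G, G))
    nx, ny, nz = levels.shape
    for off in offsets:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    a = levels[x, y, z]
                    if a == 0:
                        continue
                    x2, y2, z2 = x + off[0], y + off[1], z + off[2]
                    if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                        continue
                    b = levels[x2, y2, z2]
                    if b == 0:
                        continue
                    p[a - 1, b - 1] += 1
                    p[b - 1, a - 1] += 1
    total = p.sum()
    if total > 0:
        p /= total
    return p


def glcm_features_bruteforce(levels: np.ndarray, G: int, offsets=None) -> dict:
    p = glcm_matrix_bruteforce(levels, G, offsets)
    mu = sum((i + 1) * p[i, :].sum() for i in range(G))
    var = sum((i + 1 - mu) ** 2 * p[i, :].sum() for i in range(G))
    out = dict.fromkeys(
        "ASM IDM Homogeneity Contrast Correlation Autocor Entropy CP CS CT".split(), 0.0
    )
    psum = np.zeros(2 * G + 1)
    pdiff = np.zeros(G)
    for i in range(G):
        for j in range(G):
            v = p[i, j]
            ii, jj = i + 1, j + 1
            out["ASM"] += v * v
            out["IDM"] += v / (1 + (ii - jj) ** 2)
            out["Homogeneity"] += v / (1 + abs(ii - jj))
            out["Contrast"] += (ii - jj) ** 2 * v
            out["Autocor"] += ii * jj * v
            if v > 0:
                out["Entropy"] -= v * np.log2(v)
            dev = ii + jj - 2 * mu
            out["CP"] += dev ** 4 * v
            out["CS"] += dev ** 3 * v
            out["CT"] += dev ** 2 * v
            if var > 0:
                out["Correlation"] += (ii - mu) * (jj - mu) * v / var
            psum[ii + jj] += v
            pdiff[abs(ii - jj)] += v
    out["SumEntropy"] = -sum(q * np.log2(q) for q in psum if q > 0)
    out["DiffAverage"] = sum(k * pdiff[k] for k in range(G))
    out["DiffEntropy"] = -sum(q * np.log2(q) for q in pdiff if q > 0)
    return {f"Texture_GLCM_{k}": float(v) for k, v in out.items()}


def runs_bruteforce(levels: np.ndarray, offset) -> list[tuple[int, int]]:
    """All maximal runs (level, length) along one direction, by walking."""
    nx, ny, nz = levels.shape
    d = np.asarray(offset)
    runs = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = levels[x, y, z]
                if v == 0:
                    continue
                # start of run: predecessor absent or different
                px, py, pz = x - d[0], y - d[1], z - d[2]
                if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz and levels[px, py, pz] == v:
                    continue
                length = 1
                cx, cy, cz = x + d[0], y + d[1], z + d[2]
                while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz and levels[cx, cy, cz] == v:
                    length += 1
                    cx, cy, cz = cx + d[0], cy + d[1], cz + d[2]
                runs.append((int(v), length))
    return runs


def glrlm_features_bruteforce(levels: np.ndarray, G: int, offsets=None) -> dict:
    offsets = offsets or OFFSETS
    n_voxels = int((levels > 0).sum())
    acc: dict[str, float] = {}
    for off in offsets:
        runs = runs_bruteforce(levels, off)
        n_runs = len(runs)
        f = dict.fromkeys(
            "SRE LRE LGRE HGRE SRLGE SRHGE LRLGE LRHGE GNUN RLNUN RP RV RE".split(), 0.0
        )
        by_level: dict[int, int] = {}
        by_length: dict[int, int] = {}
        for i, j in runs:
            f["SRE"] += 1 / j ** 2
            f["LRE"] += j ** 2
            f["LGRE"] += 1 / i ** 2
            f["HGRE"] += i ** 2
            f["SRLGE"] += 1 / (i ** 2 * j ** 2)
            f["SRHGE"] += i ** 2 / j ** 2
            f["LRLGE"] += j ** 2 / i ** 2
            f["LRHGE"] += i ** 2 * j ** 2
            by_level[i] = by_level.get(i, 0) + 1
            by_length[j] = by_length.get(j, 0) + 1
        for k in "SRE LRE LGRE HGRE SRLGE SRHGE LRLGE LRHGE".split():
            f[k] /= n_runs
        f["GNUN"] = sum(c ** 2 for c in by_level.values()) / n_runs ** 2
        f["RLNUN"] = sum(c ** 2 for c in by_length.values()) / n_runs ** 2
        f["RP"] = n_runs / n_voxels
        mean_j = sum(j for _, j in runs) / n_runs
        f["RV"] = sum((j - mean_j) ** 2 for _, j in runs) / n_runs
        from collections import Counter

        cell = Counter(runs)
        f["RE"] = -sum((c / n_runs) * np.log2(c / n_runs) for c in cell.values())
        for k, v in f.items():
            acc[k] = acc.get(k, 0.0) + v
    return {f"Texture_GLRLM_{k}": float(v / len(offsets)) for k, v in acc.items()}


def auc_bruteforce(scores, labels) -> float:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins) / (pos.size * neg.size)


def youden_bruteforce(scores, labels):
    """Exhaustive search over every real cutoff (all midpoints and extremes)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    distinct = np.unique(s)
    candidates = list((distinct[:-1] + distinct[1:]) / 2.0)
    candidates += [distinct[0] - 1.0, distinct[-1] + 1.0]
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    best = None
    for c in candidates:
        sens = ((s > c) & (y == 1)).sum() / n1
        spec = ((s <= c) & (y == 0)).sum() / n0
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
        elif abs(j - best[0]) <= 1e-12 and c > best[1]:
            best = (j, c, sens, spec)
    return best  # (J, cutoff, sens, spec)


def delong_p_permutation(scores1, scores2, labels, n_perm=5000, seed=0) -> float:
    """Permutation p-value for the difference of paired AUCs.

    Null: the two score vectors are exchangeable within subject, so each
    subject's pair is swapped with probability 1/2.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = np.asarray(labels).astype(int)
    obs = abs(auc_bruteforce(s2, y) - auc_bruteforce(s1, y))
    rng = np.random.default_rng(seed)
    hits = 0
    n = len(y)
    for _ in range(n_perm):
        flip = rng.random(n) < 0.5
        a = np.where(flip, s2, s1)
        b = np.where(flip, s1, s2)
        d = abs(auc_bruteforce(b, y) - auc_bruteforce(a, y))
        if d >= obs - 1e-12:
            hits += 1
    return hits / n_perm
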