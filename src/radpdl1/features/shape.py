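"""Shape features and box-counting fractal dimension of the tumor mask."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from ..volume_io import VolumeWithMask


def _canonical_orientation(mask: np.ndarray, spacing) -> np.ndarray:
    """Bounding-box crop in a canonical grid orientation.

    Among all axis permutations that preserve the spacing vector, combined
    with all axis flips, pick the lexicographically smallest array. Any two
    masks related by a (spacing-preserving) 90-degree rotation, flip or
    translation then map to the same representative, which makes
    orientation-sensitive numerics (marching cubes) exactly invariant.
    """
    import itertools

    idx = np.nonzero(mask)
    crop = mask[tuple(slice(i.min(), i.max() + 1) for i in idx)]
    spacing = tuple(spacing)
    best = None
    for perm in itertools.permutations(range(3)):
        if tuple(spacing[p] for p in perm) != spacing:
            continue
        m = np.transpose(crop, perm)
        for bits in range(8):
            mm = m[:: -1 if bits & 1 else 1, :: -1 if bits & 2 else 1, :: -1 if bits & 4 else 1]
            key = (mm.shape, np.ascontiguousarray(mm).tobytes())
            if best is None or key < best[0]:
                best = (key, np.ascontiguousarray(mm))
    return best[1]


def _surface_area_mm2(mask: np.ndarray, spacing) -> float:
    """Triangulated isosurface area at level 0.5 (marching cubes), in mm^2.

    The binary mask is lightly smoothed (0.6-voxel Gaussian) before surface
    extraction: marching cubes on the raw staircase overestimates the area
    of smooth objects by ~8%, while the anti-aliased isosurface is within
    ~2% on a digital sphere. Falls back to the raw mask when smoothing
    drowns a thin structure below the iso-level. The mask is brought to a
    canonical orientation first so the area is exactly invariant under
    90-degree grid rotations and flips.
    """
    canon = _canonical_orientation(mask, spacing)
    padded = np.pad(canon.astype(float), 5)
    smooth = ndimage.gaussian_filter(padded, sigma=0.6)
    field = smooth if smooth.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=tuple(spacing))
    return float(measure.mesh_surface_area(verts, faces))


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 6-neighbour outside the mask."""
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~interior


def _max_pairwise(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest pairwise distance and its direction (unit vector).

    Uses the convex hull to keep the pair search small; falls back to all
    points for degenerate (flat / tiny) sets.
    """
    if len(points) < 2:
        return 0.0, np.array([1.0, 0.0, 0.0])
    pts = points
    if len(points) > 16 and points.shape[1] == 3:
        try:
            hull = ConvexHull(points)
            pts = points[hull.vertices]
        except QhullError:
            pass
    d = pdist(pts)
    k = int(np.argmax(d))
    n = len(pts)
    # unravel condensed index k -> (i, j)
    i = int(n - 2 - np.floor(np.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2)
    vec = pts[j] - pts[i]
    norm = np.linalg.norm(vec)
    return float(d[k]), (vec / norm if norm > 0 else np.array([1.0, 0.0, 0.0]))


def _largest_cross_section(mask: np.ndarray, spacing) -> tuple[np.ndarray, tuple[float, float]]:
    """Largest axis-aligned cross-section over all three slicing axes.

    Searching all three stacks (not only the conventional axial one) makes
    the result invariant under 90-degree grid rotations.
    """
    best_area = -1.0
    best = None
    for ax in range(3):
        in_plane = [spacing[a] for a in range(3) if a != ax]
        pix = in_plane[0] * in_plane[1]
        counts = mask.sum(axis=tuple(a for a in range(3) if a != ax))
        idx = int(np.argmax(counts))
        area = counts[idx] * pix
        if area > best_area:
            sl = [slice(None)] * 3
            sl[ax] = idx
            best = (mask[tuple(sl)], tuple(in_plane))
            best_area = area
    return best


def _contour_perimeter_mm(slice_mask: np.ndarray, in_plane_spacing) -> float:
    """Sub-pixel contour length of a binary slice at level 0.5, in mm."""
    padded = np.pad(slice_mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        seg = np.diff(contour, axis=0) * np.asarray(in_plane_spacing)
        total += float(np.linalg.norm(seg, axis=1).sum())
    return total


def shape_features(voi: VolumeWithMask) -> tuple[dict, list[str]]:
    """The 11 shape features (mm-based units).

    Sphericity = pi^(1/3) (6V)^(2/3) / A, Compactness = 36 pi V^2 / A^3
    (both 1 for a perfect sphere); Roundness = geometric mean of the three
    PCA SDs over the largest one; Circularity = 4 pi A_s / P^2 of the
    largest axis-aligned cross-section. Masks thinner than 2 voxels along
    some axis get face-count surface estimates and a flag.
    """
    flags: list[str] = []
    mask = voi.mask
    spacing = np.asarray(voi.spacing_mm)
    volume = voi.n_voxels * voi.voxel_volume_mm3

    extents = np.array(
        [int(np.ptp(idx)) + 1 for idx in np.nonzero(mask)]
    )
    thin = bool((extents < 2).any())
    if thin:
        flags.append("shape_thin_mask")
        # voxel-face surface: count exposed faces per axis
        area = 0.0
        face = [spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1]]
        for ax in range(3):
            m = mask.astype(np.int8)
            exposed = np.abs(np.diff(np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)]), axis=ax)).sum()
            area += exposed * face[ax]
        area = float(area)
    else:
        area = _surface_area_mm2(mask, spacing)

    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    compactness = float(36.0 * np.pi * volume ** 2 / area ** 3)

    coords = np.argwhere(mask).astype(float) * spacing
    if len(coords) > 1:
        cov = np.cov(coords, rowvar=False, ddof=1)
        eig = np.sort(np.maximum(np.linalg.eigvalsh(cov), 0.0))[::-1]
        pca_sd = np.sqrt(eig)
    else:
        pca_sd = np.zeros(3)
    if pca_sd[0] > 0:
        positive = pca_sd[pca_sd > 0]
        roundness = float(np.exp(np.log(positive).mean()) / pca_sd[0]) if len(positive) == 3 else 0.0
    else:
        roundness = 0.0

    slice_mask, in_plane = _largest_cross_section(mask, spacing)
    slice_area = float(slice_mask.sum() * in_plane[0] * in_plane[1])
    perim = _contour_perimeter_mm(slice_mask, in_plane)
    circularity = float(4.0 * np.pi * slice_area / perim ** 2) if perim > 0 else 0.0

    boundary = np.argwhere(_boundary_voxels(mask)).astype(float) * spacing
    longest1, axis1 = _max_pairwise(boundary)
    # project onto the plane orthogonal to the first axis
    proj = boundary - np.outer(boundary @ axis1, axis1)
    longest2, _ = _max_pairwise(proj)

    values = {
        "Shape_Volume": float(volume),
        "Shape_SurfaceArea": area,
        "Shape_Sphericity": sphericity,
        "Shape_Compactness": compactness,
        "Shape_Roundness": roundness,
        "Shape_Circularity": circularity,
        "Shape_Longest1stAxis": longest1,
        "Shape_Longest2ndAxis": longest2,
        "Shape_PCA1stMajorSD": float(pca_sd[0]),
        "Shape_PCA2ndMajorSD": float(pca_sd[1]),
        "Shape_PCA3rdMajorSD": float(pca_sd[2]),
    }
    return values, flags


def _box_counts(coords: np.ndarray, extent: np.ndarray, s: int) -> float:
    """Occupied-box count at scale s, averaged over the 8 corner anchorings.

    Anchoring the dyadic grid at each corner of the bounding box and
    averaging makes the count exactly invariant under axis flips and
    permutations (hence under 90-degree rotations) and under translation.
    """
    total = 0.0
    for bits in range(8):
        c = coords.copy()
        for ax in range(3):
            if bits >> ax & 1:
                c[:, ax] = extent[ax] - 1 - c[:, ax]
        boxes = c // s
        total += len(np.unique(boxes, axis=0))
    return total / 8.0


def fractal_dimension(voi: VolumeWithMask) -> tuple[dict, list[str]]:
    """Box-counting dimension of the mask's boundary voxel set.

    Least-squares slope of log N(s) against log(1/s) over dyadic scales
    drawn from {1, 2, 4, 8, 16}, clipped to [0, 3]. The fit uses the three
    finest scales not exceeding half the bounding-box extent: at coarser
    scales the count saturates on the bounding box and the slope is biased
    toward 3. Fewer than 3 usable scales raises ValueError.
    """
    boundary = _boundary_voxels(voi.mask)
    coords = np.argwhere(boundary)
    if len(coords) == 0:
        raise ValueError("mask has no boundary voxels")
    mins = coords.min(axis=0)
    coords = coords - mins
    extent = coords.max(axis=0) + 1
    scales = [s for s in (1, 2, 4, 8, 16) if s <= extent.max() / 2][:3]
    if len(scales) < 3:
        raise ValueError(f"only {len(scales)} usable box-counting scales; need >= 3")
    counts = [_box_counts(coords, extent, s) for s in scales]
    slope = np.polyfit(np.log(np.asarray(scales, dtype=float)), np.log(counts), 1)[0]
    dim = float(np.clip(-slope, 0.0, 3.0))
    return {"Fractal_Dimension": dim}, []
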