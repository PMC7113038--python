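"""Synthetic 3-D tumor phantoms and labeled cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: a ~35% PD-L1 prevalence, clinical covariates independent of the
label, and texture differences between label groups in the homogeneity
direction (positive tumors more homogeneous, with fewer necrotic cores and
a sprinkle of air-bronchogram-like low-attenuation foci).

Tumors are lobulated ellipsoids containing a stationary Gaussian random
field texture; all randomness is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import VolumeWithMask

BACKGROUND_HU = -800.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters for one synthetic tumor."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    base_hu: float = 40.0
    texture_corr_len_mm: float = 2.2
    texture_sd_hu: float = 60.0
    necrosis_prob: float = 0.5
    necrosis_hu: float = -150.0
    noise_sd_hu: float = 15.0
    lobulation_amp: float = 0.12
    radii_mm: tuple[float, float, float] = (13.0, 11.0, 9.0)
    air_focus_prob: float = 0.25
    air_focus_frac: float = 0.01
    air_focus_hu: float = -600.0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels per axis")
        if any(s <= 0 for s in self.spacing_mm) or any(r <= 0 for r in self.radii_mm):
            raise ValueError("spacing and radii must be positive")
        if not (0 <= self.necrosis_prob <= 1 and 0 <= self.air_focus_frac <= 1 and 0 <= self.air_focus_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.texture_corr_len_mm <= 0 or self.texture_sd_hu < 0 or self.noise_sd_hu < 0:
            raise ValueError("texture parameters must be positive")
        for ax in range(3):
            half_extent = (self.grid_shape[ax] - 3) * self.spacing_mm[ax] / 2.0
            if self.radii_mm[ax] * (1.0 + 3.0 * self.lobulation_amp) > half_extent:
                raise ValueError(
                    f"tumor radius {self.radii_mm[ax]} mm (+lobulation) exceeds grid along axis {ax}"
                )

    @classmethod
    def for_grid(cls, grid_shape, spacing_mm=(1.5, 1.5, 1.5), **kwargs) -> "PhantomSpec":
        """Default spec with tumor radii scaled down to fit a given grid."""
        base = cls.__dataclass_fields__["radii_mm"].default
        lob = kwargs.get("lobulation_amp", cls.__dataclass_fields__["lobulation_amp"].default)
        scale = min(
            0.95 * (grid_shape[ax] - 3) * spacing_mm[ax] / 2.0 / (1.0 + 3.0 * lob) / base[ax]
            for ax in range(3)
        )
        radii = tuple(r * min(scale, 1.0) for r in base)
        return cls(grid_shape=tuple(grid_shape), spacing_mm=tuple(spacing_mm),
                   radii_mm=radii, **kwargs)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level sampling parameters.

    Defaults follow the study population the analysis emulates: n=153
    subjects at 53/153 prevalence, age 64.6 +/- 10.7 years, 65% male,
    smoking current/past/never at 27/59/67 out of 153, 33% EGFR-mutant,
    with all clinical covariates drawn independently of the label.
    ``effect_homogeneity`` scales the label's texture effect; 0 makes the
    feature distributions label-exchangeable.
    """

    n_subjects: int = 153
    prevalence: float = 53.0 / 153.0
    age_mean: float = 64.6
    age_sd: float = 10.7
    male_fraction: float = 99.0 / 153.0
    smoking_probs: tuple[float, float, float] = (27.0 / 153.0, 59.0 / 153.0, 67.0 / 153.0)
    egfr_fraction: float = 50.0 / 153.0
    effect_homogeneity: float = 1.0
    reader2_perturb_mm: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10 (downstream statistics undefined)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9:
            raise ValueError("smoking_probs must sum to 1")


def _label_adjusted(spec: PhantomSpec, label: int, effect: float) -> PhantomSpec:
    """Apply the planted label effect to the texture knobs.

    Positive tumors draw a longer texture correlation length (more
    homogeneous), a lower probability of a necrotic core, and a sprinkle of
    air-bronchogram-like very-low-attenuation foci; negatives keep the spec
    values. The deep foci stretch the in-mask intensity range, which under
    min-max gray-level binning compresses the solid bulk into fewer, higher
    levels - raising ASM and the high-gray run statistics in the positive
    group. With ``effect == 0`` both labels share the same distribution.
    """
    if not label or effect == 0:
        return spec
    return replace(
        spec,
        texture_corr_len_mm=spec.texture_corr_len_mm * (1.0 + 0.45 * effect),
        necrosis_prob=spec.necrosis_prob * max(0.0, 1.0 - 0.8 * effect),
        air_focus_prob=min(1.0, spec.air_focus_prob + 0.35 * effect),
    )


def _angular_perturbation(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth random function on the sphere (low-order harmonics).

    ``u``: (..., 3) unit direction vectors. Returns values normalized to
    roughly unit spread, used to lobulate the ellipsoid radius.
    """
    a = rng.standard_normal((3, 3))
    a = (a + a.T) / 2.0
    a -= np.eye(3) * np.trace(a) / 3.0
    c = rng.standard_normal(3)
    c /= np.linalg.norm(c)
    quad = np.einsum("...i,ij,...j->...", u, a, u)
    cu = u @ c
    cubic = cu ** 3 - 0.6 * cu
    f = quad + cubic
    sd = f.std()
    return f / sd if sd > 0 else f


def _grf(shape, sigma_vox, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary Gaussian random field (smoothed white noise)."""
    white = rng.standard_normal(shape)
    g = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = g.std()
    return g / sd if sd > 0 else g


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def generate_phantom(
    spec: PhantomSpec, label: int, seed: int, effect_homogeneity: float = 1.0
) -> VolumeWithMask:
    """Generate one synthetic tumor volume with its mask.

    Deterministic given ``(spec, label, seed, effect_homogeneity)``. The
    tumor is a lobulated ellipsoid at the grid center filled with a
    Gaussian-random-field texture around ``base_hu``; an optional low-HU
    necrotic core and sparse air-bronchogram-like foci provide
    heterogeneity. Background is lung-like air at -800 HU.
    """
    spec = _label_adjusted(spec, int(label), effect_homogeneity)
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm)
    radii = np.asarray(spec.radii_mm)

    center = (np.asarray(shape) - 1) / 2.0 * spacing
    idx = np.indices(shape).astype(float)
    coords = np.stack([idx[a] * spacing[a] for a in range(3)], axis=-1)
    rel = (coords - center) / radii
    rho = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(rho[..., None] > 0, rel / np.maximum(rho[..., None], 1e-12), 0.0)
    f = _angular_perturbation(u, rng)
    mask = rho <= 1.0 + spec.lobulation_amp * f
    mask = _largest_component(mask)
    if not mask.any():
        raise ValueError("phantom mask is empty; check radii against grid")

    sigma_vox = spec.texture_corr_len_mm / spacing
    texture = _grf(shape, sigma_vox, rng)
    tumor = spec.base_hu + spec.texture_sd_hu * texture

    # necrosis geometry is always drawn so the stream stays aligned across labels
    has_necrosis = rng.random() < spec.necrosis_prob
    core_center = center + rng.uniform(-0.35, 0.35, size=3) * radii
    core_radii = rng.uniform(0.25, 0.45, size=3) * radii
    if has_necrosis:
        core = np.linalg.norm((coords - core_center) / core_radii, axis=-1) <= 1.0
        w = ndimage.gaussian_filter(core.astype(float), sigma=1.0)
        w = np.clip(w, 0.0, 1.0)
        tumor = tumor * (1.0 - w) + spec.necrosis_hu * w

    # air-bronchogram-like foci: per-tumor presence coin, then sparse voxels
    has_foci = rng.random() < spec.air_focus_prob
    foci_field = rng.random(shape)
    if has_foci:
        foci = foci_field < spec.air_focus_frac
        tumor = np.where(foci, spec.air_focus_hu, tumor)

    noise = rng.normal(0.0, spec.noise_sd_hu, size=shape)
    volume = np.full(shape, BACKGROUND_HU) + noise
    volume[mask] = tumor[mask] + noise[mask]
    return VolumeWithMask(volume, tuple(spec.spacing_mm), mask)


def perturb_mask(
    mask: np.ndarray,
    spacing_mm,
    magnitude_mm: float,
    seed: int,
    corr_len_mm: float = 4.0,
) -> np.ndarray:
    """Emulate a second reader's segmentation of the same tumor.

    The mask surface is displaced by a smooth zero-mean random field with
    amplitude ``magnitude_mm``: the new mask is {signed distance <= field},
    with the signed Euclidean distance positive outside. ``magnitude_mm=0``
    returns the input mask unchanged; larger magnitudes reduce the expected
    Dice overlap monotonically. If the perturbation would empty the mask the
    amplitude is halved (twice) before giving up.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("input mask is empty")
    if magnitude_mm == 0:
        return mask.copy()
    spacing = np.asarray(spacing_mm, dtype=float)
    dist_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    dist_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    sdf = dist_out - dist_in
    rng = np.random.default_rng(seed)
    fld = _grf(mask.shape, corr_len_mm / spacing, rng)
    for attempt in range(3):
        amp = magnitude_mm / 2 ** attempt
        new = _largest_component(sdf <= amp * fld)
        if new.any():
            return new
    raise ValueError("mask perturbation emptied the mask")


def reader2_mask(vm: VolumeWithMask, magnitude_mm: float, seed: int) -> np.ndarray:
    """A second reader's segmentation of an existing phantom.

    Applies the geometric surface perturbation of :func:`perturb_mask`, but
    a voxel newly *added* to the mask is kept only when its intensity is
    tumor-like (above -550 HU): a human reader delineating on the image
    would not include clear lung parenchyma. Voxels of the original mask
    are never gated, so interior low-attenuation structure stays shared
    between readers.
    """
    raw = perturb_mask(vm.mask, vm.spacing_mm, magnitude_mm, seed)
    gate = vm.intensities > (BACKGROUND_HU + 250.0)
    mask2 = (raw & vm.mask) | (raw & ~vm.mask & gate)
    mask2 = _largest_component(mask2)
    if not mask2.any():  # pragma: no cover - perturbation guards emptiness upstream
        return vm.mask.copy()
    return mask2


@dataclass
class CohortSubject:
    """One synthetic subject: volume, reader-1 mask (in volume) and reader-2 mask."""

    subject_id: str
    volume: VolumeWithMask
    mask_reader2: np.ndarray

    @property
    def volume_reader2(self) -> VolumeWithMask:
        return VolumeWithMask(self.volume.intensities, self.volume.spacing_mm, self.mask_reader2)


def _subject_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Per-subject biological variability around the base spec."""
    size = float(np.exp(rng.normal(0.0, 0.18)))
    radii = tuple(r * size * float(np.exp(rng.normal(0.0, 0.08))) for r in base.radii_mm)
    lobulation = float(np.clip(base.lobulation_amp * np.exp(rng.normal(0.0, 0.3)), 0.0, 0.25))
    # keep the (lobulated) tumor inside the grid
    limit = [
        0.999 * (base.grid_shape[ax] - 3) * base.spacing_mm[ax] / 2.0 / (1.0 + 3.0 * lobulation)
        for ax in range(3)
    ]
    radii = tuple(min(r, limit[ax]) for ax, r in enumerate(radii))
    radii = tuple(max(r, 4.0 * base.spacing_mm[ax]) for ax, r in enumerate(radii))
    return replace(
        base,
        radii_mm=radii,
        base_hu=base.base_hu + float(rng.normal(0.0, 15.0)),
        texture_corr_len_mm=base.texture_corr_len_mm * float(np.exp(rng.normal(0.0, 0.30))),
        texture_sd_hu=base.texture_sd_hu * float(np.exp(rng.normal(0.0, 0.15))),
        lobulation_amp=lobulation,
    )


def generate_cohort(
    config: CohortConfig, spec: PhantomSpec | None = None
) -> tuple[pd.DataFrame, list[CohortSubject]]:
    """Generate a labeled cohort table plus per-subject phantom volumes.

    Labels are Bernoulli(prevalence); age, sex, smoking and EGFR status are
    drawn independently of the label (the null clinical structure of the
    emulated study). Every subject carries a reader-1 mask and a perturbed
    reader-2 mask. Exactly reproducible from ``config.seed``.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(config.seed)
    table = sample_clinical_table(config, rng)
    labels = table["pdl1_positive"].values
    n = config.n_subjects
    subject_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    perturb_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    spec_rng = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))

    subjects = []
    for i in range(n):
        subj_spec = _subject_spec(spec, spec_rng)
        vm = generate_phantom(
            subj_spec, int(labels[i]), int(subject_seeds[i]), config.effect_homogeneity
        )
        mask2 = reader2_mask(vm, config.reader2_perturb_mm, int(perturb_seeds[i]))
        subjects.append(CohortSubject(str(table["subject_id"][i]), vm, mask2))
    return table, subjects


def sample_clinical_table(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample the clinical table alone (labels + covariates, no volumes).

    Labels are Bernoulli(prevalence); every covariate is drawn from its
    marginal independently of the label, mirroring the null clinical
    structure of the emulated cohort.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    labels = (rng.random(n) < config.prevalence).astype(int)
    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    sexes = np.where(rng.random(n) < config.male_fraction, "M", "F")
    smoking = rng.choice(["current", "past", "never"], size=n, p=config.smoking_probs)
    egfr = (rng.random(n) < config.egfr_fraction).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "pdl1_positive": labels,
            "age": np.round(ages, 1),
            "sex": sexes,
            "smoking": smoking,
            "egfr_mutant": egfr,
        }
    )


def extract_cohort_features(
    config: CohortConfig, spec: PhantomSpec | None = None, G: int = 32
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and extract both readers' feature tables.

    Streaming convenience wrapper: volumes are discarded after extraction.
    Returns (cohort table, reader-1 features, reader-2 features); feature
    frames are indexed by subject_id in catalogue column order.
    """
    from .features import extract_all

    table, subjects = generate_cohort(config, spec)
    rows1, rows2 = [], []
    for subj in subjects:
        fv1 = extract_all(subj.volume, G=G)
        fv2 = extract_all(subj.volume_reader2, G=G)
        rows1.append(fv1.as_series().rename(subj.subject_id))
        rows2.append(fv2.as_series().rename(subj.subject_id))
        subj.volume = None  # type: ignore[assignment]  # free memory eagerly
    f1 = pd.DataFrame(rows1)
    f2 = pd.DataFrame(rows2)
    f1.index.name = f2.index.name = "subject_id"
    return table, f1, f2
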