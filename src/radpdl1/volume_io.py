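"""NIfTI volume/mask I/O, cohort tables, and geometry validation.

The in-memory container is :class:`VolumeWithMask`: a 3-D scalar field in
Hounsfield units, its voxel spacing in mm, and a co-registered binary tumor
mask on the same grid. All physical quantities downstream are in mm-based
units; voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .catalogue import ALL_FEATURES

#: required columns of a cohort table, in order
COHORT_COLUMNS = ("subject_id", "pdl1_positive", "age", "sex", "smoking", "egfr_mutant")

VALID_SEX = {"M", "F"}
VALID_SMOKING = {"never", "past", "current"}


class GeometryError(ValueError):
    """Image and mask grids disagree (shape or spacing)."""


class ValidationError(ValueError):
    """A table or mask fails the pipeline's validity contracts."""


@dataclass
class VolumeWithMask:
    """A 3-D HU field with voxel spacing (mm) and a binary tumor mask."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be a 3-D array")
        if self.intensities.shape != self.mask.shape:
            raise GeometryError(
                f"shape mismatch: image {self.intensities.shape} vs mask {self.mask.shape}"
            )
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not self.mask.any():
            raise ValidationError("mask is empty")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def inside(self) -> np.ndarray:
        """In-mask intensities as a flat array."""
        return self.intensities[self.mask]


def _affine(spacing_mm) -> np.ndarray:
    # RAS+ affine with the voxel size on the diagonal
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def write_volume_pair(vm: VolumeWithMask, image_path, mask_path) -> None:
    """Write intensities and mask as NIfTI files sharing one affine."""
    aff = _affine(vm.spacing_mm)
    nib.save(nib.Nifti1Image(vm.intensities.astype(np.float32), aff), str(image_path))
    nib.save(nib.Nifti1Image(vm.mask.astype(np.uint8), aff), str(mask_path))


def write_mask(mask: np.ndarray, spacing_mm, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _affine(spacing_mm)), str(path))


def read_volume_pair(image_path, mask_path, spacing_tol: float = 1e-3) -> VolumeWithMask:
    """Load an image/mask NIfTI pair and validate their shared geometry.

    The mask is binarized at 0.5. Raises :class:`GeometryError` when shapes
    or voxel spacings (tolerance ``spacing_tol`` mm) disagree and
    :class:`ValidationError` for an empty mask.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mdata = np.asarray(msk.dataobj, dtype=float)
    if data.shape != mdata.shape:
        raise GeometryError(f"shape mismatch: image {data.shape} vs mask {mdata.shape}")
    sp_img = tuple(float(z) for z in img.header.get_zooms()[:3])
    sp_msk = tuple(float(z) for z in msk.header.get_zooms()[:3])
    if any(abs(a - b) > spacing_tol for a, b in zip(sp_img, sp_msk)):
        raise GeometryError(f"spacing mismatch: image {sp_img} vs mask {sp_msk}")
    mask = mdata > 0.5
    if not mask.any():
        raise ValidationError(f"empty mask in {mask_path}")
    return VolumeWithMask(data, sp_img, mask)


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Required columns: subject_id, pdl1_positive (0/1), age, sex (M/F),
    smoking (never/past/current), egfr_mutant (0/1). Missing values are
    allowed but reported through the returned frame's NaNs; invalid label
    values raise :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    lab = df["pdl1_positive"].dropna()
    if not lab.isin([0, 1]).all():
        bad = sorted(set(lab) - {0, 1})
        raise ValidationError(f"pdl1_positive must be 0/1, found {bad}")
    sex = df["sex"].dropna()
    if not sex.isin(VALID_SEX).all():
        raise ValidationError(f"sex must be one of {sorted(VALID_SEX)}")
    smoking = df["smoking"].dropna()
    if not smoking.isin(VALID_SMOKING).all():
        raise ValidationError(f"smoking must be one of {sorted(VALID_SMOKING)}")
    egfr = df["egfr_mutant"].dropna()
    if not egfr.isin([0, 1]).all():
        raise ValidationError("egfr_mutant must be 0/1")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature CSV with columns ordered by the 58-name catalogue.

    Leading identifier/label columns (anything not in the catalogue) are
    kept first in their original order; the 58 feature columns follow in
    canonical order and must all be present.
    """
    feature_cols = [c for c in table.columns if c in ALL_FEATURES]
    missing = [c for c in ALL_FEATURES if c not in feature_cols]
    if missing:
        raise ValidationError(f"feature table missing {len(missing)} catalogue features: {missing[:5]}...")
    lead = [c for c in table.columns if c not in ALL_FEATURES]
    table[lead + list(ALL_FEATURES)].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV and verify all 58 catalogue columns are present."""
    df = pd.read_csv(path)
    missing = [c for c in ALL_FEATURES if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing {len(missing)} catalogue features: {missing[:5]}...")
    return df
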