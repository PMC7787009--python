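"""Volumetric I/O: NIfTI reading, searchlight back-projection, thresholded
statistical-map export.

Searchlight analyses produce one value per *calculation unit* (kernel
placement), not per voxel. :func:`units_to_voxels` projects a unit grid
back to voxel space: each voxel's value is the arithmetic mean over all
units whose kernel covers it, the rule used throughout this package.

Export applies, in order: multiple-comparison correction of the voxel
p-value family, then p/|value| thresholding (a voxel survives iff
``p < p_threshold``, strictly — a voxel at exactly the threshold is
filtered), then optional Gaussian smoothing of the value volume. Filtered
voxels are written as 0, the conventional sentinel in statistical NIfTI
maps; note a genuine value of 0 is indistinguishable from it, so a NaN
sentinel is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import nibabel as nib
import numpy as np

from .arrays import NeuroArray, SearchlightGrid
from .stats import fdr_correct, fwe_correct

__all__ = [
    "VoxelMap",
    "units_to_voxels",
    "save_corr_nii",
    "save_stats_nii",
    "read_fmri_nii",
]


@dataclass(frozen=True)
class VoxelMap:
    """An X x Y x Z statistic volume with its affine.

    ``meaning`` records whether values are correlation coefficients ("r")
    or t-statistics ("t"). ``coverage`` (optional) counts, per voxel, how
    many searchlight units contributed to it; 0 means the voxel was covered
    by no unit and its value is the filler 0.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meaning: str = "r"
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "affine", affine)
        if values.ndim != 3:
            raise ValueError(f"volume must be 3-d, got shape {values.shape}")
        _check_affine(affine)
        if self.meaning not in ("r", "t"):
            raise ValueError("meaning must be 'r' or 't'")


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is not invertible")


def units_to_voxels(
    unit_values: np.ndarray,
    grid: SearchlightGrid,
    affine: np.ndarray | None = None,
    meaning: str = "r",
) -> VoxelMap:
    """Average searchlight-unit values back onto the voxel grid.

    Each voxel's value is the mean over all units whose kernel contains it;
    non-finite unit values (missing units) are excluded from the average.
    Voxels covered by no (finite) unit are set to 0 and flagged through the
    ``coverage`` count volume.
    """
    unit_values = np.asarray(unit_values, dtype=float)
    if unit_values.shape != grid.n_units:
        raise ValueError(
            f"unit grid {unit_values.shape} does not match searchlight layout {grid.n_units}"
        )
    kx, ky, kz = grid.kernel
    total = np.zeros(grid.image_size)
    count = np.zeros(grid.image_size, dtype=int)
    for idx in product(*(range(n) for n in grid.n_units)):
        v = unit_values[idx]
        if not np.isfinite(v):
            continue
        ox, oy, oz = grid.unit_origin(idx)
        total[ox : ox + kx, oy : oy + ky, oz : oz + kz] += v
        count[ox : ox + kx, oy : oy + ky, oz : oz + kz] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return VoxelMap(
        values,
        np.eye(4) if affine is None else affine,
        meaning,
        coverage=count,
    )


def _threshold_volume(
    values: np.ndarray,
    p_volume: np.ndarray,
    p_threshold: float | None,
    value_threshold: float | None,
    correction: str,
    sentinel: float,
) -> np.ndarray:
    p = np.asarray(p_volume, dtype=float)
    if p.shape != values.shape:
        raise ValueError(f"p volume shape {p.shape} does not match {values.shape}")
    if correction not in ("none", "FDR", "FWE"):
        raise ValueError("correction must be 'none', 'FDR' or 'FWE'")
    if p_threshold is not None and not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")

    if correction == "FDR":
        _, p = fdr_correct(p)
    elif correction == "FWE":
        _, p = fwe_correct(p)

    survive = np.isfinite(values) & np.isfinite(p)
    if p_threshold is not None:
        survive &= p < p_threshold  # strict: p >= threshold is filtered
    if value_threshold is not None:
        survive &= np.abs(values) >= value_threshold
    return np.where(survive, values, sentinel)


def _smooth(values: np.ndarray, affine: np.ndarray, fwhm_mm: float) -> np.ndarray:
    from nilearn.image import smooth_img

    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    return np.asarray(smooth_img(img, fwhm_mm).get_fdata())


def _write_nii(values: np.ndarray, affine: np.ndarray, filename: str) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    img.set_qform(affine)
    img.set_sform(affine)
    nib.save(img, filename)
    return img


def save_corr_nii(
    r_volume: np.ndarray | VoxelMap,
    p_volume: np.ndarray,
    filename: str,
    affine: np.ndarray | None = None,
    p_threshold: float | None = 0.05,
    r_threshold: float | None = None,
    correction: str = "none",
    smooth_fwhm: float | None = None,
    sentinel: float = 0.0,
) -> np.ndarray:
    """Write a thresholded correlation map as a NIfTI-1 file.

    Pipeline: FDR/FWE correction of the p family (if requested) →
    filtering (survive iff ``p < p_threshold`` and ``|r| >= r_threshold``)
    → optional Gaussian smoothing (FWHM in mm) → write as 32-bit float
    with the given affine in both qform and sform. Returns the volume that
    was written. Without smoothing, reading the file back reproduces it to
    float32 storage precision.
    """
    if isinstance(r_volume, VoxelMap):
        affine = r_volume.affine if affine is None else affine
        r_volume = r_volume.values
    if affine is None:
        affine = np.eye(4)
    _check_affine(np.asarray(affine, dtype=float))
    out = _threshold_volume(
        np.asarray(r_volume, dtype=float), p_volume, p_threshold, r_threshold,
        correction, sentinel,
    )
    if smooth_fwhm is not None:
        out = _smooth(out, affine, smooth_fwhm)
    _write_nii(out, affine, filename)
    return out


def save_stats_nii(
    t_volume: np.ndarray | VoxelMap,
    p_volume: np.ndarray,
    filename: str,
    affine: np.ndarray | None = None,
    p_threshold: float | None = 0.05,
    t_threshold: float | None = None,
    correction: str = "none",
    smooth_fwhm: float | None = None,
    sentinel: float = 0.0,
) -> np.ndarray:
    """Write a thresholded t-map as NIfTI-1; same pipeline as
    :func:`save_corr_nii` with ``|t|`` in place of ``|r|``."""
    return save_corr_nii(
        t_volume,
        p_volume,
        filename,
        affine=affine,
        p_threshold=p_threshold,
        r_threshold=t_threshold,
        correction=correction,
        smooth_fwhm=smooth_fwhm,
        sentinel=sentinel,
    )


def read_fmri_nii(paths) -> tuple[NeuroArray, np.ndarray]:
    """Stack NIfTI volumes into fMRI-shaped data ``[condition, subject, x, y, z]``.

    ``paths`` is a nested sequence ``paths[condition][subject]``; every
    volume must share one shape and affine (a mismatch names the offending
    file).
    """
    ref_affine = None
    ref_shape = None
    conditions = []
    for cond_paths in paths:
        subjects = []
        for path in cond_paths:
            img = nib.load(str(path))
            data = np.asarray(img.get_fdata())
            if ref_affine is None:
                ref_affine = img.affine
                ref_shape = data.shape
            if data.shape != ref_shape:
                raise ValueError(
                    f"{path}: shape {data.shape} differs from {ref_shape}"
                )
            if not np.allclose(img.affine, ref_affine):
                raise ValueError(f"{path}: affine differs from the first volume")
            subjects.append(data)
        conditions.append(np.stack(subjects))
    values = np.stack(conditions)
    return NeuroArray.fmri(values), ref_affine
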