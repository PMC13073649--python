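"""Volume/mask data model, NIfTI I/O, SUV computation, and isotropic resampling.

Conventions used throughout the package:

* arrays are indexed ``(x, y, z)`` with ``z`` the cranio-caudal axis;
* voxel indices are 0-based and map to physical space through the
  voxel-center rule ``coord = origin + index * spacing`` (mm);
* intensities are standardized uptake values (SUV, g/mL by convention,
  treated as dimensionless), finite and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk

AXIS_NAMES = ("x", "y", "z")

__all__ = [
    "PetVolume",
    "LesionMask",
    "suv_from_activity",
    "mtv_ml",
    "resample_bspline",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class PetVolume:
    """A 3-D SUV grid with physical voxel geometry.

    Parameters
    ----------
    values
        3-D array of SUV, axis order (x, y, z).
    spacing
        Per-axis voxel size in mm.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {values.ndim}-D")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if np.any(values < 0):
            raise ValueError("SUV values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Physical coordinate (mm) of voxel-center ``index`` (may be fractional)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-center physical coordinates."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )


@dataclass(frozen=True)
class LesionMask:
    """Binary VOI congruent with a :class:`PetVolume`; its volume is the MTV."""

    indicator: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if ind.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {ind.ndim}-D")
        ind = ind.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "indicator", ind)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.indicator.sum())

    def check_congruent(self, volume: PetVolume) -> None:
        """Raise if the mask does not share the volume's grid geometry."""
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} != volume shape {volume.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing, rtol=1e-5, atol=1e-5):
            raise ValueError(
                f"mask spacing {self.spacing} != volume spacing {volume.spacing}"
            )
        if not np.allclose(self.origin, volume.origin, rtol=1e-5, atol=1e-3):
            raise ValueError(
                f"mask origin {self.origin} != volume origin {volume.origin}"
            )

    def foreground_coordinates(self) -> np.ndarray:
        """(n, 3) physical coordinates (mm) of foreground voxel centers."""
        idx = np.argwhere(self.indicator)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


def suv_from_activity(
    activity_conc: np.ndarray,
    injected_activity_kbq: float,
    body_weight_g: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> PetVolume:
    """Convert a decay-corrected activity-concentration grid (kBq/mL) to SUV.

    SUV = (activity per mL of tissue) / (injected activity / body weight),
    with injected activity in kBq and body weight in grams.
    """
    if injected_activity_kbq <= 0:
        raise ValueError(
            f"injected activity must be positive, got {injected_activity_kbq}"
        )
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_g}")
    values = np.asarray(activity_conc, dtype=np.float64) / (
        injected_activity_kbq / body_weight_g
    )
    return PetVolume(values=values, spacing=spacing, origin=origin)


def mtv_ml(mask: LesionMask) -> float:
    """Metabolic tumor volume in mL: foreground voxels x voxel volume."""
    n = mask.voxel_count
    if n == 0:
        raise ValueError("mask is empty; MTV is undefined")
    return n * mask.voxel_volume_mm3 / 1000.0


def _to_sitk(volume: PetVolume) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our convention is (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    return img


def resample_bspline(
    volume: PetVolume,
    target_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> PetVolume:
    """Resample onto an isotropic grid with cubic B-spline interpolation.

    The output grid is anchored at the input origin and sized so its
    field of view covers the input (voxel-center extent). Samples outside
    the input support use nearest-edge extension; negative interpolation
    overshoot is clamped to zero.
    """
    target = tuple(float(t) for t in target_spacing)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be three positive values, got {target}")
    for a in range(3):
        if volume.shape[a] < 2:
            raise ValueError(
                f"cannot resample along degenerate axis {AXIS_NAMES[a]!r} "
                f"(size {volume.shape[a]})"
            )
    size = tuple(
        int(np.ceil((volume.shape[a] - 1) * volume.spacing[a] / target[a])) + 1
        for a in range(3)
    )
    img = _to_sitk(volume)
    out = sitk.Resample(
        img,
        size,
        sitk.Transform(),
        sitk.sitkBSpline,
        tuple(volume.origin),
        target,
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        0.0,
        sitk.sitkFloat64,
        True,  # nearest-neighbor extrapolation outside the input support
    )
    values = sitk.GetArrayFromImage(out).T
    return PetVolume(
        values=np.clip(values, 0.0, None), spacing=target, origin=volume.origin
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(volume: PetVolume, path) -> None:
    img = nib.Nifti1Image(
        volume.values.astype(np.float32), _affine(volume.spacing, volume.origin)
    )
    nib.save(img, str(path))


def read_volume(path) -> PetVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI image, got {data.ndim}-D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return PetVolume(
        values=np.clip(np.asarray(data, dtype=np.float64), 0.0, None),
        spacing=spacing,
        origin=origin,
    )


def write_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(
        mask.indicator.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


def read_mask(path, parent: PetVolume) -> LesionMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI mask, got {data.ndim}-D: {path}")
    rounded = np.rint(np.asarray(data, dtype=np.float64))
    if not np.isin(rounded, (0.0, 1.0)).all():
        raise ValueError(f"mask file contains values other than 0/1: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    mask = LesionMask(indicator=rounded.astype(bool), spacing=spacing, origin=origin)
    mask.check_congruent(parent)
    return mask
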