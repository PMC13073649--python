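"""Hotspot-displacement morphological features.

NHOC (normalized hotspot-to-centroid distance) and NHOP (normalized
hotspot-to-perimeter distance) quantify where the metabolic hotspot sits
inside the lesion: NHOC is the distance from the hotspot to the lesion's
geometric centroid, NHOP the distance from the hotspot to the nearest
point of the discretized lesion surface (exposed voxel-face centers),
both divided by the lesion's equivalent-sphere radius
``r_eq = (3 * MTV / 4pi)^(1/3)``. On an ideal ball these two satisfy
NHOC + NHOP = 1 for any interior hotspot, which motivates the
equivalent-radius normalization.

Each distance comes in two flavors: the hotspot located by the single
hottest voxel (SUVmax) and by the SUVpeak sphere (mean SUV in a 1 mL
sphere). SUVpeak and its derived features are undefined for lesions
below 1 mL and propagate as missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import AXIS_NAMES, LesionMask, PetVolume, mtv_ml

__all__ = [
    "PEAK_SPHERE_RADIUS_MM",
    "HotspotFeatureSet",
    "find_suvmax",
    "suv_peak",
    "centroid",
    "nhoc",
    "nhop",
    "boundary_voxel_coordinates",
    "boundary_face_centers",
    "equivalent_sphere_radius_mm",
    "compute_hotspot_features",
]

#: radius (mm) of the 1 mL SUVpeak sphere: (3*1000 / 4pi)^(1/3)
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _lex_argmax(values: np.ndarray, valid: np.ndarray) -> tuple[int, int, int]:
    """Arg-max of ``values`` over ``valid`` voxels, ties broken by lowest
    lexicographic (z, y, x) index. Arrays are (x, y, z)-ordered."""
    vt = np.where(valid, values, -np.inf).T  # (z, y, x), C-order ravel
    flat = int(np.argmax(vt))
    z, y, x = np.unravel_index(flat, vt.shape)
    return int(x), int(y), int(z)


def find_suvmax(volume: PetVolume, mask: LesionMask) -> tuple[np.ndarray, float]:
    """Location (mm) and value of the hottest voxel inside the VOI."""
    mask.check_congruent(volume)
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    idx = _lex_argmax(volume.values, mask.indicator)
    return volume.index_to_physical(idx), float(volume.values[idx])


def _sphere_kernel(spacing: tuple[float, float, float]) -> np.ndarray:
    """Binary kernel of voxel offsets whose centers lie within the 1 mL
    sphere radius of the kernel center."""
    r = PEAK_SPHERE_RADIUS_MM
    half = [int(math.floor(r / s)) for s in spacing]
    grids = np.meshgrid(
        *(np.arange(-h, h + 1) * s for h, s in zip(half, spacing)), indexing="ij"
    )
    d2 = sum(g**2 for g in grids)
    return d2 <= r**2


def _feasible_centers(shape, spacing) -> tuple[np.ndarray, list[int]]:
    """Boolean grid of voxel centers around which the full SUVpeak sphere
    fits inside the image, plus the per-axis margins in voxels."""
    margins = [int(math.floor(PEAK_SPHERE_RADIUS_MM / s)) for s in spacing]
    ok = np.zeros(shape, dtype=bool)
    inner = tuple(
        slice(m, n - m) if n - 2 * m > 0 else slice(0, 0)
        for m, n in zip(margins, shape)
    )
    ok[inner] = True
    return ok, margins


def suv_peak(
    volume: PetVolume, mask: LesionMask, mode: str = "search"
) -> tuple[np.ndarray, float] | None:
    """SUVpeak: mean SUV within a 1 mL sphere, and the sphere center (mm).

    Returns ``None`` for lesions below the 1 mL volumetric requirement.
    ``mode="search"`` (default) centers the sphere on the mask voxel that
    maximizes the sphere-mean SUV; ``mode="max"`` centers it on the SUVmax
    voxel. The mean runs over all grid voxels in the sphere, not only mask
    voxels.
    """
    mask.check_congruent(volume)
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    if mtv_ml(mask) < 1.0:
        return None
    if mode not in ("search", "max"):
        raise ValueError(f"unknown SUVpeak mode {mode!r}")

    kernel = _sphere_kernel(volume.spacing)
    sphere_mean = ndimage.convolve(
        volume.values, kernel.astype(np.float64), mode="constant"
    ) / kernel.sum()
    feasible, margins = _feasible_centers(volume.shape, volume.spacing)

    if mode == "max":
        candidates = np.zeros(volume.shape, dtype=bool)
        candidates[_lex_argmax(volume.values, mask.indicator)] = True
    else:
        candidates = mask.indicator
    usable = candidates & feasible
    if not usable.any():
        ref = _lex_argmax(volume.values, mask.indicator)
        for a in range(3):
            if not (margins[a] <= ref[a] < volume.shape[a] - margins[a]):
                raise ValueError(
                    f"SUVpeak sphere would be clipped by the image grid along "
                    f"axis {AXIS_NAMES[a]!r}"
                )
        raise ValueError("SUVpeak sphere would be clipped by the image grid")
    idx = _lex_argmax(sphere_mean, usable)
    return volume.index_to_physical(idx), float(sphere_mean[idx])


def centroid(mask: LesionMask) -> np.ndarray:
    """Unweighted mean of foreground voxel-center coordinates (mm)."""
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    return mask.foreground_coordinates().mean(axis=0)


def equivalent_sphere_radius_mm(mask: LesionMask) -> float:
    """Radius (mm) of the sphere with the lesion's MTV."""
    return (3.0 * mtv_ml(mask) * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def boundary_voxel_coordinates(mask: LesionMask) -> np.ndarray:
    """Coordinates (mm) of foreground voxels with at least one face-adjacent
    in-grid background neighbor."""
    eroded = ndimage.binary_erosion(
        mask.indicator, structure=_FACE_STRUCT, border_value=1
    )
    boundary = mask.indicator & ~eroded
    if not boundary.any():
        raise ValueError("mask has no boundary (fills the grid)")
    return np.asarray(mask.origin) + np.argwhere(boundary) * np.asarray(mask.spacing)


def boundary_face_centers(mask: LesionMask) -> np.ndarray:
    """Centers (mm) of exposed voxel faces: faces between a foreground voxel
    and a face-adjacent in-grid background voxel.

    This is the discretized lesion surface used by NHOP; it sits half a
    voxel outside the boundary-voxel centers, which keeps the ball identity
    NHOC + NHOP = 1 unbiased under digitization.
    """
    ind = mask.indicator
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    centers = []
    for axis in range(3):
        for sign in (1, -1):
            neighbor = np.zeros_like(ind)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            src[axis] = slice(1, None) if sign > 0 else slice(None, -1)
            dst[axis] = slice(None, -1) if sign > 0 else slice(1, None)
            neighbor[tuple(dst)] = ind[tuple(src)]
            # interior slab only: faces against the grid edge are undefined
            exposed = np.zeros_like(ind)
            exposed[tuple(dst)] = ind[tuple(dst)] & ~neighbor[tuple(dst)]
            idx = np.argwhere(exposed)
            if idx.size:
                offset = np.zeros(3)
                offset[axis] = 0.5 * sign * spacing[axis]
                centers.append(origin + idx * spacing + offset)
    if not centers:
        raise ValueError("mask has no boundary (fills the grid)")
    return np.vstack(centers)


def nhoc(hotspot_mm: np.ndarray, mask: LesionMask) -> float:
    """Normalized hotspot-to-centroid distance."""
    r_eq = equivalent_sphere_radius_mm(mask)
    if r_eq == 0:
        raise ValueError("equivalent radius is zero")
    return float(np.linalg.norm(np.asarray(hotspot_mm) - centroid(mask)) / r_eq)


def nhop(hotspot_mm: np.ndarray, mask: LesionMask) -> float:
    """Normalized hotspot-to-perimeter distance: minimum distance from the
    hotspot to the exposed-face surface of the VOI, over r_eq."""
    r_eq = equivalent_sphere_radius_mm(mask)
    if r_eq == 0:
        raise ValueError("equivalent radius is zero")
    surface = boundary_face_centers(mask)
    d = np.linalg.norm(surface - np.asarray(hotspot_mm), axis=1)
    return float(d.min() / r_eq)


@dataclass(frozen=True)
class HotspotFeatureSet:
    """Hotspot localization and displacement features for one lesion.

    Peak-based entries are ``None`` when the lesion is below the 1 mL
    SUVpeak volumetric requirement.
    """

    suv_max: float
    suv_peak: float | None
    hotspot_max_mm: tuple[float, float, float]
    hotspot_peak_mm: tuple[float, float, float] | None
    centroid_mm: tuple[float, float, float]
    mtv_ml: float
    r_eq_mm: float
    nhoc_max: float
    nhop_max: float
    nhoc_peak: float | None
    nhop_peak: float | None


def compute_hotspot_features(
    volume: PetVolume, mask: LesionMask, peak_mode: str = "search"
) -> HotspotFeatureSet:
    """All hotspot-displacement features for one lesion VOI."""
    hot_max, smax = find_suvmax(volume, mask)
    cen = centroid(mask)
    vol_ml = mtv_ml(mask)
    r_eq = equivalent_sphere_radius_mm(mask)
    peak = suv_peak(volume, mask, mode=peak_mode)
    if peak is None:
        hot_peak = speak = nhoc_p = nhop_p = None
    else:
        hot_peak_arr, speak = peak
        hot_peak = tuple(float(v) for v in hot_peak_arr)
        nhoc_p = nhoc(hot_peak_arr, mask)
        nhop_p = nhop(hot_peak_arr, mask)
    return HotspotFeatureSet(
        suv_max=smax,
        suv_peak=speak,
        hotspot_max_mm=tuple(float(v) for v in hot_max),
        hotspot_peak_mm=hot_peak,
        centroid_mm=tuple(float(v) for v in cen),
        mtv_ml=vol_ml,
        r_eq_mm=r_eq,
        nhoc_max=nhoc(hot_max, mask),
        nhop_max=nhop(hot_max, mask),
        nhoc_peak=nhoc_p,
        nhop_peak=nhop_p,
    )
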