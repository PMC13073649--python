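"""Fractional-SUVmax VOI delineation, inclusion filtering, and per-patient
lesion selection.

Delineation mirrors the common semi-automated PET workflow: a seed box
(here replacing the manual initial VOI) is thresholded at a fraction of
the intra-box SUVmax, and the 26-connected component containing the max
voxel becomes the VOI. VOIs for gated, non-gated, and resampled images
are always produced by independent segmentation runs, never by mask
interpolation, to avoid misregistration artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import LesionMask, PetVolume, mtv_ml

__all__ = [
    "SeedRegion",
    "threshold_segment",
    "passes_inclusion",
    "largest_lesion_per_patient",
    "MIN_VOXELS",
]

#: minimum VOI size for reproducible radiomic extraction
MIN_VOXELS = 64

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedRegion:
    """Axis-aligned voxel-index box (inclusive low, exclusive high)."""

    low: tuple[int, int, int]
    high: tuple[int, int, int]

    def clipped(self, shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        lo = [max(0, int(l)) for l in self.low]
        hi = [min(int(s), int(h)) for s, h in zip(shape, self.high)]
        if any(l >= h for l, h in zip(lo, hi)):
            raise ValueError(
                f"seed region {self.low}..{self.high} does not intersect grid {shape}"
            )
        return tuple(slice(l, h) for l, h in zip(lo, hi))

    @classmethod
    def whole_grid(cls, shape: tuple[int, int, int]) -> "SeedRegion":
        return cls(low=(0, 0, 0), high=tuple(int(s) for s in shape))


def threshold_segment(
    volume: PetVolume, region: SeedRegion, fraction: float = 0.40
) -> LesionMask:
    """Segment one lesion at ``fraction`` of the intra-region SUVmax.

    Voxels inside the region with SUV >= fraction * max are kept, reduced
    to the 26-connected component containing the max voxel.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    sl = region.clipped(volume.shape)
    sub = volume.values[sl]
    m = float(sub.max())
    if m <= 0:
        raise ValueError("no signal: maximum SUV inside the seed region is 0")
    above = sub >= fraction * m
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    max_idx = np.unravel_index(int(np.argmax(sub)), sub.shape)
    component = labels == labels[max_idx]
    indicator = np.zeros(volume.shape, dtype=bool)
    indicator[sl] = component
    return LesionMask(
        indicator=indicator, spacing=volume.spacing, origin=volume.origin
    )


def passes_inclusion(mask: LesionMask, min_voxels: int = MIN_VOXELS) -> bool:
    """True iff the VOI meets the minimum voxel count for extraction."""
    return mask.voxel_count >= min_voxels


def largest_lesion_per_patient(
    lesions: list[tuple[str, LesionMask]],
) -> dict[str, tuple[int, LesionMask]]:
    """Select, per patient, the lesion with the largest MTV.

    Returns ``{patient_id: (lesion_index, mask)}`` where ``lesion_index``
    is the position in the input list; ties go to the lowest index.
    """
    if not lesions:
        raise ValueError("no lesions provided")
    best: dict[str, tuple[int, LesionMask]] = {}
    for i, (patient_id, mask) in enumerate(lesions):
        if patient_id not in best:
            best[patient_id] = (i, mask)
        else:
            j, current = best[patient_id]
            if mtv_ml(mask) > mtv_ml(current):
                best[patient_id] = (i, mask)
    return best
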