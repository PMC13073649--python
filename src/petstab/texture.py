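"""Respiratory-stable reference features: fixed-bin-width discretization,
first-order entropy, GLCM joint/sum entropy, IDN, IDMN, GLRLM run entropy,
and voxel-face sphericity.

Texture matrices are 3-D, computed over the 13 unique distance-1
directions, with counts merged over directions before normalization and
the gray-level axis restricted to the occupied range (min..max occupied
level). All entropies use log base 2 (bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_core import LesionMask, PetVolume, mtv_ml

__all__ = [
    "DEFAULT_BIN_WIDTH",
    "DiscretizedVolume",
    "GLCMatrix",
    "discretize_fbw",
    "first_order_entropy",
    "glcm",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_run_entropy",
    "sphericity",
    "DIRECTIONS_13",
]

#: fixed bin width in SUV for gray-level discretization
DEFAULT_BIN_WIDTH = 0.25

#: the 13 unique 3-D distance-1 directions (one per +/- pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass(frozen=True)
class DiscretizedVolume:
    """Integer gray levels for mask voxels, anchored at absolute 0 SUV:
    ``level(v) = floor(v / bin_width) + 1``."""

    levels: np.ndarray  # int level per voxel; meaningful only under mask
    mask: np.ndarray  # bool, same shape
    bin_width: float

    @property
    def occupied(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def level_range(self) -> tuple[int, int]:
        occ = self.occupied
        return int(occ.min()), int(occ.max())

    @property
    def n_levels(self) -> int:
        """Number of levels in the occupied range (min..max occupied)."""
        lo, hi = self.level_range
        return hi - lo + 1


def discretize_fbw(
    volume: PetVolume, mask: LesionMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DiscretizedVolume:
    """Fixed-bin-width gray-level discretization of the VOI."""
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    mask.check_congruent(volume)
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    vals = volume.values[mask.indicator]
    if np.any(vals < 0):
        raise ValueError("negative SUV inside the mask")
    levels = np.floor(volume.values / bin_width).astype(np.int64) + 1
    return DiscretizedVolume(levels=levels, mask=mask.indicator, bin_width=bin_width)


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def first_order_entropy(d: DiscretizedVolume) -> float:
    """Shannon entropy (bits) of the occupied-level histogram."""
    _, counts = np.unique(d.occupied, return_counts=True)
    return _entropy_bits(counts / counts.sum())


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric joint gray-level co-occurrence probabilities over the
    occupied level range; ``p[i, j]`` with i, j zero-based within that range."""

    p: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM entries must be non-negative and sum to 1")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")
        object.__setattr__(self, "p", p)


def glcm(d: DiscretizedVolume) -> GLCMatrix:
    """Merged symmetric GLCM over the 13 distance-1 directions.

    Pairs with either voxel outside the mask are skipped; counts from the
    13 directions (both orderings) are summed, then normalized.
    """
    lo, hi = d.level_range
    n = hi - lo + 1
    idx = d.levels - lo
    counts = np.zeros((n, n), dtype=np.int64)
    shape = d.mask.shape
    for off in DIRECTIONS_13:
        src = tuple(
            slice(max(0, -o), s - max(0, o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), s - max(0, -o)) for o, s in zip(off, shape)
        )
        valid = d.mask[src] & d.mask[dst]
        a = idx[src][valid]
        b = idx[dst][valid]
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask neighbor pairs for the GLCM")
    return GLCMatrix(p=counts / total, n_levels=n)


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """Joint entropy, sum entropy (bits), IDN, and IDMN of a GLCM."""
    n = m.n_levels
    p = m.p
    i, j = np.indices(p.shape)
    diff = np.abs(i - j)
    # p_{x+y}(k): distribution of i + j
    k = i + j
    p_sum = np.bincount(k.ravel(), weights=p.ravel(), minlength=2 * n - 1)
    return {
        "joint_entropy": _entropy_bits(p),
        "sum_entropy": _entropy_bits(p_sum),
        "idn": float((p / (1.0 + diff / n)).sum()),
        "idmn": float((p / (1.0 + (diff / n) ** 2)).sum()),
    }


def _lines(shape: tuple[int, int, int], direction: tuple[int, int, int]):
    """Yield voxel-index arrays for every maximal grid line along a direction."""
    d = np.asarray(direction)
    shape_arr = np.asarray(shape)
    # starts: voxels whose predecessor along -d lies outside the grid
    coords = np.indices(shape).reshape(3, -1).T
    prev = coords - d
    outside = ((prev < 0) | (prev >= shape_arr)).any(axis=1)
    for start in coords[outside]:
        # number of steps until leaving the grid
        steps = []
        for a in range(3):
            if d[a] > 0:
                steps.append((shape[a] - 1 - start[a]) // d[a])
            elif d[a] < 0:
                steps.append(start[a] // (-d[a]))
        length = int(min(steps)) + 1 if steps else 1
        t = np.arange(length)
        yield tuple((start[a] + t * d[a]) for a in range(3))


def glrlm_matrix(
    d: DiscretizedVolume,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> np.ndarray:
    """Merged run-length matrix r(level, run_length) over the given directions.

    Runs are maximal sequences of in-mask voxels of equal level along a
    direction; out-of-mask voxels break runs. Rows are levels in the
    occupied range (zero-based), columns run lengths 1..L.
    """
    lo, hi = d.level_range
    n = hi - lo + 1
    max_len = max(d.mask.shape)
    counts = np.zeros((n, max_len), dtype=np.int64)
    # crop to the mask bounding box: runs cannot involve voxels outside it
    bbox = tuple(
        slice(int(ax.min()), int(ax.max()) + 1) for ax in np.nonzero(d.mask)
    )
    mask = d.mask[bbox]
    idx = (d.levels - lo)[bbox]
    for direction in directions:
        for line in _lines(mask.shape, direction):
            m = mask[line]
            if not m.any():
                continue
            lv = idx[line]
            # run breaks: mask change, level change, or sequence boundary
            key = np.where(m, lv, -1)
            change = np.empty(key.size, dtype=bool)
            change[0] = True
            change[1:] = key[1:] != key[:-1]
            starts = np.flatnonzero(change)
            lengths = np.diff(np.append(starts, key.size))
            for s, ln in zip(starts, lengths):
                if key[s] >= 0:
                    counts[key[s], ln - 1] += 1
    return counts


def glrlm_run_entropy(
    d: DiscretizedVolume,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> float:
    """Run entropy (bits) of the direction-merged run-length matrix."""
    counts = glrlm_matrix(d, directions=directions)
    total = counts.sum()
    if total == 0:
        raise ValueError("mask produced no runs")
    return _entropy_bits(counts[counts > 0] / total)


def sphericity(mask: LesionMask) -> float:
    """(36 pi V^2)^(1/3) / A with V the MTV (mm^3) and A the total exposed
    voxel-face area (mm^2); 1 for a ball, smaller for irregular shapes."""
    v_mm3 = mtv_ml(mask) * 1000.0
    ind = mask.indicator
    sp = mask.spacing
    area = 0.0
    for axis in range(3):
        face = sp[(axis + 1) % 3] * sp[(axis + 2) % 3]
        padded = np.pad(ind, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        exposed = np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum()
        area += float(exposed) * face
    if area == 0:
        raise ValueError("mask has no exposed surface")
    return float((36.0 * math.pi * v_mm3**2) ** (1.0 / 3.0) / area)
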