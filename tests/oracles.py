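"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible from the definitions
(explicit loops, exhaustive enumeration, 1-D numerical likelihood
maximization) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

DIRECTIONS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def brute_glcm(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric merged co-occurrence counts by triple loop over voxels."""
    lo = int(levels[mask].min())
    hi = int(levels[mask].max())
    n = hi - lo + 1
    counts = np.zeros((n, n), dtype=np.int64)
    shape = mask.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in DIRECTIONS_13:
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]):
                        continue
                    if not mask[u, v, w]:
                        continue
                    a = levels[x, y, z] - lo
                    b = levels[u, v, w] - lo
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts


def brute_glrlm(levels: np.ndarray, mask: np.ndarray) -> dict[tuple[int, int], int]:
    """Run counts {(zero-based level, run length): count} merged over the
    13 directions, by walking every line voxel by voxel."""
    lo = int(levels[mask].min())
    shape = mask.shape
    runs: dict[tuple[int, int], int] = {}
    for d in DIRECTIONS_13:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    # run starts: no same-level in-mask predecessor along -d
                    if not mask[x, y, z]:
                        continue
                    px, py, pz = x - d[0], y - d[1], z - d[2]
                    if (
                        0 <= px < shape[0]
                        and 0 <= py < shape[1]
                        and 0 <= pz < shape[2]
                        and mask[px, py, pz]
                        and levels[px, py, pz] == levels[x, y, z]
                    ):
                        continue
                    length = 1
                    cx, cy, cz = x + d[0], y + d[1], z + d[2]
                    while (
                        0 <= cx < shape[0]
                        and 0 <= cy < shape[1]
                        and 0 <= cz < shape[2]
                        and mask[cx, cy, cz]
                        and levels[cx, cy, cz] == levels[x, y, z]
                    ):
                        length += 1
                        cx, cy, cz = cx + d[0], cy + d[1], cz + d[2]
                    key = (int(levels[x, y, z] - lo), length)
                    runs[key] = runs.get(key, 0) + 1
    return runs


def brute_suvmax(values: np.ndarray, mask: np.ndarray) -> tuple[tuple[int, int, int], float]:
    """Exhaustive scan with lowest-(z, y, x) tie-break."""
    best = None
    best_val = -np.inf
    shape = mask.shape
    for z in range(shape[2]):
        for y in range(shape[1]):
            for x in range(shape[0]):
                if mask[x, y, z] and values[x, y, z] > best_val:
                    best_val = values[x, y, z]
                    best = (x, y, z)
    return best, float(best_val)


def brute_centroid(mask: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    coords = []
    shape = mask.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if mask[x, y, z]:
                    coords.append(
                        [origin[a] + (x, y, z)[a] * spacing[a] for a in range(3)]
                    )
    return np.mean(coords, axis=0)


def brute_surface_min_distance(point: np.ndarray, mask: np.ndarray, spacing) -> float:
    """Exhaustive minimum distance to exposed voxel-face centers."""
    shape = mask.shape
    best = np.inf
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for axis in range(3):
                    for sign in (1, -1):
                        nb = [x, y, z]
                        nb[axis] += sign
                        if not (0 <= nb[axis] < shape[axis]):
                            continue
                        if mask[tuple(nb)]:
                            continue
                        face = np.array(
                            [(x, y, z)[a] * spacing[a] for a in range(3)], dtype=float
                        )
                        face[axis] += 0.5 * sign * spacing[axis]
                        best = min(best, float(np.linalg.norm(face - point)))
    return best


def brute_icc_2_1(table: np.ndarray) -> float:
    """ICC(2,1) from explicit two-way ANOVA sums of squares."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def brute_cox_coef(times: np.ndarray, events: np.ndarray, x: np.ndarray) -> float:
    """1-D maximizer of the written Breslow partial likelihood."""

    def negll(beta: float) -> float:
        ll = 0.0
        for i in range(len(times)):
            if events[i] != 1:
                continue
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -ll

    res = minimize_scalar(negll, bounds=(-20, 20), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def brute_cindex(times, events, risks) -> float:
    """Pair enumeration with Harrell's conventions."""
    num = 0.0
    den = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shorter_event = events[i] == 1 and (
                times[i] < times[j] or (times[i] == times[j] and events[j] == 0)
            )
            if not shorter_event:
                continue
            den += 1
            if risks[i] > risks[j]:
                num += 1.0
            elif risks[i] == risks[j]:
                num += 0.5
    return num / den
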