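"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use different algorithms from the package:
flood fill instead of scipy labeling, exhaustive all-pairs instead of a
hull reduction, exact rational halfspace arithmetic instead of float
geometry, and full enumeration of group assignments instead of the
rank-sum null recurrence.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from osteolacuna.volume_io import VoxelVolume


# ---------------------------------------------------------------------------
# oracle: connected-component labeling by flood fill


def _neighbours(connectivity: int):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Reference labeling: BFS flood fill over the chosen neighbourhood."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    offs = _neighbours(connectivity)
    current = 0
    for idx in np.argwhere(mask):
        if labels[tuple(idx)]:
            continue
        current += 1
        queue = deque([tuple(idx)])
        labels[tuple(idx)] = current
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(n, mask.shape)) and mask[n] and not labels[n]:
                    labels[n] = current
                    queue.append(n)
    return labels


def same_partition(lab_a: np.ndarray, lab_b: np.ndarray) -> bool:
    """Two labelings describe the same partition of the foreground."""
    if (lab_a > 0).sum() != (lab_b > 0).sum() or lab_a.max() != lab_b.max():
        return False
    mapping: dict[int, int] = {}
    for a, b in zip(lab_a[lab_a > 0].ravel(), lab_b[lab_a > 0].ravel()):
        if b == 0 or mapping.setdefault(int(a), int(b)) != int(b):
            return False
    return len(set(mapping.values())) == len(mapping)


# ---------------------------------------------------------------------------
# oracle: exact rational point-in-hull count


def rational_hull_point_count(voxels: np.ndarray) -> int:
    """Integer bounding-box grid points inside-or-on the convex hull of
    integer points, decided in exact rational arithmetic.

    Facet planes are taken through the hull simplices reported by qhull,
    but normals and offsets are rebuilt as exact integers from the
    simplex vertices, so every membership decision is exact.
    """
    from scipy.spatial import ConvexHull

    pts = [tuple(int(v) for v in p) for p in voxels]
    hull = ConvexHull(np.asarray(voxels, dtype=float))
    interior = [Fraction(int(voxels[:, k].sum()), len(voxels)) for k in range(3)]
    planes = []
    for simplex in hull.simplices:
        p0, p1, p2 = (np.asarray(pts[i], dtype=object) for i in simplex)
        v1 = p1 - p0
        v2 = p2 - p0
        n = (
            int(v1[1] * v2[2] - v1[2] * v2[1]),
            int(v1[2] * v2[0] - v1[0] * v2[2]),
            int(v1[0] * v2[1] - v1[1] * v2[0]),
        )
        if n == (0, 0, 0):
            continue
        d = sum(int(ni) * int(pi) for ni, pi in zip(n, p0))
        side = sum(Fraction(ni) * ci for ni, ci in zip(n, interior)) - d
        if side > 0:
            n = tuple(-ni for ni in n)
            d = -d
        planes.append((n, d))
    lo = voxels.min(axis=0)
    hi = voxels.max(axis=0)
    count = 0
    for z in range(lo[0], hi[0] + 1):
        for y in range(lo[1], hi[1] + 1):
            for x in range(lo[2], hi[2] + 1):
                if all(n[0] * z + n[1] * y + n[2] * x <= d for n, d in planes):
                    count += 1
    return count


# ---------------------------------------------------------------------------
# oracle: rank-sum by full enumeration of group assignments


def enumerate_rank_sum_p(a, b) -> tuple[float, float]:
    """(U1, two-sided p) by enumerating all C(n1+n2, n1) assignments."""
    a = list(a)
    b = list(b)
    n1 = len(a)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free data only

    def u_of(group_ranks):
        return sum(group_ranks) - n1 * (n1 + 1) / 2

    u_obs = u_of([ranks[v] for v in a])
    u_min = min(u_obs, n1 * len(b) - u_obs)
    hits = sum(
        u_of(chosen) <= u_min
        for chosen in combinations(range(1, len(pooled) + 1), n1)
    )
    total = comb(len(pooled), n1)
    return u_obs, min(1.0, 2.0 * hits / total)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_blob(rng, n_voxels: int, shape=(40, 40, 40)) -> np.ndarray:
    """Connected random voxel set grown by a random walk (indices (z,y,x))."""
    pos = np.array(shape) // 2
    seen = {tuple(pos)}
    while len(seen) < n_voxels:
        step = np.zeros(3, dtype=int)
        axis = rng.integers(0, 3)
        step[axis] = rng.choice((-1, 1))
        pos = np.clip(pos + step, 0, np.array(shape) - 1)
        seen.add(tuple(pos))
    return np.array(sorted(seen))


def make_volume(data, voxel_size_um=1.0, origin=(0.0, 0.0, 0.0)) -> VoxelVolume:
    return VoxelVolume(np.asarray(data), voxel_size_um, origin)
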