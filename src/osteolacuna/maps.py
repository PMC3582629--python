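"""Qualitative field maps of lacuna density, volume and orientation.

Three exportable fields summarise a labeled cube visually:

* ``density_field`` — a Gaussian-smoothed point cloud of lacuna
  centroids (each lacuna contributes one unit of mass),
* ``volume_field`` — every voxel of a component painted with that
  component's physical volume,
* ``orientation_rgb`` — every voxel painted with the absolute components
  (|dx|, |dy|, |dz|) of its component's maximum-length direction (the
  symmetric "RGB tripod" coding; Feret direction sign is arbitrary).

These maps are qualitative exports; no quantitative conclusion of the
pipeline depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .extraction import LabeledVolume
from .morphometry import LacunaRecord


class MapError(Exception):
    pass


@dataclass
class FieldMap:
    grid: np.ndarray  # (Z,Y,X) scalar or (Z,Y,X,3) for orientation
    voxel_size_um: float
    kind: str  # "density" | "volume" | "orientation"
    params: dict = field(default_factory=dict)


def density_field(
    records: list[LacunaRecord],
    grid_shape: tuple[int, int, int],
    voxel_size_um: float,
    sigma_um: float,
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> FieldMap:
    """Sum of normalised Gaussian kernels centered at lacuna centroids.

    Each lacuna deposits total mass 1 (in units of lacunae), so the sum
    over the grid approximates the lacuna count for interior centroids.
    """
    if sigma_um <= 0:
        raise MapError("sigma_um must be positive")
    if min(grid_shape) < 1:
        raise MapError("empty grid")
    grid = np.zeros(grid_shape, dtype=np.float64)
    s = voxel_size_um
    ox, oy, oz = origin_um
    for r in records:
        x, y, z = r.centroid_um
        idx = (int((z - oz) / s), int((y - oy) / s), int((x - ox) / s))
        if all(0 <= i < n for i, n in zip(idx, grid_shape)):
            grid[idx] += 1.0
    smoothed = ndimage.gaussian_filter(grid, sigma=sigma_um / s, mode="constant")
    return FieldMap(smoothed, voxel_size_um, "density", {"sigma_um": sigma_um})


def volume_field(lab: LabeledVolume, records: list[LacunaRecord]) -> FieldMap:
    """Paint every voxel of component i with volume_um3(i); background 0."""
    lookup = np.zeros(lab.n_components + 1, dtype=np.float64)
    seen = set()
    for r in records:
        lookup[r.id] = r.volume_um3
        seen.add(r.id)
    missing = set(range(1, lab.n_components + 1)) - seen
    if missing:
        raise MapError(f"labels without a record: {sorted(missing)[:5]}")
    return FieldMap(lookup[lab.labels], lab.voxel_size_um, "volume", {})


def orientation_rgb(lab: LabeledVolume, records: list[LacunaRecord]) -> FieldMap:
    """Paint voxels of component i with (|dx|, |dy|, |dz|) of its
    maximum-length direction; undefined directions map to neutral gray."""
    lookup = np.full((lab.n_components + 1, 3), 0.0)
    seen = set()
    for r in records:
        lookup[r.id] = np.abs(r.max_dir) if r.max_dir is not None else (0.5, 0.5, 0.5)
        seen.add(r.id)
    missing = set(range(1, lab.n_components + 1)) - seen
    if missing:
        raise MapError(f"labels without a record: {sorted(missing)[:5]}")
    lookup[0] = 0.0
    return FieldMap(lookup[lab.labels], lab.voxel_size_um, "orientation", {})


def save_midslice_png(fmap: FieldMap, path, axis: int = 0) -> None:
    """Write the central slice of a field map as a PNG preview."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mid = fmap.grid.shape[axis] // 2
    sl = np.take(fmap.grid, mid, axis=axis)
    fig, ax = plt.subplots(figsize=(4, 4))
    if fmap.kind == "orientation":
        ax.imshow(np.clip(sl, 0, 1))
    else:
        im = ax.imshow(sl, cmap="inferno")
        fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"{fmap.kind} (mid-slice)")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
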