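"""Synthetic cortical-bone phantom cubes with known ground truth.

The generator emulates the statistical structure of segmented micro-CT
cubes of osteocyte lacunae so the full analysis chain can be exercised
and validated without scan data:

* lacunae as non-overlapping particles — triaxial ellipsoids (compact,
  "round/oval" lacunae) or ellipsoid bodies with radiating spikes
  (stellate lacunae),
* lognormal body-volume distribution (lacuna volumes are right-skewed;
  a normal model fails a qq diagnostic),
* isotropic or axis-aligned particle orientation with angular scatter,
* optional vertical "stacks" of closely spaced lacunae and optional
  extrinsic-fibre cylinders spanning the cube,
* sub-threshold speckle (segmentation noise) and a grayscale renderer
  with point-spread blur and additive noise.

Every entry point is deterministic under its seed.  ``build_preset``
returns attachment/reference cube pairs whose generating parameters
encode the published comparison signatures for the Desmognathus,
Eusthenopteron and Compagopiscis attachment regions (density multiplier,
orientation similar/different, volume similar/different, stellate or
not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .volume_io import VoxelVolume

DEFAULT_VOXEL_SIZE_UM = 0.678

_AXIS_VEC = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


class GenerationError(Exception):
    pass


@dataclass(frozen=True)
class CompactShape:
    """Triaxial ellipsoid: long semi-axis `a`, equal short axes; a/b drawn
    uniformly from axis_ratio_range."""

    kind: Literal["compact"] = "compact"
    axis_ratio_range: tuple[float, float] = (1.5, 2.4)


@dataclass(frozen=True)
class StellateShape:
    """Ellipsoid body plus radiating spikes (thin capsules).

    One antipodal spike pair lies along the particle's orientation axis
    at full ``spike_length_um``; the remaining spikes point in random
    directions at 65–90 % of that length, so the maximum-length direction
    of the particle is its orientation axis by construction.
    """

    kind: Literal["stellate"] = "stellate"
    spike_count_range: tuple[int, int] = (8, 12)
    spike_length_um: float = 10.0
    spike_radius_um: float = 0.9
    body_axis_ratio_range: tuple[float, float] = (1.2, 1.8)


@dataclass(frozen=True)
class Orientation:
    mode: Literal["isotropic", "aligned"] = "isotropic"
    axis: Literal["x", "y", "z"] = "z"
    angular_sd_deg: float = 25.0


@dataclass(frozen=True)
class Clustering:
    mode: Literal["none", "stacks"] = "none"
    axis: Literal["x", "y", "z"] = "z"
    stack_count: int = 40
    jitter_um: float = 2.0
    spacing_um: float | None = None  # None: 1.2 × typical particle extent


@dataclass(frozen=True)
class Fibres:
    """Extrinsic-fibre cylinders spanning the whole cube."""

    count: int = 0
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)  # (X, Y, Z)
    radius_um: float = 1.2


@dataclass(frozen=True)
class SceneConfig:
    extents: tuple[int, int, int] = (200, 200, 200)  # (Z, Y, X)
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    lacuna_count: int = 200
    volume_mean_um3: float = 300.0  # mean of the lognormal body-volume law
    volume_sigma: float = 0.45  # lognormal sigma (log-space)
    shape: CompactShape | StellateShape = field(default_factory=CompactShape)
    orientation: Orientation = field(default_factory=Orientation)
    clustering: Clustering = field(default_factory=Clustering)
    fibres: Fibres | None = None
    speckle_count: int = 120
    speckle_size_range: tuple[int, int] = (1, 4)
    boundary_mode: Literal["interior_only", "allow_cut"] = "interior_only"
    seed: int = 0

    def validate(self) -> None:
        if min(self.extents) < 1:
            raise GenerationError("zero-extent cube")
        if self.voxel_size_um <= 0 or self.volume_mean_um3 <= 0 or self.volume_sigma < 0:
            raise GenerationError("physical sizes must be positive")
        if self.lacuna_count < 0 or self.speckle_count < 0:
            raise GenerationError("counts must be non-negative")
        if self.boundary_mode not in ("interior_only", "allow_cut"):
            raise GenerationError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass
class ParticleTruth:
    centroid_um: tuple[float, float, float]  # (X, Y, Z)
    voxel_count: int
    volume_um3: float  # rasterized volume
    body_volume_um3: float  # sampled analytic body volume
    direction: tuple[float, float, float]  # orientation axis (X, Y, Z), canonical sign
    shape_class: str  # "stellate" | "compact"
    cut_by_edge: bool  # has a voxel on a cube face after clipping


@dataclass
class GroundTruth:
    particles: list[ParticleTruth]
    specks: list[tuple[tuple[int, int, int], int]]  # (seed voxel (z,y,x), size)
    fibre_voxel_count: int = 0

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def n_uncut(self) -> int:
        return sum(1 for p in self.particles if not p.cut_by_edge)


# ---------------------------------------------------------------------------
# geometry helpers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _canonical(v: np.ndarray) -> np.ndarray:
    for c in v:
        if c != 0:
            return v if c > 0 else -v
    return v


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _sample_direction(orientation: Orientation, rng: np.random.Generator) -> np.ndarray:
    """Unit orientation vector in (X, Y, Z), canonical sign."""
    if orientation.mode == "isotropic":
        return _canonical(_random_unit(rng))
    e = _AXIS_VEC[orientation.axis]
    # tangent-plane Gaussian perturbation; angular scatter ~ angular_sd_deg
    sd = np.tan(np.deg2rad(min(orientation.angular_sd_deg, 60.0)))
    t1 = _unit(np.cross(e, [1.0, 0.7, 0.3]))
    t2 = np.cross(e, t1)
    g1, g2 = rng.normal(0, sd, size=2)
    return _canonical(_unit(e + g1 * t1 + g2 * t2))


def _basis_from(u: np.ndarray) -> np.ndarray:
    """Orthonormal 3x3 matrix whose first column is u."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = _unit(np.cross(u, ref))
    w = np.cross(u, v)
    return np.stack([u, v, w], axis=1)


def _grid_points(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, ...]:
    """Dense integer (z,y,x) coordinates of the box [lo, hi) as flat arrays."""
    gz, gy, gx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    return gz.ravel(), gy.ravel(), gx.ravel()


def _offsets_um(gz, gy, gx, center_vox: np.ndarray, s: float) -> np.ndarray:
    """Physical (X,Y,Z) offsets in µm of voxel centers from the particle center."""
    cz, cy, cx = center_vox
    return np.stack([(gx - cx) * s, (gy - cy) * s, (gz - cz) * s], axis=1)


def _ellipsoid_voxels(center_vox, R, a: float, b: float, s: float) -> np.ndarray:
    r_vox = int(np.ceil(a / s)) + 1
    lo = np.floor(center_vox - r_vox).astype(int)
    hi = np.ceil(center_vox + r_vox).astype(int) + 1
    gz, gy, gx = _grid_points(lo, hi)
    q = _offsets_um(gz, gy, gx, center_vox, s) @ R
    inside = (q[:, 0] / a) ** 2 + (q[:, 1] / b) ** 2 + (q[:, 2] / b) ** 2 <= 1.0
    return np.stack([gz[inside], gy[inside], gx[inside]], axis=1)


def _capsule_voxels(center_vox, d_xyz, L: float, r: float, s: float) -> np.ndarray:
    """Voxels within distance r of the segment center→center + L·d."""
    step_zyx = np.array([d_xyz[2], d_xyz[1], d_xyz[0]]) * (L / s)
    pad = r / s + 1.0
    lo = np.floor(np.minimum(center_vox, center_vox + step_zyx) - pad).astype(int)
    hi = np.ceil(np.maximum(center_vox, center_vox + step_zyx) + pad).astype(int) + 1
    gz, gy, gx = _grid_points(lo, hi)
    p = _offsets_um(gz, gy, gx, center_vox, s)
    t = np.clip(p @ d_xyz, 0.0, L)
    diff = p - t[:, None] * d_xyz
    inside = np.einsum("ij,ij->i", diff, diff) <= r * r
    return np.stack([gz[inside], gy[inside], gx[inside]], axis=1)


def _rasterize_shape(
    phase: np.ndarray,  # sub-voxel offset in [0,1)³, (z,y,x)
    u_xyz: np.ndarray,
    body_volume_um3: float,
    shape: CompactShape | StellateShape,
    voxel_size: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize one particle (body ellipsoid plus optional spikes) around
    the origin at a given sub-voxel phase.

    Returns integer (z,y,x) voxel offsets (may be negative).  Each
    primitive is rasterized in its own bounding box and the voxel sets
    are merged, so thin spikes stay cheap.  The shape is computed once
    per particle; placement attempts translate it by integer offsets.
    """
    s = voxel_size
    center = np.asarray(phase, dtype=float)
    if isinstance(shape, CompactShape):
        q = rng.uniform(*shape.axis_ratio_range)
    else:
        q = rng.uniform(*shape.body_axis_ratio_range)
    b = (3.0 * body_volume_um3 / (4.0 * np.pi * q)) ** (1.0 / 3.0)
    a = q * b
    spikes: list[tuple[np.ndarray, float]] = []
    if isinstance(shape, StellateShape):
        # spikes always protrude well beyond the body, so large-bodied
        # particles stay star-like (low solidity) too
        L = max(shape.spike_length_um, 1.6 * a)
        k = int(rng.integers(shape.spike_count_range[0], shape.spike_count_range[1] + 1))
        spikes = [(u_xyz, L), (-u_xyz, L)]
        for _ in range(max(k - 2, 0)):
            spikes.append((_random_unit(rng), L * rng.uniform(0.65, 0.9)))
    parts = [_ellipsoid_voxels(center, _basis_from(u_xyz), a, b, s)]
    if spikes:
        r_spike = shape.spike_radius_um  # type: ignore[union-attr]
        for d, L in spikes:
            parts.append(_capsule_voxels(center, d, L, r_spike, s))
    vox = np.concatenate(parts)
    lo = vox.min(axis=0)
    span = vox.max(axis=0) - lo + 1
    key = (vox - lo) @ np.array([span[1] * span[2], span[2], 1])
    return vox[np.unique(key, return_index=True)[1]]


_DILATE = ndimage.generate_binary_structure(3, 3)


class _Occupancy:
    """Occupancy grid with a 26-dilated shadow, so that a conflict test
    ("would this voxel set overlap or touch an existing particle?") is a
    single fancy-index lookup.  The separation guarantees that separately
    placed particles never merge under connected-component labeling."""

    def __init__(self, extents: tuple[int, int, int]):
        self.grid = np.zeros(extents, dtype=bool)
        self.dilated = np.zeros(extents, dtype=bool)

    def conflicts(self, vox: np.ndarray) -> bool:
        return bool(self.dilated[vox[:, 0], vox[:, 1], vox[:, 2]].any())

    def add(self, vox: np.ndarray) -> None:
        self.grid[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        lo = np.maximum(vox.min(axis=0) - 1, 0)
        hi = np.minimum(vox.max(axis=0) + 2, self.grid.shape)
        local = np.zeros(hi - lo, dtype=bool)
        rel = vox - lo
        local[rel[:, 0], rel[:, 1], rel[:, 2]] = True
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        self.dilated[sl] |= ndimage.binary_dilation(local, structure=_DILATE)

    def add_mask(self, mask: np.ndarray) -> None:
        self.grid |= mask
        self.dilated |= ndimage.binary_dilation(mask, structure=_DILATE)


def _stack_centers(
    cfg: SceneConfig, rng: np.random.Generator, typical_extent_um: float
) -> list[np.ndarray]:
    """Proposed centers (voxel coords, (z,y,x)) for stack clustering.

    Stacks are centered on their anchor and sized so the whole run of
    particles fits inside the cube; spacing defaults to 1.2× the typical
    particle extent so consecutive stack members sit close without
    forcing overlap rejections."""
    cl = cfg.clustering
    s = cfg.voxel_size_um
    spacing = (cl.spacing_um or 1.2 * typical_extent_um) / s
    axis_xyz = _AXIS_VEC[cl.axis]
    step = np.array([axis_xyz[2], axis_xyz[1], axis_xyz[0]]) * spacing  # to (z,y,x)
    jitter = cl.jitter_um / s
    ext = np.array(cfg.extents, dtype=float)
    per_stack = int(np.ceil(cfg.lacuna_count / max(cl.stack_count, 1)))
    # shrink stacks that cannot fit along the axis
    margin = typical_extent_um / (2 * s)
    axis_dim = {"z": 0, "y": 1, "x": 2}[cl.axis]
    while per_stack > 1 and (per_stack - 1) * spacing > ext[axis_dim] - 2 * margin:
        per_stack -= 1
    centers = []
    n_stacks = int(np.ceil(cfg.lacuna_count * 2 / per_stack))
    span = (per_stack - 1) * spacing
    lo = np.full(3, margin)
    lo[axis_dim] += span / 2
    for _ in range(n_stacks):
        anchor = lo + rng.uniform(size=3) * np.maximum(ext - 2 * lo, 1.0)
        for m in range(per_stack):
            centers.append(anchor + (m - (per_stack - 1) / 2) * step + rng.normal(0, jitter, size=3))
    rng.shuffle(centers)
    return [np.asarray(c) for c in centers]


def generate_scene(config: SceneConfig) -> tuple[VoxelVolume, GroundTruth]:
    """Generate a clean binary phantom cube and its ground truth.

    Particles are placed by rejection sampling with a 26-neighbourhood
    separation constraint, so each rasterized lacuna is exactly one
    connected component.  Raises :class:`GenerationError` if the requested
    density cannot be packed within the attempt budget.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ext = np.array(config.extents)
    occ = _Occupancy(config.extents)
    s = config.voxel_size_um
    truth_particles: list[ParticleTruth] = []
    fibre_voxels = 0

    # fibres first: lacunae then avoid them
    if config.fibres is not None and config.fibres.count > 0:
        d = _unit(np.asarray(config.fibres.direction, dtype=float))
        r2 = config.fibres.radius_um**2
        gz, gy, gx = np.meshgrid(*(np.arange(n) for n in ext), indexing="ij", sparse=True)
        fibre_mask = np.zeros(config.extents, dtype=bool)
        for _ in range(config.fibres.count):
            p0 = rng.uniform(0, 1, size=3) * ext  # (z,y,x) voxel coords
            px = (gx + 0.5 - p0[2]) * s
            py = (gy + 0.5 - p0[1]) * s
            pz = (gz + 0.5 - p0[0]) * s
            t = px * d[0] + py * d[1] + pz * d[2]
            dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
            fibre_mask |= dist2 <= r2
        occ.add_mask(fibre_mask)
        fibre_voxels = int(fibre_mask.sum())

    mu = np.log(config.volume_mean_um3) - config.volume_sigma**2 / 2.0

    proposed: list[np.ndarray] | None = None
    if config.clustering.mode == "stacks" and config.lacuna_count > 0:
        typical = 2.0 * (3.0 * config.volume_mean_um3 / (4 * np.pi)) ** (1 / 3)
        if isinstance(config.shape, StellateShape):
            typical = max(typical, 2 * (config.shape.spike_length_um + config.shape.spike_radius_um))
        proposed = _stack_centers(config, rng, typical)

    max_attempts = 4000
    for _i in range(config.lacuna_count):
        body_volume = float(rng.lognormal(mu, config.volume_sigma))
        u = _sample_direction(config.orientation, rng)
        rel = _rasterize_shape(rng.uniform(0, 1, size=3), u, body_volume, config.shape, s, rng)
        rel_lo = rel.min(axis=0)
        rel_hi = rel.max(axis=0)
        placed = False
        proposal_tries = 0
        for _attempt in range(max_attempts):
            if _attempt and _attempt % 500 == 0:
                # re-rasterize the same geometry at a fresh sub-voxel phase
                rel = _rasterize_shape(rng.uniform(0, 1, size=3), u, body_volume, config.shape, s, rng)
                rel_lo = rel.min(axis=0)
                rel_hi = rel.max(axis=0)
            if proposed and proposal_tries < 15:
                # stack proposals first; fall back to uniform placement if
                # the neighbourhood is too crowded
                proposal_tries += 1
                c = np.clip(proposed.pop(), 1.0, ext - 2.0)
            elif config.boundary_mode == "interior_only":
                c = rng.uniform(0, 1, size=3) * (ext - 2.0) + 1.0
            else:
                c = rng.uniform(0, 1, size=3) * ext
            ci = np.round(c).astype(int)
            if config.boundary_mode == "interior_only":
                # every voxel strictly off the six faces
                if (ci + rel_lo < 1).any() or (ci + rel_hi > ext - 2).any():
                    continue
                vox = rel + ci
                touches_face = False
            else:
                vox = rel + ci
                inside = np.all((vox >= 0) & (vox < ext), axis=1)
                if not inside.any():
                    continue
                vox = vox[inside]
                touches_face = bool(((vox == 0) | (vox == ext - 1)).any())
            if occ.conflicts(vox):
                continue
            occ.add(vox)
            centroid_idx = vox.mean(axis=0)
            truth_particles.append(
                ParticleTruth(
                    centroid_um=(
                        (centroid_idx[2] + 0.5) * s,
                        (centroid_idx[1] + 0.5) * s,
                        (centroid_idx[0] + 0.5) * s,
                    ),
                    voxel_count=len(vox),
                    volume_um3=len(vox) * s**3,
                    body_volume_um3=body_volume,
                    direction=tuple(u),
                    shape_class="stellate" if isinstance(config.shape, StellateShape) else "compact",
                    cut_by_edge=touches_face,
                )
            )
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"unplaceable density: failed to place particle {_i + 1}/{config.lacuna_count} "
                f"after {max_attempts} attempts (cube {tuple(ext)}, fill "
                f"{occ.grid.mean():.1%})"
            )

    specks: list[tuple[tuple[int, int, int], int]] = []
    lo_size, hi_size = config.speckle_size_range
    for _ in range(config.speckle_count):
        size = int(rng.integers(lo_size, hi_size + 1))
        for _attempt in range(max_attempts):
            start = tuple(int(v) for v in rng.integers(0, ext))
            cells = [np.array(start)]
            for _g in range(size - 1):
                step = np.zeros(3, dtype=int)
                axis = int(rng.integers(0, 3))
                step[axis] = 1 if rng.random() < 0.5 else -1
                cells.append(np.clip(cells[-1] + step, 0, ext - 1))
            vox = np.unique(np.stack(cells), axis=0)
            if occ.conflicts(vox):
                continue
            occ.add(vox)
            specks.append((start, len(vox)))
            break
        else:
            raise GenerationError("unplaceable speckle noise")

    mask = VoxelVolume(occ.grid.astype(np.uint8), s)
    return mask, GroundTruth(truth_particles, specks, fibre_voxels)


def render_grayscale(
    mask: VoxelVolume,
    contrast: tuple[float, float] = (200.0, 60.0),
    noise_sd: float = 0.0,
    blur_sigma_um: float = 0.0,
    seed: int = 0,
) -> VoxelVolume:
    """Render a binary mask as a grayscale scan.

    ``contrast = (bg_level, fg_level)``: background (bone matrix) and
    foreground (lacuna) intensity.  The two-level image is convolved with
    a Gaussian point-spread of ``blur_sigma_um`` and corrupted with
    additive Gaussian noise of standard deviation ``noise_sd``.
    Deterministic under *seed*.
    """
    bg, fg = contrast
    if fg == bg:
        raise ValueError("fg_level must differ from bg_level")
    if noise_sd < 0:
        raise ValueError("negative noise_sd")
    if blur_sigma_um < 0:
        raise ValueError("negative blur_sigma_um")
    img = np.where(mask.data > 0, float(fg), float(bg)).astype(np.float32)
    if blur_sigma_um > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma_um / mask.voxel_size_um, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    return VoxelVolume(img, mask.voxel_size_um, mask.origin_um)


# ---------------------------------------------------------------------------
# Presets encoding the published attachment/reference signatures
#
# Each preset returns (attachment SceneConfig, reference SceneConfig).
# The attachment cube's parameters encode the published comparison row:
# retained-count multiplier relative to the reference cube, orientation
# similar (both isotropic) or different (aligned vs isotropic), volume
# similar (same lognormal) or different (shifted mean), stellate or
# compact shape.  Counts are post-filter retained counts: presets place
# lacunae interior-only, so the noise and edge-cut filters leave exactly
# the placed population.  Eusthenopteron fibre-bearing areas hold the
# published 450–500 lacunae per cube; other absolute counts are free
# choices at realistic fill fractions, with the published multipliers.

_DESMO_REF = dict(lacuna_count=140, volume_mean_um3=300.0, volume_sigma=0.45,
                  shape=CompactShape(axis_ratio_range=(1.5, 2.4)))
_EUSTH_REF = dict(lacuna_count=315, volume_mean_um3=260.0, volume_sigma=0.40,
                  shape=CompactShape(axis_ratio_range=(1.3, 2.0)))
_COMPAG_REF = dict(lacuna_count=250, volume_mean_um3=280.0, volume_sigma=0.40,
                   shape=CompactShape(axis_ratio_range=(1.5, 2.2)))

_ALIGNED = Orientation(mode="aligned", axis="z", angular_sd_deg=25.0)
_ISO = Orientation(mode="isotropic")


def _preset_table() -> dict[str, tuple[dict, dict]]:
    stellate = StellateShape()
    return {
        # density ×2.5, orientation different, volume different, stellate
        "desmognathus_umfe": (
            dict(lacuna_count=350, volume_mean_um3=330.0, volume_sigma=0.45,
                 shape=stellate, orientation=Orientation(mode="aligned", axis="z", angular_sd_deg=20.0),
                 clustering=Clustering(mode="stacks", axis="z", stack_count=80, jitter_um=2.0, spacing_um=29.0)),
            _DESMO_REF,
        ),
        # density ×1.8, orientation different, volume similar, compact
        "desmognathus_pmfe": (
            dict(lacuna_count=252, volume_mean_um3=300.0, volume_sigma=0.45,
                 shape=CompactShape(axis_ratio_range=(1.5, 2.4)), orientation=_ALIGNED),
            _DESMO_REF,
        ),
        # ×1.5 (≥), different, similar, compact; 450–500 lacunae in the cube
        "eusthenopteron_area1": (
            dict(_EUSTH_REF, lacuna_count=490, orientation=_ALIGNED),
            _EUSTH_REF,
        ),
        # ×1.5, similar orientation, larger volumes (the anomalous region), compact
        "eusthenopteron_area2": (
            dict(_EUSTH_REF, lacuna_count=473, volume_mean_um3=340.0, orientation=_ISO),
            _EUSTH_REF,
        ),
        # ×1.7, different, similar, compact
        "eusthenopteron_area3": (
            dict(_EUSTH_REF, lacuna_count=536, orientation=_ALIGNED),
            _EUSTH_REF,
        ),
        "eusthenopteron_area4": (_EUSTH_REF, _EUSTH_REF),
        # ×1.04 / ×1.3 / ×1.2, different, different, stellate
        "compagopiscis_area1": (
            dict(lacuna_count=260, volume_mean_um3=300.0, volume_sigma=0.40,
                 shape=stellate, orientation=_ALIGNED),
            _COMPAG_REF,
        ),
        "compagopiscis_area2": (
            dict(lacuna_count=325, volume_mean_um3=300.0, volume_sigma=0.40,
                 shape=stellate, orientation=_ALIGNED),
            _COMPAG_REF,
        ),
        "compagopiscis_area3": (
            dict(lacuna_count=300, volume_mean_um3=300.0, volume_sigma=0.40,
                 shape=stellate, orientation=_ALIGNED),
            _COMPAG_REF,
        ),
        "compagopiscis_area4": (_COMPAG_REF, _COMPAG_REF),
    }


#: Published density multiplier encoded by each preset (attachment /
#: reference retained counts).
PRESET_DENSITY_MULTIPLIER = {
    "desmognathus_umfe": 2.5,
    "desmognathus_pmfe": 1.8,
    "eusthenopteron_area1": 490 / 315,
    "eusthenopteron_area2": 473 / 315,
    "eusthenopteron_area3": 536 / 315,
    "eusthenopteron_area4": 1.0,
    "compagopiscis_area1": 1.04,
    "compagopiscis_area2": 1.3,
    "compagopiscis_area3": 1.2,
    "compagopiscis_area4": 1.0,
}


def preset_names() -> list[str]:
    return sorted(_preset_table().keys())


def build_preset(
    name: str,
    extents: tuple[int, int, int] = (200, 200, 200),
    seed: int = 0,
) -> tuple[SceneConfig, SceneConfig]:
    """Attachment/reference SceneConfig pair for a named comparison.

    The two cubes share extents, voxel size and speckle settings; the
    reference cube uses a seed offset so the pair is independent.  The
    table's lacuna counts refer to a 200³-voxel cube; other extents
    scale the counts proportionally to the cube volume, preserving the
    number densities and hence the encoded density multiplier.
    """
    table = _preset_table()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(sorted(table))}")
    att_kw, ref_kw = table[name]
    scale = float(np.prod(extents)) / 200**3
    base = dict(extents=tuple(extents), voxel_size_um=DEFAULT_VOXEL_SIZE_UM,
                speckle_count=max(1, round(120 * scale)), boundary_mode="interior_only")
    att_kw = dict(att_kw, lacuna_count=max(1, round(att_kw["lacuna_count"] * scale)))
    ref_kw = dict(ref_kw, lacuna_count=max(1, round(ref_kw["lacuna_count"] * scale)))
    attachment = SceneConfig(**base, **att_kw, seed=seed)
    reference = SceneConfig(**base, **ref_kw, seed=seed + 500_000)
    return attachment, reference
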