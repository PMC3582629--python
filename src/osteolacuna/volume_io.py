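"""Reading, writing and cropping 3D voxel volumes with physical metadata.

Volumes are kept as plain numpy arrays indexed ``(Z, Y, X)`` (slice-major,
the order in which a TIFF stack is paged), while every physical-space
3-vector — the origin and, downstream, centroids and direction vectors —
is expressed in ``(X, Y, Z)`` order.  The voxel grid is isotropic: a single
``voxel_size_um`` applies to all three axes.  The physical coordinate of
the *corner* of voxel ``(i, j, k)`` (index order) is::

    (x, y, z) = origin_um + voxel_size_um * (k, j, i)

Three on-disk formats are supported: multi-page TIFF, NRRD (raw encoding)
and raw binary with a JSON sidecar.  Each round-trips the data bit-exactly
together with the voxel size and origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

AXIS_ORDER = ("Z", "Y", "X")
_SUPPORTED_EXTENSIONS = (".tif", ".tiff", ".nrrd", ".raw")


class VolumeIOError(Exception):
    """Raised for malformed files, unsupported formats or bad metadata."""


class MissingVoxelSizeError(VolumeIOError):
    """The container carries no voxel size and no override was given."""


@dataclass
class VoxelVolume:
    """A 3D scalar grid with isotropic voxel size in micrometres.

    Parameters
    ----------
    data
        3D array, indexed (Z, Y, X).  Intensities or a {0, 1} mask.
    voxel_size_um
        Isotropic voxel edge length in µm.
    origin_um
        Physical coordinate (X, Y, Z) of the corner of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: tuple[str, str, str] = AXIS_ORDER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(f"expected a 3D grid, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise VolumeIOError("all three grid extents must be >= 1")
        if not (self.voxel_size_um > 0):
            raise VolumeIOError("voxel_size_um must be positive")
        self.origin_um = tuple(float(v) for v in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        """Edge lengths (X, Y, Z) of the grid in µm."""
        nz, ny, nx = self.data.shape
        return (nx * self.voxel_size_um, ny * self.voxel_size_um, nz * self.voxel_size_um)

    def volume_mm3(self) -> float:
        """Physical volume of the whole grid in mm³."""
        return float(np.prod(self.data.shape)) * (self.voxel_size_um * 1e-3) ** 3


@dataclass(frozen=True)
class RegionSpec:
    """A half-open cuboid region ``[lo, hi)`` in index space (Z, Y, X)."""

    name: str
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    role: str = "attachment"  # "attachment" | "reference"

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if any(h <= l for l, h in zip(lo, hi)):
            raise ValueError(f"region {self.name!r}: lo must be < hi componentwise, got lo={lo} hi={hi}")
        if self.role not in ("attachment", "reference"):
            raise ValueError(f"region role must be 'attachment' or 'reference', got {self.role!r}")

    @property
    def extents(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def voxel_count(self) -> int:
        return int(np.prod(self.extents))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _metadata_dict(vol: VoxelVolume) -> dict:
    return {
        "voxel_size_um": vol.voxel_size_um,
        "origin_um": list(vol.origin_um),
        "axis_order": list(vol.axis_order),
    }


# ---------------------------------------------------------------------------
# NRRD (raw encoding, little-endian) — minimal reader/writer


_NRRD_TYPES = {
    "uint8": np.uint8, "uchar": np.uint8,
    "uint16": np.uint16, "unsigned short": np.uint16,
    "int16": np.int16, "short": np.int16,
    "int32": np.int32, "int": np.int32,
    "uint32": np.uint32,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAMES = {np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16",
               np.dtype(np.int16): "int16", np.dtype(np.int32): "int32",
               np.dtype(np.uint32): "uint32", np.dtype(np.float32): "float",
               np.dtype(np.float64): "double"}


def _write_nrrd(vol: VoxelVolume, path: Path) -> None:
    dtype = vol.data.dtype
    if dtype == np.bool_:
        data = vol.data.astype(np.uint8)
        dtype = data.dtype
    else:
        if dtype not in _NRRD_NAMES:
            raise VolumeIOError(f"dtype {dtype} not supported for NRRD output")
        data = vol.data
    nz, ny, nx = data.shape
    s = vol.voxel_size_um
    ox, oy, oz = vol.origin_um
    # NRRD sizes are fastest axis first; our memory order is (Z,Y,X) C-order,
    # so the fastest-varying axis is X.
    header = [
        "NRRD0004",
        "# minimal raw-encoding NRRD",
        f"type: {_NRRD_NAMES[np.dtype(dtype)]}",
        "dimension: 3",
        "space: right-anterior-superior",
        f"sizes: {nx} {ny} {nz}",
        f"space directions: ({s},0,0) (0,{s},0) (0,0,{s})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        f"space origin: ({ox},{oy},{oz})",
        "",
        "",
    ]
    buf = data.astype(data.dtype.newbyteorder("<"), copy=False).tobytes()
    path.write_bytes("\n".join(header).encode("ascii") + buf)


def _parse_nrrd_vector(text: str) -> tuple[float, ...]:
    return tuple(float(v) for v in text.strip().lstrip("(").rstrip(")").split(","))


def _read_nrrd(path: Path, voxel_size_override: float | None) -> VoxelVolume:
    raw = path.read_bytes()
    end = raw.find(b"\n\n")
    if end < 0:
        raise VolumeIOError(f"{path}: malformed NRRD header (no blank line)")
    lines = raw[:end].decode("ascii", errors="replace").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise VolumeIOError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.strip()
    if fields.get("encoding", "raw") != "raw":
        raise VolumeIOError(f"{path}: only raw NRRD encoding is supported")
    try:
        dtype = np.dtype(_NRRD_TYPES[fields["type"]])
        sizes = tuple(int(v) for v in fields["sizes"].split())
    except KeyError as exc:
        raise VolumeIOError(f"{path}: missing NRRD field {exc}") from exc
    if len(sizes) != 3:
        raise VolumeIOError(f"{path}: expected 3D NRRD, got sizes {sizes}")
    voxel_size = voxel_size_override
    if "space directions" in fields:
        vecs = [_parse_nrrd_vector(v) for v in fields["space directions"].replace(") (", ")|(").split("|")]
        spacings = [float(np.linalg.norm(v)) for v in vecs]
        if max(spacings) - min(spacings) > 1e-9 * max(spacings):
            raise VolumeIOError(f"{path}: isotropic voxels required, got spacings {spacings}")
        if voxel_size is None:
            voxel_size = spacings[0]
    elif "spacings" in fields:
        spacings = [float(v) for v in fields["spacings"].split()]
        if max(spacings) - min(spacings) > 1e-9 * max(spacings):
            raise VolumeIOError(f"{path}: isotropic voxels required, got spacings {spacings}")
        if voxel_size is None:
            voxel_size = spacings[0]
    if voxel_size is None:
        raise MissingVoxelSizeError(f"{path}: NRRD header carries no voxel size and no override was given")
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        origin = _parse_nrrd_vector(fields["space origin"])
    if fields.get("endian", "little") != "little":
        dtype = dtype.newbyteorder(">")
    nx, ny, nz = sizes
    expected = nx * ny * nz * dtype.itemsize
    buf = raw[end + 2:]
    if len(buf) < expected:
        raise VolumeIOError(f"{path}: truncated NRRD payload ({len(buf)} < {expected} bytes)")
    data = np.frombuffer(buf[:expected], dtype=dtype).reshape(nz, ny, nx)
    return VoxelVolume(np.ascontiguousarray(data), voxel_size, tuple(origin))


# ---------------------------------------------------------------------------
# TIFF stack


def _write_tiff(vol: VoxelVolume, path: Path) -> None:
    data = vol.data.astype(np.uint8) if vol.data.dtype == np.bool_ else vol.data
    tifffile.imwrite(path, data, description=json.dumps(_metadata_dict(vol)))
    _sidecar_path(path).write_text(json.dumps(_metadata_dict(vol), indent=1))


def _read_tiff(path: Path, voxel_size_override: float | None) -> VoxelVolume:
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise VolumeIOError(f"{path}: inconsistent slice shapes in stack: {sorted(shapes)}")
        data = tif.asarray()
        description = tif.pages[0].description or ""
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D stack, got {data.ndim}D data")
    meta: dict = {}
    try:
        meta = json.loads(description)
    except (json.JSONDecodeError, TypeError):
        pass
    if not meta:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
    voxel_size = voxel_size_override if voxel_size_override is not None else meta.get("voxel_size_um")
    if voxel_size is None:
        raise MissingVoxelSizeError(
            f"{path}: TIFF carries no voxel size (no JSON description or sidecar); pass voxel_size_override"
        )
    origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
    return VoxelVolume(data, float(voxel_size), origin)


# ---------------------------------------------------------------------------
# Raw + JSON sidecar


def _write_raw(vol: VoxelVolume, path: Path) -> None:
    data = vol.data.astype(np.uint8) if vol.data.dtype == np.bool_ else vol.data
    if data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise VolumeIOError("raw format supports uint8/uint16 only; use TIFF or NRRD")
    path.write_bytes(np.ascontiguousarray(data.astype(data.dtype.newbyteorder("<"))).tobytes())
    meta = _metadata_dict(vol)
    meta["shape"] = list(data.shape)
    meta["dtype"] = data.dtype.name
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_raw(path: Path, voxel_size_override: float | None) -> VoxelVolume:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeIOError(f"{path}: raw volume requires a JSON sidecar at {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta["dtype"]).newbyteorder("<")
    data = np.frombuffer(path.read_bytes(), dtype=dtype).reshape(shape)
    voxel_size = voxel_size_override if voxel_size_override is not None else meta.get("voxel_size_um")
    if voxel_size is None:
        raise MissingVoxelSizeError(f"{path}: sidecar has no voxel_size_um and no override was given")
    return VoxelVolume(np.ascontiguousarray(data), float(voxel_size), tuple(meta.get("origin_um", (0, 0, 0))))


# ---------------------------------------------------------------------------
# Public API


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write *vol* to *path*; the extension selects the format.

    Supported: ``.tif``/``.tiff`` (multi-page stack, metadata in the image
    description and a JSON sidecar), ``.nrrd`` (raw encoding), ``.raw``
    (uint8/uint16 + JSON sidecar).
    """
    path = Path(path)
    if not path.parent.exists():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        _write_tiff(vol, path)
    elif suffix == ".nrrd":
        _write_nrrd(vol, path)
    elif suffix == ".raw":
        _write_raw(vol, path)
    else:
        raise VolumeIOError(
            f"unsupported extension {path.suffix!r}; supported formats: {', '.join(_SUPPORTED_EXTENSIONS)}"
        )
    return path


def read_volume(path: str | Path, voxel_size_override: float | None = None) -> VoxelVolume:
    """Read a volume written by :func:`write_volume` (or compatible files).

    Raises :class:`MissingVoxelSizeError` when the container carries no
    voxel size and *voxel_size_override* is None — never silently assumes
    a default spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if voxel_size_override is not None and not voxel_size_override > 0:
        raise VolumeIOError("voxel_size_override must be positive")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path, voxel_size_override)
    if suffix == ".nrrd":
        return _read_nrrd(path, voxel_size_override)
    if suffix == ".raw":
        return _read_raw(path, voxel_size_override)
    raise VolumeIOError(
        f"unsupported extension {path.suffix!r}; supported formats: {', '.join(_SUPPORTED_EXTENSIONS)}"
    )


def extract_cube(vol: VoxelVolume, region: RegionSpec) -> VoxelVolume:
    """Extract the half-open cuboid ``[lo, hi)`` as a new volume.

    The origin is shifted so every retained voxel keeps its physical
    coordinate.
    """
    for axis, (l, h, n) in enumerate(zip(region.lo, region.hi, vol.data.shape)):
        if l < 0 or h > n:
            raise IndexError(
                f"region {region.name!r} out of bounds on axis {AXIS_ORDER[axis]}: "
                f"[{l}, {h}) outside [0, {n})"
            )
    lz, ly, lx = region.lo
    hz, hy, hx = region.hi
    data = vol.data[lz:hz, ly:hy, lx:hx].copy()
    s = vol.voxel_size_um
    ox, oy, oz = vol.origin_um
    return VoxelVolume(data, s, (ox + lx * s, oy + ly * s, oz + lz * s))


def load_regions(path: str | Path) -> list[RegionSpec]:
    """Load a list of RegionSpec from a YAML or JSON config file.

    Expected structure::

        regions:
          - {name: cube1, lo: [0, 0, 0], hi: [200, 200, 200], role: attachment}
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    entries = doc["regions"] if isinstance(doc, dict) else doc
    return [RegionSpec(name=e["name"], lo=tuple(e["lo"]), hi=tuple(e["hi"]),
                       role=e.get("role", "attachment")) for e in entries]


def check_identical_extents(regions: Sequence[RegionSpec]) -> tuple[int, int, int]:
    """Verify all regions share one extent (comparison cubes must match)."""
    extents = {r.extents for r in regions}
    if len(extents) != 1:
        raise ValueError(f"regions in one comparison set must have identical extents, got {sorted(extents)}")
    return next(iter(extents))
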