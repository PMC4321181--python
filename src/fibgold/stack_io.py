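"""Volume and particle-table I/O and the coordinate contract.

Every array in the package is indexed ``(slice, row, col)`` = ``(z, y, x)``,
0-based.  Physical coordinates are nanometres; the centre of voxel
``(k, j, i)`` sits at ``origin + (k*dz, j*dy, i*dx)``.  Voxel ``k`` therefore
owns the half-open physical interval ``(z_k - dz/2, z_k + dz/2]`` along each
axis, so a point exactly on a voxel boundary belongs to the lower-index voxel.

Volumes are stored as multi-page TIFF or MRC2014; particle tables as RFC-4180
CSV with a header row.  TIFF resolution tags are never trusted: the caller
supplies the voxel size.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, SchemaError, ShapeError

#: Compartment legend shared by the whole pipeline.
COMPARTMENTS = {
    0: "outside",
    1: "cytoplasm",
    2: "nucleus_euchromatin",
    3: "nucleolus",
    4: "heterochromatin",
}

#: Label sets for the aggregate compartments used in reports.
NUCLEUS_LABELS = frozenset({2, 3, 4})
NUCLEUS_WITHOUT_NUCLEOLI_LABELS = frozenset({2, 4})
CELL_LABELS = frozenset({1, 2, 3, 4})

PARTICLE_COLUMNS = [
    "id",
    "x_nm",
    "y_nm",
    "z_nm",
    "n_voxels",
    "n_slices",
    "peak_intensity",
    "mean_intensity",
    "compartment",
]


@dataclass
class VoxelGrid:
    """A 3D scalar intensity volume with anisotropic physical voxel size.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``; intensities as stored, any scalar
        dtype.  Processing stages promote to float32.
    voxel_size
        ``(dz, dy, dx)`` in nm, all > 0.
    origin
        Physical position (nm) of voxel ``(0, 0, 0)``'s centre, as
        ``(z0, y0, x0)``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ShapeError(f"expected a 3D stack, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise FormatError(f"voxel_size must be three positive nm values, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def plane_z(self, k) -> np.ndarray | float:
        """Physical z (nm) of the imaged surface of slice ``k``."""
        return self.origin[0] + np.asarray(k) * self.voxel_size[0]

    def index_to_nm(self, index) -> np.ndarray:
        """Physical (z, y, x) nm of the centre of voxel ``index`` = (k, j, i)."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        out = np.asarray(self.origin) + idx * np.asarray(self.voxel_size)
        return out[0] if np.ndim(index) == 1 else out

    def nm_to_index(self, position) -> np.ndarray:
        """Voxel index (k, j, i) owning physical position (z, y, x) nm.

        Boundaries resolve to the lower-index voxel (half-open convention).
        """
        pos = np.atleast_2d(np.asarray(position, dtype=float))
        rel = (pos - np.asarray(self.origin)) / np.asarray(self.voxel_size)
        idx = np.ceil(rel - 0.5).astype(np.int64)
        return idx[0] if np.ndim(position) == 1 else idx

    def contains_nm(self, position) -> np.ndarray | bool:
        """Whether a physical (z, y, x) point lies inside the gridded volume."""
        idx = np.atleast_2d(self.nm_to_index(position))
        ok = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        return bool(ok[0]) if np.ndim(position) == 1 else ok

    def physical_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return self.data.size * dz * dy * dx * 1e-9

    def copy(self, data: np.ndarray | None = None) -> "VoxelGrid":
        return VoxelGrid(
            self.data.copy() if data is None else data,
            self.voxel_size,
            self.origin,
        )


@dataclass
class LabelVolume:
    """Integer compartment map congruent with a :class:`VoxelGrid`.

    ``legend`` maps label -> compartment name; the default is the five-way
    cell partition in :data:`COMPARTMENTS`.  The "whole nucleus" aggregate is
    labels {2, 3, 4}; "nucleus without nucleoli" is {2, 4}.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: dict = field(default_factory=lambda: dict(COMPARTMENTS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ShapeError(f"expected a 3D label volume, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be integer")
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.legend)
        if unknown:
            raise FormatError(f"labels {sorted(unknown)} missing from legend")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def as_grid(self) -> VoxelGrid:
        """View the labels as a VoxelGrid (shared coordinate contract)."""
        return VoxelGrid(self.labels, self.voxel_size, self.origin)

    def mask(self, labels) -> np.ndarray:
        """Boolean mask of the union of the given label values."""
        wanted = {labels} if np.isscalar(labels) else set(labels)
        return np.isin(self.labels, sorted(wanted))


# ---------------------------------------------------------------------------
# Minimal MRC2014 reader/writer (1024-byte header + raw C-ordered sections).
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODE_OF = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _write_mrc(path: Path, grid: VoxelGrid) -> None:
    data = grid.data
    if data.dtype not in _MRC_MODE_OF:
        raise FormatError(
            f"dtype {data.dtype} not representable in MRC (modes {sorted(_MRC_MODES)})"
        )
    nz, ny, nx = data.shape
    dz, dy, dx = grid.voxel_size
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, _MRC_MODE_OF[data.dtype])
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # sampling grid
    # cell dimensions in angstrom (1 nm = 10 A)
    struct.pack_into("<3f", header, 40, nx * dx * 10, ny * dy * 10, nz * dz * 10)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(data).tobytes())


def _read_mrc(path: Path, voxel_size=None) -> VoxelGrid:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise FormatError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode not in _MRC_MODES:
            raise FormatError(f"{path}: unsupported MRC mode {mode}")
        xlen, ylen, zlen = struct.unpack_from("<3f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        fh.seek(1024 + nsymbt)
        dtype = np.dtype(_MRC_MODES[mode])
        raw = fh.read(nx * ny * nz * dtype.itemsize)
    if len(raw) != nx * ny * nz * dtype.itemsize:
        raise FormatError(f"{path}: truncated MRC data block")
    data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx).copy()
    if voxel_size is None:
        if nx == 0 or ny == 0 or nz == 0 or xlen <= 0:
            raise FormatError(f"{path}: MRC header carries no usable voxel size")
        voxel_size = (zlen / nz / 10.0, ylen / ny / 10.0, xlen / nx / 10.0)
    return VoxelGrid(data, voxel_size)


# ---------------------------------------------------------------------------
# Public stack / label I/O
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_MRC_SUFFIXES = {".mrc", ".map", ".rec", ".st"}


def write_stack(path, grid: VoxelGrid) -> None:
    """Write a VoxelGrid as multi-page TIFF or MRC, chosen by suffix.

    The array is written bit-exactly in its in-memory dtype; the voxel size is
    stored in the format metadata (TIFF resolution tags in pixels/cm plus an
    ImageJ-style spacing, MRC cell dimensions).
    """
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        dz, dy, dx = grid.voxel_size
        tifffile.imwrite(
            path,
            grid.data,
            resolution=(1e7 / dx, 1e7 / dy),
            resolutionunit="CENTIMETER",
            metadata={"spacing": dz / 1000.0, "unit": "um", "axes": "ZYX"},
            imagej=grid.data.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
        )
    elif path.suffix.lower() in _MRC_SUFFIXES:
        _write_mrc(path, grid)
    else:
        raise FormatError(f"unrecognised volume suffix: {path.suffix!r}")


def read_stack(path, voxel_size=None) -> VoxelGrid:
    """Read a multi-page TIFF or MRC volume.

    ``voxel_size`` (dz, dy, dx in nm) overrides — and for TIFF must supply —
    the file metadata; TIFF tags are deliberately never guessed at.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # tifffile raises several internal types
            raise FormatError(f"{path}: unreadable TIFF ({exc})") from exc
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise ShapeError(f"{path}: expected 2D pages, got array of shape {data.shape}")
        if voxel_size is None:
            raise FormatError(f"{path}: TIFF voxel size must be supplied by the caller")
        return VoxelGrid(data, voxel_size)
    if suffix in _MRC_SUFFIXES:
        return _read_mrc(path, voxel_size)
    raise FormatError(f"unrecognised volume suffix: {path.suffix!r}")


def write_labels(path, labels: LabelVolume) -> None:
    grid = VoxelGrid(labels.labels.astype(np.uint8), labels.voxel_size, labels.origin)
    write_stack(path, grid)


def read_labels(path, voxel_size=None, legend=None) -> LabelVolume:
    grid = read_stack(path, voxel_size)
    return LabelVolume(
        grid.data.astype(np.int32),
        grid.voxel_size,
        grid.origin,
        legend=dict(COMPARTMENTS) if legend is None else legend,
    )


# ---------------------------------------------------------------------------
# Particle tables
# ---------------------------------------------------------------------------

def empty_particle_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        PARTICLE_COLUMNS,
        [np.int64, float, float, float, np.int64, np.int64, float, float, np.int64],
    )})


def validate_particle_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARTICLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"particle table missing mandatory columns: {missing}")
    if table["id"].duplicated().any():
        raise SchemaError("particle ids are not unique")
    if len(table) and (table["n_slices"] < 1).any():
        raise SchemaError("n_slices must be >= 1")
    return table


def write_particles(table: pd.DataFrame, path) -> None:
    """Write a particle table as RFC-4180 CSV, floats at 9 significant digits."""
    validate_particle_table(table)
    table.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def read_particles(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such particle table: {path}")
    table = pd.read_csv(path)
    if len(table) == 0:
        table = table.astype({c: d for c, d in empty_particle_table().dtypes.items()
                              if c in table.columns})
    return validate_particle_table(table)
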