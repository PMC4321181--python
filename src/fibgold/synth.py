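"""Ground-truthed synthetic FIB/SEM stack generator.

The phantom is a HeLa-like cell: an ellipsoidal cell body containing a
spherical nucleus, a peripheral heterochromatin shell lining the nuclear
envelope, and a spherical nucleolus.  Amplified immunogold beads are placed
as a homogeneous Poisson process per compartment (particles / um^3), then the
stack is rendered with a surface-imaging model: slice ``k`` shows the
compartment base intensity at its milled surface plane ``z = k * dz``, and a
bead centred at ``z_p`` contributes a radially Gaussian spot (FWHM ~ its
diameter ``d``) on every plane with ``|k*dz - z_p| <= d/2 + p``, its
amplitude scaled by the sphere's chord cross-section at that depth.  Electron
-dense structures are HIGH intensity (the package-internal polarity; pass
``tem_like=True`` to the renderer for the inverted, TEM-like look).

Instrument imperfections emulated: additive Gaussian noise, per-slice
gain/offset drift, and bounded integer per-slice lateral jitter.  Everything
is reproducible from ``SimulationConfig.seed``: independent RNG substreams
are derived per stage (placement / jitter / drift / noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detectability import DetectionGeometry
from .errors import ConfigError
from .stack_io import LabelVolume, VoxelGrid

# RNG substream tags (seed sequence spawn keys)
_STREAM_PLACE, _STREAM_JITTER, _STREAM_DRIFT, _STREAM_NOISE = 1, 2, 3, 4

#: Default volumetric bead densities (particles / um^3) per compartment:
#: cytoplasm and nucleolus at the measured Fab-probe values, euchromatin at
#: the nucleus-without-nucleoli value, heterochromatin unlabelled.
DEFAULT_DENSITIES = {1: 4.7, 2: 24.4, 3: 7.5, 4: 0.0}

#: Default base grey per compartment (dense = bright).  The spread stays well
#: below the bead amplitude: amplified gold is by far the brightest structure
#: ("high contrast"), which is what threshold detection relies on.
DEFAULT_BASE_INTENSITIES = {0: 0.05, 1: 0.15, 2: 0.25, 3: 0.45, 4: 0.35}


@dataclass
class SimulationConfig:
    """Full description of one synthetic acquisition.

    Geometry is desk-scale by default (a ~1.4 um nucleus rather than the
    physiological ~14 um one); densities stay physical so compartment counts
    scale with the simulated volume.
    """

    shape: tuple[int, int, int] = (120, 256, 256)          # (nz, ny, nx)
    voxel_size: tuple[float, float, float] = (25.0, 5.0, 5.0)  # (dz, dy, dx) nm
    # the cell extends through the whole milling depth (every slice cuts it,
    # as in a real acquisition, so slice-to-slice registration has structure)
    cell_semiaxes: tuple[float, float, float] = (2600.0, 620.0, 620.0)  # nm, (z, y, x)
    nucleus_diameter: float = 900.0          # nm
    nucleolus_diameter: float = 320.0        # nm
    nucleolus_offset: tuple[float, float, float] = (0.0, 120.0, 120.0)  # nm from nucleus centre
    heterochromatin_thickness: float = 100.0  # nm shell inside the nuclear envelope
    densities: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    detection_geometry: DetectionGeometry = field(default_factory=DetectionGeometry)
    base_intensities: dict = field(default_factory=lambda: dict(DEFAULT_BASE_INTENSITIES))
    particle_amplitude: float = 1.0
    noise_sigma: float = 0.1                 # 10% of particle amplitude
    gain_drift: float = 0.05                 # per-slice multiplicative, U(+-)
    offset_drift: float = 0.02               # per-slice additive, U(+-)
    jitter_max_px: int = 2                   # per-slice integer lateral shift
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.densities.values()):
            raise ConfigError("densities must be >= 0")
        if self.nucleus_diameter < 0 or self.nucleolus_diameter < 0:
            raise ConfigError("diameters must be >= 0")
        geom = self.detection_geometry
        if abs(geom.t - self.voxel_size[0]) > 1e-9:
            # slice thickness and z sampling are the same physical thing here
            self.detection_geometry = replace(geom, t=self.voxel_size[0])

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """True bead positions plus the phantom they were placed in."""

    positions: pd.DataFrame            # columns id, x_nm, y_nm, z_nm, compartment
    label_volume: LabelVolume
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.positions)


def _center_nm(config: SimulationConfig) -> np.ndarray:
    shape = np.asarray(config.shape, dtype=float)
    voxel = np.asarray(config.voxel_size, dtype=float)
    return (shape - 1.0) / 2.0 * voxel  # (z, y, x) of the grid centre


def build_phantom(config: SimulationConfig) -> LabelVolume:
    """Deterministic compartment map: cell > nucleus > heterochromatin shell >
    nucleolus, painted in precedence order."""
    r_nuc = config.nucleus_diameter / 2.0
    r_nol = config.nucleolus_diameter / 2.0
    off = np.asarray(config.nucleolus_offset, dtype=float)
    if r_nol > 0 and float(np.linalg.norm(off)) + r_nol > r_nuc:
        raise ConfigError("nucleolus does not fit inside the nucleus")

    nz, ny, nx = config.shape
    dz, dy, dx = config.voxel_size
    cz, cy, cx = _center_nm(config)
    z = (np.arange(nz) * dz - cz).astype(np.float32)[:, None, None]
    y = (np.arange(ny) * dy - cy).astype(np.float32)[None, :, None]
    x = (np.arange(nx) * dx - cx).astype(np.float32)[None, None, :]

    az, ay, ax = config.cell_semiaxes
    cell = (z / az) ** 2 + (y / ay) ** 2 + (x / ax) ** 2 <= 1.0
    r2_nuc = z * z + y * y + x * x
    nucleus = r2_nuc <= r_nuc ** 2

    labels = np.zeros(config.shape, dtype=np.int32)
    labels[cell] = 1
    labels[cell & nucleus] = 2
    if config.heterochromatin_thickness > 0 and r_nuc > 0:
        inner = max(r_nuc - config.heterochromatin_thickness, 0.0)
        labels[cell & nucleus & (r2_nuc > inner ** 2)] = 4
    if r_nol > 0:
        r2_nol = (z - off[0]) ** 2 + (y - off[1]) ** 2 + (x - off[2]) ** 2
        labels[cell & nucleus & (r2_nol <= r_nol ** 2)] = 3
    return LabelVolume(labels, config.voxel_size)


def _truth_frame(positions: np.ndarray, compartments: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": np.arange(len(positions), dtype=np.int64),
            "x_nm": positions[:, 2] if len(positions) else np.array([], dtype=float),
            "y_nm": positions[:, 1] if len(positions) else np.array([], dtype=float),
            "z_nm": positions[:, 0] if len(positions) else np.array([], dtype=float),
            "compartment": compartments.astype(np.int64),
        }
    )


def _sample_in_voxels(flat_choice: np.ndarray, shape, voxel_size, rng) -> np.ndarray:
    """Uniform physical positions inside the chosen voxels (voxel k owns the
    half-open interval (k - 1/2, k + 1/2] in index units)."""
    idx = np.column_stack(np.unravel_index(flat_choice, shape)).astype(float)
    u = rng.uniform(-0.5, 0.5, size=idx.shape)
    return (idx + u) * np.asarray(voxel_size)


def place_particles(labels: LabelVolume, densities: dict,
                    seed_or_rng) -> GroundTruth | pd.DataFrame:
    """Homogeneous Poisson placement per compartment.

    Per non-zero label with density ``lam`` the count is Poisson(lam * V) and
    positions are i.i.d. uniform within the compartment (voxelized mask,
    uniform within voxels).  Returns a truth DataFrame.
    """
    if any(v < 0 for v in densities.values()):
        raise ConfigError("densities must be >= 0")
    present = [int(v) for v in np.unique(labels.labels) if v != 0]
    missing = [v for v in present if v not in densities]
    if missing:
        raise ConfigError(f"no density given for compartment labels {missing}")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    dz, dy, dx = labels.voxel_size
    voxel_um3 = dz * dy * dx * 1e-9
    pos_chunks, comp_chunks = [], []
    flat = labels.labels.ravel()
    for lab in present:
        lam = float(densities[lab])
        voxels = np.flatnonzero(flat == lab)
        volume = voxels.size * voxel_um3
        n = rng.poisson(lam * volume) if lam > 0 and volume > 0 else 0
        if n == 0:
            continue
        choice = rng.choice(voxels, size=n, replace=True)
        pos_chunks.append(_sample_in_voxels(choice, labels.shape, labels.voxel_size, rng))
        comp_chunks.append(np.full(n, lab))
    if pos_chunks:
        positions = np.concatenate(pos_chunks)
        compartments = np.concatenate(comp_chunks)
    else:
        positions = np.empty((0, 3))
        compartments = np.empty(0, dtype=np.int64)
    return _truth_frame(positions, compartments)


def place_fixed_count(labels: LabelVolume, label_set, n: int,
                      seed_or_rng, z_margin_nm: float = 0.0) -> pd.DataFrame:
    """Place exactly ``n`` beads uniformly in the union of ``label_set``,
    optionally keeping ``z_margin_nm`` clear of the axial stack faces (so
    every bead's visibility window lies inside the imaged range)."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    mask = labels.mask(label_set)
    if z_margin_nm > 0:
        dz = labels.voxel_size[0]
        k_lo = int(np.ceil(z_margin_nm / dz))
        k_hi = labels.shape[0] - 1 - k_lo
        if k_hi < k_lo:
            raise ConfigError("z margin leaves no admissible slices")
        keep = np.zeros(labels.shape[0], dtype=bool)
        keep[k_lo:k_hi + 1] = True
        mask = mask & keep[:, None, None]
    voxels = np.flatnonzero(mask.ravel())
    if voxels.size == 0:
        raise ConfigError("empty placement region")
    choice = rng.choice(voxels, size=n, replace=True)
    positions = _sample_in_voxels(choice, labels.shape, labels.voxel_size, rng)
    idx = np.column_stack(np.unravel_index(choice, labels.shape))
    compartments = labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    return _truth_frame(positions, compartments)


def simulate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Phantom + Poisson placement under the configured densities."""
    labels = build_phantom(config)
    table = place_particles(labels, config.densities, config.rng(_STREAM_PLACE))
    return GroundTruth(table, labels, config)


def slice_jitter(config: SimulationConfig) -> np.ndarray:
    """The per-slice integer (dy, dx) jitter the renderer applies.

    Slice 0 is the registration reference and is never jittered.
    """
    nz = config.shape[0]
    j = config.jitter_max_px
    rng = config.rng(_STREAM_JITTER)
    jitter = rng.integers(-j, j + 1, size=(nz, 2)) if j > 0 else np.zeros((nz, 2), np.int64)
    jitter[0] = 0
    return jitter


def slice_drift(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice multiplicative gain and additive offset drift."""
    nz = config.shape[0]
    rng = config.rng(_STREAM_DRIFT)
    gain = 1.0 + rng.uniform(-config.gain_drift, config.gain_drift, size=nz)
    offset = rng.uniform(-config.offset_drift, config.offset_drift, size=nz)
    return gain, offset


def _chord_weight(dz_nm: np.ndarray, d: float, p: float) -> np.ndarray:
    """Normalized chord cross-section area of a sphere of diameter ``d`` at
    axial distance ``dz`` from the imaged surface; the penetration depth ``p``
    extends the window by letting sub-surface material within ``p`` nm
    contribute as if at its closest approach."""
    eff = np.maximum(np.abs(dz_nm) - p, 0.0)
    return np.clip(1.0 - (2.0 * eff / d) ** 2, 0.0, None)


def render_stack(truth, config: SimulationConfig,
                 tem_like: bool = False) -> VoxelGrid:
    """Render the surface-imaging model for a ground truth.

    ``truth`` is a :class:`GroundTruth` or a (positions DataFrame, LabelVolume)
    pair consistent with ``config``.  Deterministic given ``config.seed``.
    """
    if isinstance(truth, GroundTruth):
        table, labels = truth.positions, truth.label_volume
    else:
        table, labels = truth
    if labels.shape != tuple(config.shape):
        raise ConfigError("ground truth grid does not match config shape")

    nz, ny, nx = config.shape
    dz, dy, dx = config.voxel_size
    geom = config.detection_geometry
    d, p = geom.d, config.detection_geometry.p
    base_lut = np.zeros(max(config.base_intensities) + 1, dtype=np.float32)
    for lab, g in config.base_intensities.items():
        base_lut[lab] = g
    stack = base_lut[labels.labels]

    # beads: radially Gaussian spots, FWHM = d laterally, chord-area amplitude
    sigma_nm = d / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    trunc_nm = sigma_nm * math.sqrt(-2.0 * math.log(5e-3))  # clip tails below 0.5% amplitude
    ry, rx = int(math.ceil(trunc_nm / dy)), int(math.ceil(trunc_nm / dx))
    jy = (np.arange(-ry, ry + 1) * dy).astype(np.float32)
    jx = (np.arange(-rx, rx + 1) * dx).astype(np.float32)
    half = d / 2.0 + p
    for x_nm, y_nm, z_nm in zip(table["x_nm"], table["y_nm"], table["z_nm"]):
        k_lo = max(int(math.ceil((z_nm - half) / dz)), 0)
        k_hi = min(int(math.floor((z_nm + half) / dz)), nz - 1)
        if k_hi < k_lo:
            continue
        jc, ic = int(round(y_nm / dy)), int(round(x_nm / dx))
        gy = np.exp(-((jy + jc * dy - y_nm) ** 2) / (2.0 * sigma_nm ** 2))
        gx = np.exp(-((jx + ic * dx - x_nm) ** 2) / (2.0 * sigma_nm ** 2))
        spot = np.outer(gy, gx).astype(np.float32)
        spot[spot < 5e-3] = 0.0
        j0, j1 = max(jc - ry, 0), min(jc + ry + 1, ny)
        i0, i1 = max(ic - rx, 0), min(ic + rx + 1, nx)
        view = spot[j0 - (jc - ry): j1 - (jc - ry), i0 - (ic - rx): i1 - (ic - rx)]
        for k in range(k_lo, k_hi + 1):
            w = _chord_weight(k * dz - z_nm, d, p)
            if w <= 0.0:
                continue
            stack[k, j0:j1, i0:i1] += np.float32(config.particle_amplitude * w) * view

    # per-slice lateral jitter (integer, edge-padded)
    jitter = slice_jitter(config)
    for k in range(nz):
        sy, sx = int(jitter[k, 0]), int(jitter[k, 1])
        if sy or sx:
            stack[k] = _shift2d_edge(stack[k], sy, sx)

    gain, offset = slice_drift(config)
    stack *= gain[:, None, None].astype(np.float32)
    stack += offset[:, None, None].astype(np.float32)

    if config.noise_sigma > 0:
        stack += config.rng(_STREAM_NOISE).normal(
            0.0, config.noise_sigma, size=stack.shape).astype(np.float32)

    if tem_like:
        stack = (stack.max() + stack.min()) - stack
    return VoxelGrid(stack, config.voxel_size)


def _shift2d_edge(img: np.ndarray, sy: int, sx: int) -> np.ndarray:
    """Integer 2D shift with edge-value padding (content moves by +sy, +sx)."""
    out = np.empty_like(img)
    ys = np.clip(np.arange(img.shape[0]) - sy, 0, img.shape[0] - 1)
    xs = np.clip(np.arange(img.shape[1]) - sx, 0, img.shape[1] - 1)
    out[:] = img[np.ix_(ys, xs)]
    return out


def simulate(config: SimulationConfig, tem_like: bool = False) -> tuple[VoxelGrid, GroundTruth]:
    """One-call generator: phantom, placement, rendering."""
    truth = simulate_ground_truth(config)
    stack = render_stack(truth, config, tem_like=tem_like)
    return stack, truth


def quantize_uint16(grid: VoxelGrid, lo: float | None = None,
                    hi: float | None = None) -> VoxelGrid:
    """Map a float stack affinely onto the full uint16 range for disk storage."""
    data = grid.data.astype(np.float64)
    lo = float(data.min()) if lo is None else lo
    hi = float(data.max()) if hi is None else hi
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    q = np.clip((data - lo) * scale, 0, 65535).astype(np.uint16)
    return VoxelGrid(q, grid.voxel_size, grid.origin)
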