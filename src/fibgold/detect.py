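"""Amplified-gold particle detection with sub-pixel localization.

Beads are the brightest structures in the (dense-bright, normalized) stack,
so detection is a density threshold followed by 3D connected-component
labelling: 26-connectivity links the footprint of one physical bead across
consecutive imaged planes into a single component.  Each component yields an
intensity-weighted sub-pixel centroid in physical nm — the weights are the
above-threshold intensity excess, which suppresses bias from the flat
super-threshold plateau of saturated beads — and is assigned the compartment
of the voxel containing its centroid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .detectability import DetectionGeometry
from .errors import AssignmentError, ConfigError
from .stack_io import (NUCLEUS_LABELS, LabelVolume, VoxelGrid,
                       empty_particle_table, validate_particle_table)


@dataclass
class DetectionParams:
    """Threshold / linking / size-filter parameters.

    ``threshold="auto"`` sets the density threshold to
    ``mean + k_sigma * SD`` of the nuclear-region intensities (whole stack if
    no label volume is available); the bead contrast is high, so a large
    fixed offset is robust.
    """

    threshold: float | str = "auto"
    k_sigma: float = 6.0
    connectivity: int = 26
    min_voxels: int = 2
    max_voxels: int | None = None
    slice_gap_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ConfigError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.min_voxels < 1:
            raise ConfigError("min_voxels must be >= 1")
        if self.threshold != "auto" and not np.isreal(self.threshold):
            raise ConfigError(f"threshold must be a number or 'auto', got {self.threshold!r}")


@dataclass
class Component:
    """One detected connected component (candidate bead)."""

    indices: tuple            # (k, j, i) integer arrays
    intensities: np.ndarray


def default_max_voxels(geom: DetectionGeometry, voxel_size) -> int:
    """Reject components larger than a sphere of 3x the bead diameter —
    membrane-adjacent aggregates, not single beads."""
    dz, dy, dx = voxel_size
    return int(math.ceil((math.pi / 6.0) * (3.0 * geom.d) ** 3 / (dz * dy * dx)))


def auto_threshold(stack: VoxelGrid, labels: LabelVolume | None = None,
                   k_sigma: float = 6.0) -> float:
    """Density threshold ``k`` noise-widths above the nuclear-region level.

    The location/scale are the median and the MAD-derived sigma of the
    reference region, so bright contaminants (bead voxels themselves,
    segmentation spill-over from denser organelles) cannot inflate the
    estimate.  The euchromatin compartment is preferred as the reference when
    labelled (it dominates the nucleus and its spread is pure imaging noise);
    otherwise the whole nucleus, otherwise the whole stack.
    """
    region = None
    if labels is not None:
        for wanted in ({2}, NUCLEUS_LABELS):
            candidate = stack.data[labels.mask(wanted)]
            if candidate.size:
                region = candidate
                break
    if region is None:
        region = stack.data.ravel()
    med = float(np.median(region))
    sigma = 1.4826 * float(np.median(np.abs(region - med)))
    return med + k_sigma * sigma


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def detect(stack: VoxelGrid, params: DetectionParams,
           labels: LabelVolume | None = None) -> tuple[list[Component], float]:
    """Threshold + link + size-filter; returns components and the threshold used.

    A bead intersected by several imaged planes forms one component (cross-
    slice linking through 26-connectivity); the size filter runs after
    linking.  ``slice_gap_tolerance > 0`` additionally bridges components
    whose voxels overlap laterally across a gap of that many dark slices.
    """
    thr = (auto_threshold(stack, labels, params.k_sigma)
           if params.threshold == "auto" else float(params.threshold))
    mask = stack.data >= thr
    if not mask.any():
        if thr > float(stack.data.max()):
            warnings.warn("detection threshold above the data range: no components",
                          stacklevel=2)
        return [], thr
    if params.slice_gap_tolerance > 0:
        # bridge beads invisible on intermediate slices: dilate along z before
        # linking, then keep only the original voxels of each component
        st = np.ones((2 * params.slice_gap_tolerance + 1, 1, 1), dtype=bool)
        bridged = ndimage.binary_dilation(mask, structure=st)
        labelled, n = ndimage.label(bridged, structure=_structure(params.connectivity))
        labelled[~mask] = 0
    else:
        labelled, n = ndimage.label(mask, structure=_structure(params.connectivity))
    objects = ndimage.find_objects(labelled)
    components = []
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        idx = np.nonzero(labelled[sl] == lab)
        size = idx[0].size
        if size < params.min_voxels:
            continue
        if params.max_voxels is not None and size > params.max_voxels:
            continue
        ks = idx[0] + sl[0].start
        js = idx[1] + sl[1].start
        is_ = idx[2] + sl[2].start
        components.append(Component((ks, js, is_), stack.data[ks, js, is_].astype(float)))
    return components, thr


def subpixel_centroid(component: Component, grid: VoxelGrid,
                      background: float = 0.0) -> tuple[float, float, float]:
    """Intensity-weighted centre of mass in physical nm, as (x, y, z).

    Weights are ``I - background`` clipped at zero (background defaults to
    the detection threshold upstream); if every weight vanishes the
    unweighted geometric centroid is used with a warning.  z interpolates
    between the member planes ``k * dz``.
    """
    ks, js, is_ = component.indices
    if ks.size == 0:
        raise ConfigError("empty component")
    w = np.clip(component.intensities - background, 0.0, None)
    if w.sum() <= 0:
        warnings.warn("all centroid weights zero: falling back to geometric centroid",
                      stacklevel=2)
        w = np.ones_like(w)
    w = w / w.sum()
    dz, dy, dx = grid.voxel_size
    z0, y0, x0 = grid.origin
    return (
        float(x0 + np.dot(w, is_) * dx),
        float(y0 + np.dot(w, js) * dy),
        float(z0 + np.dot(w, ks) * dz),
    )


def assign_compartment(position_xyz_nm, labels: LabelVolume) -> int:
    """Label of the voxel containing a physical (x, y, z) nm position.

    Points exactly on a voxel boundary resolve to the lower-index voxel.
    """
    x, y, z = position_xyz_nm
    grid = labels.as_grid()
    k, j, i = grid.nm_to_index((z, y, x))
    if not (0 <= k < labels.shape[0] and 0 <= j < labels.shape[1] and 0 <= i < labels.shape[2]):
        raise AssignmentError(f"centroid ({x:.1f}, {y:.1f}, {z:.1f}) nm outside the grid")
    return int(labels.labels[k, j, i])


def find_particles(stack: VoxelGrid, params: DetectionParams | None = None,
                   labels: LabelVolume | None = None) -> pd.DataFrame:
    """Full detection pass: components -> centroids -> compartments.

    Returns a particle table (see stack_io.PARTICLE_COLUMNS); compartment is
    -1 when no label volume is given.
    """
    params = params or DetectionParams()
    components, thr = detect(stack, params, labels)
    if not components:
        return empty_particle_table()
    rows = []
    for pid, comp in enumerate(components):
        x, y, z = subpixel_centroid(comp, stack, background=thr)
        ks = comp.indices[0]
        compartment = assign_compartment((x, y, z), labels) if labels is not None else -1
        rows.append((pid, x, y, z, ks.size, int(ks.max() - ks.min() + 1),
                     float(comp.intensities.max()), float(comp.intensities.mean()),
                     compartment))
    table = pd.DataFrame(rows, columns=empty_particle_table().columns)
    return validate_particle_table(table)
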