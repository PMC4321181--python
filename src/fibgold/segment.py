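"""Semi-automatic compartment segmentation.

Mirrors a threshold-and-trace workflow: grey bands (chosen by multi-level
Otsu or supplied per compartment) define candidate voxels, region growing
from operator seed points extracts the connected component, and a fixed
precedence (nucleolus > heterochromatin > nucleus > cytoplasm) composes the
masks into one label volume.  A fully automatic mode maps ordered Otsu
classes onto compartments; it stands in for the operator on phantoms and is
flagged heuristic for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .errors import ConfigError, SegmentationError
from .stack_io import (CELL_LABELS, COMPARTMENTS, NUCLEUS_LABELS,
                       NUCLEUS_WITHOUT_NUCLEOLI_LABELS, LabelVolume, VoxelGrid)

#: Later entries override earlier ones when composing masks.
PRECEDENCE = (1, 2, 4, 3)  # cytoplasm < nucleus < heterochromatin < nucleolus


@dataclass
class SegmentationParams:
    """Parameters of the threshold-and-trace segmentation."""

    bands: dict = field(default_factory=dict)   # label -> (lo, hi) grey band, or "auto"
    seeds: dict = field(default_factory=dict)   # label -> (k, j, i) seed voxel
    connectivity: int = 26
    min_object_voxels: int = 100
    closing_radius: int = 1
    smooth_sigma: float = 2.0                   # lateral Gaussian denoise (px) before thresholding

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ConfigError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        for lab, band in self.bands.items():
            if band != "auto" and not band[0] < band[1]:
                raise ConfigError(f"band for label {lab} must satisfy lo < hi, got {band}")


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def _nearest_in_mask(mask: np.ndarray, seed, radius: int):
    """Closest True voxel to ``seed`` within a cubic neighbourhood, or None."""
    k, j, i = seed
    lo = [max(v - radius, 0) for v in seed]
    patch = mask[lo[0]:k + radius + 1, lo[1]:j + radius + 1, lo[2]:i + radius + 1]
    if not patch.any():
        return None
    cand = np.argwhere(patch) + np.asarray(lo)
    dist = np.sum((cand - np.asarray(seed)) ** 2, axis=1)
    return tuple(int(v) for v in cand[np.argmin(dist)])


def smooth(stack: VoxelGrid, sigma: float) -> VoxelGrid:
    """In-plane Gaussian denoise (slices are independent surface images)."""
    if sigma <= 0:
        return stack
    data = ndimage.gaussian_filter(stack.data.astype(np.float32), sigma=(0, sigma, sigma))
    return VoxelGrid(data, stack.voxel_size, stack.origin)


def auto_thresholds(stack: VoxelGrid, n_classes: int) -> np.ndarray:
    """Multi-level Otsu thresholds partitioning the intensity histogram into
    ``n_classes`` classes (``n_classes - 1`` thresholds, ascending)."""
    if n_classes < 2:
        raise ConfigError("need at least 2 classes")
    data = stack.data
    if float(data.min()) == float(data.max()):
        raise SegmentationError("constant image: no threshold separates it")
    return threshold_multiotsu(data.ravel(), classes=n_classes, nbins=512)


def seed_levels(stack: VoxelGrid, seeds: dict, radius: int = 2) -> dict:
    """Local median grey at every operator seed point."""
    levels = {}
    for lab, s in seeds.items():
        k, j, i = (int(v) for v in s)
        patch = stack.data[max(k - radius, 0):k + radius + 1,
                           max(j - radius, 0):j + radius + 1,
                           max(i - radius, 0):i + radius + 1]
        levels[lab] = float(np.median(patch))
    return levels


def trace_region(stack: VoxelGrid, seed_point, band, connectivity: int = 26) -> np.ndarray:
    """Connected component of ``{lo <= I <= hi}`` containing the seed voxel.

    Connectivity is topological, so voxel anisotropy does not affect it.
    """
    lo, hi = band
    seed = tuple(int(v) for v in seed_point)
    value = float(stack.data[seed])
    if not lo <= value <= hi:
        raise SegmentationError(
            f"seed {seed} intensity {value:.4g} outside band ({lo:.4g}, {hi:.4g})")
    candidates = (stack.data >= lo) & (stack.data <= hi)
    labelled, _ = ndimage.label(candidates, structure=_structure(connectivity))
    return labelled == labelled[seed]


def cleanup_mask(mask: np.ndarray, min_object_voxels: int = 100,
                 closing_radius: int = 1, fill_holes: bool = True) -> np.ndarray:
    """Operator-style cleanup: close, fill holes, drop small specks."""
    out = mask
    if closing_radius > 0:
        st = ndimage.generate_binary_structure(3, 1)
        out = ndimage.binary_closing(out, structure=st, iterations=closing_radius)
    if fill_holes:
        out = ndimage.binary_fill_holes(out)
    if min_object_voxels > 1:
        labelled, n = ndimage.label(out, structure=_structure(26))
        if n:
            counts = np.bincount(labelled.ravel())
            keep = counts >= min_object_voxels
            keep[0] = False
            out = keep[labelled]
    return out


def compose_labels(masks: dict, voxel_size, origin=(0.0, 0.0, 0.0)) -> LabelVolume:
    """Compose per-compartment masks into one label volume.

    Overlaps resolve by fixed precedence nucleolus > heterochromatin >
    nucleus > cytoplasm; every voxel receives exactly one label.
    """
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ConfigError(f"masks are not congruent: shapes {shapes}")
    shape = next(iter(shapes))
    labels = np.zeros(shape, dtype=np.int32)
    for lab in PRECEDENCE:
        if lab in masks:
            labels[masks[lab]] = lab
    extra = set(masks) - set(PRECEDENCE)
    if extra:
        raise ConfigError(f"masks for unknown compartment labels {sorted(extra)}")
    return LabelVolume(labels, voxel_size, origin)


def segment_semiautomatic(stack: VoxelGrid, params: SegmentationParams) -> LabelVolume:
    """Seeded semi-automatic segmentation.

    Compartments with an explicit grey band are traced as the seed's
    connected component within the band.  Compartments with band ``"auto"``
    are segmented jointly by nearest-seed-level classification: each voxel
    takes the seeded compartment whose local grey level is closest (the
    operator "traces a grey level", the tool assigns every voxel to the
    closest traced level), then only the component connected to the seed is
    kept.  A seed for label 0 lets the extracellular background claim its
    own grey level instead of leaking into the dimmest compartment.
    """
    sm = smooth(stack, params.smooth_sigma)
    auto_labs = [lab for lab, band in params.bands.items() if band == "auto"]
    explicit = {lab: band for lab, band in params.bands.items() if band != "auto"}
    for lab in params.bands:
        if lab not in params.seeds:
            raise ConfigError(f"compartment {lab} has a band but no seed point")
    masks = {}
    if auto_labs:
        levels = seed_levels(sm, {lab: params.seeds[lab] for lab in auto_labs})
        if len(set(np.round(list(levels.values()), 6))) < len(levels):
            raise ConfigError("seed grey levels are not distinct; cannot classify")
        labs = sorted(levels)
        dist = np.stack([np.abs(sm.data - levels[lab]) for lab in labs])
        cls = np.argmin(dist, axis=0)
        st = _structure(params.connectivity)
        for ci, lab in enumerate(labs):
            if lab == 0:
                continue  # background participates in the classification only
            mask = cls == ci
            comp, _ = ndimage.label(mask, structure=st)
            seed = tuple(int(v) for v in params.seeds[lab])
            if not mask[seed]:
                # the exact seed voxel may be a noise flip; accept the class
                # voxel nearest to the seed within a small neighbourhood
                seed = _nearest_in_mask(mask, seed, radius=3)
                if seed is None:
                    raise SegmentationError(
                        f"seed {params.seeds[lab]} not classified as compartment {lab}")
            masks[lab] = comp == comp[seed]
    for lab, band in explicit.items():
        masks[lab] = trace_region(sm, params.seeds[lab], band, params.connectivity)
    for lab, mask in masks.items():
        # a shell compartment (heterochromatin) must keep its enclosed cavity
        masks[lab] = cleanup_mask(mask, params.min_object_voxels,
                                  params.closing_radius, fill_holes=(lab != 4))
    return compose_labels(masks, stack.voxel_size, stack.origin)


def segment_auto(stack: VoxelGrid, params: SegmentationParams | None = None) -> LabelVolume:
    """Heuristic fully automatic mode: 5-class Otsu, classes mapped onto
    compartments by ascending mean grey (outside < cytoplasm < euchromatin <
    heterochromatin < nucleolus in the internal dense-bright polarity)."""
    params = params or SegmentationParams()
    sm = smooth(stack, params.smooth_sigma)
    thresholds = auto_thresholds(sm, n_classes=5)
    classes = np.digitize(sm.data, thresholds)
    order = (0, 1, 2, 4, 3)  # ascending grey -> compartment label
    masks = {}
    for cls, lab in enumerate(order):
        if lab == 0:
            continue
        # filling holes in the hollow heterochromatin shell would flood the
        # nucleus interior, so the shell keeps its cavity
        masks[lab] = cleanup_mask(classes == cls, params.min_object_voxels,
                                  params.closing_radius, fill_holes=(lab != 4))
    return compose_labels(masks, stack.voxel_size, stack.origin)


def compartment_volumes(labels: LabelVolume) -> dict:
    """Volumes in um^3 per compartment plus the report aggregates."""
    dz, dy, dx = labels.voxel_size
    voxel_um3 = dz * dy * dx * 1e-9
    counts = np.bincount(labels.labels.ravel(), minlength=5)
    out = {COMPARTMENTS[lab]: counts[lab] * voxel_um3 for lab in COMPARTMENTS}
    out["whole_nucleus"] = sum(counts[lab] for lab in NUCLEUS_LABELS) * voxel_um3
    out["nucleus_without_nucleoli"] = (
        sum(counts[lab] for lab in NUCLEUS_WITHOUT_NUCLEOLI_LABELS) * voxel_um3)
    out["cell_total"] = sum(counts[lab] for lab in CELL_LABELS) * voxel_um3
    return out
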