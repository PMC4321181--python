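"""Stack conditioning: grey-level inversion, intensity normalization,
translational slice alignment, centre cropping.

The stages are designed to run in the order invert -> normalize -> align ->
crop; each is usable on its own.  All stages preserve the coordinate
contract: physical positions of structures are unchanged (cropping updates
the grid origin, alignment reports the shifts it applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .stack_io import LabelVolume, VoxelGrid


@dataclass
class AlignmentResult:
    """Per-slice (dy, dx) correction applied during alignment.

    Applying ``shifts[k]`` to raw slice ``k`` (content moved by +dy, +dx)
    brings it into the reference frame; the reference slice's shift is (0, 0).
    """

    shifts: np.ndarray          # (nz, 2) float, (dy, dx) pixels
    reference: str              # "previous" or "fixed"

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if not np.all(np.isfinite(self.shifts)):
            raise ConfigError("alignment shifts must be finite")


def invert(stack: VoxelGrid, float_range: tuple[float, float] = (0.0, 1.0)) -> VoxelGrid:
    """Invert the grey-level scale.

    Integer data maps ``x -> max_representable - x`` (an involution on the
    dtype's full range); float data maps ``x -> hi - x + lo`` for the stated
    ``float_range``.
    """
    data = stack.data
    if np.issubdtype(data.dtype, np.integer):
        out = (np.iinfo(data.dtype).max - data).astype(data.dtype)
    else:
        lo, hi = float_range
        out = (hi - data + lo).astype(data.dtype)
    return VoxelGrid(out, stack.voxel_size, stack.origin)


def normalize(stack: VoxelGrid, mode: str = "global",
              clip_percentiles: tuple[float, float] = (0.0, 100.0)) -> VoxelGrid:
    """Affinely map intensities to [0, 1] between percentile bounds.

    ``mode="global"`` uses one pair of bounds for the whole stack;
    ``"per_slice"`` removes slice-wise gain/offset drift by mapping each
    slice on its own bounds.  The default bounds are the full min/max: the
    amplified beads are the brightest voxels by design and robust percentile
    clipping (e.g. ``(0.5, 99.5)``) would saturate their cores together with
    the brightest organelle voxels, flattening exactly the contrast the
    detector thresholds on.  Tighter percentiles remain available for stacks
    with hot-pixel artefacts.  A constant slice (or stack) maps to 0.5 with a
    warning.
    """
    lo_p, hi_p = clip_percentiles
    if not lo_p < hi_p:
        raise ConfigError(f"clip percentiles must satisfy low < high, got {clip_percentiles}")
    if mode not in ("global", "per_slice"):
        raise ConfigError(f"unknown normalization mode {mode!r}")
    data = stack.data.astype(np.float32, copy=True)
    if mode == "global":
        _normalize_inplace(data, lo_p, hi_p, what="stack")
    else:
        for k in range(data.shape[0]):
            _normalize_inplace(data[k], lo_p, hi_p, what=f"slice {k}")
    return VoxelGrid(data, stack.voxel_size, stack.origin)


def _normalize_inplace(arr: np.ndarray, lo_p: float, hi_p: float, what: str) -> None:
    lo, hi = np.percentile(arr, [lo_p, hi_p])
    if hi <= lo:
        warnings.warn(f"constant {what}: normalized to 0.5", stacklevel=3)
        arr[:] = 0.5
        return
    arr -= lo
    arr /= (hi - lo)
    np.clip(arr, 0.0, 1.0, out=arr)


def _registration_image(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gradient-magnitude representation used for registration.

    Phase correlation whitens the spectrum, so on smooth slices the peak is
    dominated by pixel noise; the gradient of a lightly smoothed image
    concentrates the energy on edges (cell and organelle boundaries, beads)
    and makes the peak robust.
    """
    if sigma > 0:
        img = ndimage.gaussian_filter(img.astype(np.float32), sigma)
    return np.hypot(ndimage.sobel(img, axis=0), ndimage.sobel(img, axis=1))


def _pairwise_shift(ref: np.ndarray, mov: np.ndarray, search_radius: int,
                    subpixel: bool) -> np.ndarray:
    """Cross-correlation shift (dy, dx) to apply to ``mov`` to match ``ref``,
    with the peak search restricted to ``|shift| <= search_radius``.

    Plain (mean-subtracted) cross-correlation, not phase correlation: on the
    gradient-magnitude inputs the peak is already sharp, and whitening would
    re-amplify the noise floor on texture-poor slices.
    """
    f_ref = np.fft.rfft2(ref - ref.mean())
    f_mov = np.fft.rfft2(mov - mov.mean())
    corr = np.fft.irfft2(f_ref * np.conj(f_mov), s=ref.shape)
    s = int(search_radius)
    window = np.fft.fftshift(corr)
    cy, cx = ref.shape[0] // 2, ref.shape[1] // 2
    patch = window[cy - s:cy + s + 1, cx - s:cx + s + 1]
    py, px = np.unravel_index(np.argmax(patch), patch.shape)
    shift = np.array([py - s, px - s], dtype=float)
    if subpixel:
        for axis, p in enumerate((py, px)):
            if 0 < p < patch.shape[axis] - 1:
                sl = patch[p - 1:p + 2, px] if axis == 0 else patch[py, p - 1:p + 2]
                denom = sl[0] - 2 * sl[1] + sl[2]
                if denom < 0:
                    shift[axis] += 0.5 * (sl[0] - sl[2]) / denom
    return shift


def remove_slice_drift(stack: VoxelGrid, background_fraction: float = 0.3) -> VoxelGrid:
    """Remove per-slice intensity drift, anchored on the resin background.

    The embedding resin is featureless and present in every slice, so its
    grey level is constant up to acquisition drift; the per-slice median of
    the voxels inside a fixed global grey window over the dark (resin) end of
    the histogram estimates that drift independently of the z-varying
    cellular content, and each slice is offset so its background sits at the
    stack-wide level.  ``background_fraction`` is the approximate volume
    fraction the background occupies: the window extends to that global
    quantile, so a well-chosen value covers the whole background mode (full
    sensitivity) without admitting tissue.  Residual multiplicative (gain)
    drift is not corrected: anchored at the background it perturbs the
    brightest tissue by only its few-percent amplitude.
    """
    data = stack.data.astype(np.float32, copy=True)
    lo, hi = np.quantile(data[:, ::2, ::2], [0.02, background_fraction])
    levels = np.empty(data.shape[0], dtype=np.float64)
    for k in range(data.shape[0]):
        s = data[k].ravel()[::4]  # subsample: only a robust stat is needed
        sel = s[(s >= lo) & (s <= hi)]
        levels[k] = float(np.median(sel)) if sel.size else np.nan
    target = float(np.nanmedian(levels))
    for k in range(data.shape[0]):
        if np.isfinite(levels[k]):
            data[k] -= np.float32(levels[k] - target)
    return VoxelGrid(data, stack.voxel_size, stack.origin)


def estimate_shifts(stack: VoxelGrid, reference: str = "previous",
                    max_shift: float | None = None, upsample: int = 1,
                    search_radius: int = 16, smooth_sigma: float = 2.0,
                    detrend: bool = True, detrend_window: int = 15) -> AlignmentResult:
    """Estimate per-slice translational corrections by phase correlation.

    ``reference="previous"`` registers each slice to its predecessor and
    accumulates the pairwise shifts into corrections relative to slice 0;
    ``"fixed"`` registers every slice directly to slice 0.  ``upsample=1``
    gives integer shifts (the default); larger values fit a sub-pixel peak.
    The peak search is restricted to ``search_radius`` pixels (slice-to-slice
    motion is small) and runs on gradient-magnitude images, where the
    correlation peak is sharp even for smooth organelle content.  ``detrend`` (default on) subtracts the
    running median of the cumulative shifts: pairwise estimation errors on
    coarsely sectioned stacks (content decorrelates between consecutive
    surfaces) accumulate into a random-walk staircase that the detrend
    removes, at the cost of also removing any genuine slow drift.
    """
    if reference not in ("previous", "fixed"):
        raise ConfigError(f"unknown alignment reference {reference!r}")
    data = stack.data
    nz = data.shape[0]
    if max_shift is not None and max_shift >= min(data.shape[1], data.shape[2]) / 2:
        raise ConfigError("max_shift must be below half the slice extent")
    search_radius = min(search_radius, min(data.shape[1], data.shape[2]) // 2 - 1)
    reg = [_registration_image(data[k], smooth_sigma) for k in range(nz)]
    shifts = np.zeros((nz, 2))
    for k in range(1, nz):
        ref = reg[k - 1] if reference == "previous" else reg[0]
        shifts[k] = _pairwise_shift(ref, reg[k], search_radius, subpixel=upsample > 1)
    if reference == "previous":
        shifts = np.cumsum(shifts, axis=0)
    if detrend:
        shifts = shifts - _running_median(shifts, detrend_window)
    if max_shift is not None and np.any(np.abs(shifts) >= max_shift):
        warnings.warn("estimated shift at the max_shift bound; registration may have failed",
                      stacklevel=2)
        shifts = np.clip(shifts, -max_shift, max_shift)
    if upsample == 1:
        shifts = np.round(shifts) + 0.0  # -0.0 -> 0.0
    return AlignmentResult(shifts, reference)


def _running_median(shifts: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(shifts)
    for k in range(len(shifts)):
        lo, hi = max(0, k - half), min(len(shifts), k + half + 1)
        out[k] = np.median(shifts[lo:hi], axis=0)
    return out


def apply_shifts(stack: VoxelGrid, result: AlignmentResult) -> VoxelGrid:
    """Shift each slice by its correction; out-of-frame pixels take the edge value."""
    from scipy import ndimage

    data = stack.data.astype(np.float32, copy=True)
    for k, (sy, sx) in enumerate(result.shifts):
        if sy == 0 and sx == 0:
            continue
        if float(sy).is_integer() and float(sx).is_integer():
            data[k] = _integer_shift(data[k], int(sy), int(sx))
        else:
            data[k] = ndimage.shift(data[k], (sy, sx), order=1, mode="nearest")
    return VoxelGrid(data, stack.voxel_size, stack.origin)


def _integer_shift(img: np.ndarray, sy: int, sx: int) -> np.ndarray:
    ys = np.clip(np.arange(img.shape[0]) - sy, 0, img.shape[0] - 1)
    xs = np.clip(np.arange(img.shape[1]) - sx, 0, img.shape[1] - 1)
    return img[np.ix_(ys, xs)]


def align(stack: VoxelGrid, reference: str = "previous",
          max_shift: float | None = None, upsample: int = 1,
          detrend: bool = True) -> tuple[VoxelGrid, AlignmentResult]:
    """Estimate and apply translational corrections; see :func:`estimate_shifts`."""
    result = estimate_shifts(stack, reference=reference, max_shift=max_shift,
                             upsample=upsample, detrend=detrend)
    return apply_shifts(stack, result), result


def crop_center(volume, size: tuple[int, int]):
    """Crop every slice to a centred (rows, cols) window.

    Odd margins are split toward the lower indices.  The origin is updated so
    physical coordinates of the retained content are preserved.  Works on
    VoxelGrid and LabelVolume alike.
    """
    rows, cols = size
    is_labels = isinstance(volume, LabelVolume)
    data = volume.labels if is_labels else volume.data
    nz, ny, nx = data.shape
    if rows > ny or cols > nx:
        raise ConfigError(f"crop size {size} exceeds slice extent {(ny, nx)}")
    r0, c0 = (ny - rows) // 2, (nx - cols) // 2
    out = data[:, r0:r0 + rows, c0:c0 + cols]
    dz, dy, dx = volume.voxel_size
    z0, y0, x0 = volume.origin
    origin = (z0, y0 + r0 * dy, x0 + c0 * dx)
    if is_labels:
        return LabelVolume(out.copy(), volume.voxel_size, origin, legend=volume.legend)
    return VoxelGrid(out.copy(), volume.voxel_size, origin)
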