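"""Motion correction, intensity normalization and isotropic resampling.

In-vivo multiphoton stacks acquire one z-slice at a time, so respiration
and heartbeat displace successive slices nonuniformly within the plane.
Correction registers each slice to the (already corrected) slice above it
with diffeomorphic demons — a nonparametric intensity-driven registration
whose mean-squared-error updates are Gaussian-smoothed (sigma = 1.3 by
default) and composed from small invertible steps.

Normalization linearly maps the 1st..99th intensity percentiles to [0, 1]
and clips the extreme 1% of voxels; volumes are then resampled to an
isotropic grid (1 um^3 by default) for cross-dataset comparability.
"""

from __future__ import annotations

import logging

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .core import ImageStack, SliceDeformation

log = logging.getLogger(__name__)

DEFAULT_DEMONS_SIGMA = 1.3
DEFAULT_DEMONS_ITERATIONS = 50
DEFAULT_PYRAMID_LEVELS = 3


def _demons_2d(
    fixed: np.ndarray,
    moving: np.ndarray,
    sigma: float,
    n_iterations: int,
    n_levels: int,
) -> np.ndarray:
    """Register ``moving`` to ``fixed`` (2D); return (2, Y, X) field (uy, ux).

    Coarse-to-fine: demons runs on a shrink pyramid, each level seeded with
    the upsampled field from the previous one.  All images keep unit
    spacing, so displacements are in pixel units.
    """
    f = sitk.GetImageFromArray(np.ascontiguousarray(fixed, dtype=np.float32))
    m = sitk.GetImageFromArray(np.ascontiguousarray(moving, dtype=np.float32))
    demons = sitk.DiffeomorphicDemonsRegistrationFilter()
    demons.SetNumberOfIterations(int(n_iterations))
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(float(sigma))
    demons.SetSmoothUpdateField(True)
    demons.SetUpdateFieldStandardDeviations(float(sigma))

    factors = [2**k for k in range(n_levels - 1, -1, -1)]
    field = None
    for factor in factors:
        if factor > 1:
            fs = sitk.Shrink(f, [factor, factor])
            ms = sitk.Shrink(m, [factor, factor])
        else:
            fs, ms = f, m
        if field is None:
            field = sitk.Image(fs.GetSize(), sitk.sitkVectorFloat64, 2)
            field.CopyInformation(fs)
        else:
            field = sitk.Resample(field, fs, sitk.Transform(), sitk.sitkLinear)
        field = demons.Execute(fs, ms, field)
    field = sitk.Resample(field, f, sitk.Transform(), sitk.sitkLinear)
    arr = sitk.GetArrayFromImage(field)  # (Y, X, 2) with components (dx, dy) physical
    # unit spacing -> physical == pixel units; reorder to (uy, ux)
    return np.stack([arr[..., 1], arr[..., 0]], axis=0).astype(np.float32)


def warp_slice(slice_2d: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Apply a (2, Y, X) pull-back displacement field to one slice."""
    ny, nx = slice_2d.shape
    yy, xx = np.meshgrid(np.arange(ny, dtype=np.float64), np.arange(nx, dtype=np.float64), indexing="ij")
    return map_coordinates(
        slice_2d.astype(np.float64), [yy + field[0], xx + field[1]], order=1, mode="nearest"
    ).astype(slice_2d.dtype)


def register_stack(
    stack: ImageStack,
    smoothing_sigma: float = DEFAULT_DEMONS_SIGMA,
    n_iterations: int = DEFAULT_DEMONS_ITERATIONS,
    n_levels: int = DEFAULT_PYRAMID_LEVELS,
) -> tuple[ImageStack, SliceDeformation]:
    """Remove per-slice motion by chained slice-to-slice demons registration.

    Slice 0 is the fixed reference; every subsequent slice is registered to
    the already-registered slice above it, so corrections accumulate down
    the stack.  Returns the warped stack and the per-slice displacement
    fields (slice 0 carries the identity field).
    """
    stack.require_finite()
    data = np.asarray(stack.data, dtype=np.float32)
    nz, ny, nx = data.shape
    fields = np.zeros((nz, 2, ny, nx), dtype=np.float32)
    out = data.copy()
    if nz < 2:
        return ImageStack(out, stack.voxel_size_um), SliceDeformation(fields)
    for z in range(1, nz):
        field = _demons_2d(out[z - 1], data[z], smoothing_sigma, n_iterations, n_levels)
        fields[z] = field
        out[z] = warp_slice(data[z], field)
    return ImageStack(out, stack.voxel_size_um), SliceDeformation(fields)


def adjacent_slice_mse(data: np.ndarray) -> float:
    """Mean squared intensity difference between consecutive z-slices."""
    data = np.asarray(data, dtype=np.float64)
    if data.shape[0] < 2:
        return 0.0
    return float(np.mean((data[1:] - data[:-1]) ** 2))


def normalize_intensity(
    stack: ImageStack,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    per_slice: bool = False,
) -> ImageStack:
    """Map the [low_pct, high_pct] intensity range linearly onto [0, 1].

    Voxels outside the range (the extreme percentiles) are clipped to 0/1.
    Percentiles are taken over the whole volume by default; ``per_slice``
    renormalizes each z-slice independently (can compensate depth-dependent
    signal loss at the price of amplifying noise in empty slices).
    """
    if high_pct <= low_pct:
        raise ValueError("high_pct must exceed low_pct")
    stack.require_finite()
    data = np.asarray(stack.data, dtype=np.float64)

    def _rescale(vol):
        lo, hi = np.percentile(vol, [low_pct, high_pct])
        if hi <= lo:
            log.warning("constant intensity region: normalization yields all zeros")
            return np.zeros_like(vol)
        return np.clip((vol - lo) / (hi - lo), 0.0, 1.0)

    if per_slice:
        out = np.stack([_rescale(data[z]) for z in range(data.shape[0])])
    else:
        out = _rescale(data)
    return ImageStack(out.astype(np.float32), stack.voxel_size_um)


def resample_isotropic(
    stack: ImageStack, target_um: float = 1.0, interpolation: str = "linear"
) -> ImageStack:
    """Trilinearly resample onto an isotropic grid of ``target_um`` spacing.

    Output shape is ``round(shape * spacing / target)`` per axis.  Use
    ``interpolation="nearest"`` for binary masks (preserves binarity).
    """
    if target_um <= 0:
        raise ValueError("target spacing must be positive")
    spacing = np.asarray(stack.voxel_size_um, dtype=np.float64)
    shape = np.asarray(stack.shape)
    if np.allclose(spacing, target_um):
        return ImageStack(stack.data.copy(), (target_um,) * 3)
    new_shape = np.maximum(np.round(shape * spacing / target_um).astype(int), 1)
    coords = np.meshgrid(
        *[np.arange(n) * target_um / s for n, s in zip(new_shape, spacing)], indexing="ij"
    )
    order = 0 if interpolation == "nearest" else 1
    out = map_coordinates(
        np.asarray(stack.data, dtype=np.float64), coords, order=order, mode="nearest"
    )
    dtype = stack.data.dtype if interpolation == "nearest" else np.float32
    return ImageStack(out.astype(dtype), (target_um,) * 3)
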