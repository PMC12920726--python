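"""Shared voxelised VOI geometry: kernels and sliding-window statistics.

All VOIs in the pipeline (liver sphere, aorta cylinder, SULpeak sphere) are
sets of voxel *centres* falling inside an analytic shape centred on a voxel
centre.  Sliding means/SDs over such kernels are computed with FFT
convolution so that every candidate centre of a volume is scored at once.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .volumes import ImageGrid


def ball_kernel(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    """Boolean kernel of voxel centres within ``radius_mm`` of the centre voxel."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(radius_mm / spacing).astype(int)
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    return dx * dx + dy * dy + dz * dz <= radius_mm * radius_mm + 1e-9


def cylinder_kernel(
    spacing: tuple[float, float, float],
    radius_mm: float,
    height_mm: float,
    axis: np.ndarray,
) -> np.ndarray:
    """Boolean kernel of voxel centres inside a cylinder along ``axis`` (world mm).

    ``axis`` is a unit vector in grid-aligned world coordinates (direction
    matrix already applied by the caller); the cylinder is centred on the
    centre voxel.
    """
    spacing = np.asarray(spacing, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    reach = np.hypot(height_mm / 2.0, radius_mm)
    half = np.floor(reach / spacing).astype(int)
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([dx, dy, dz], axis=-1)
    axial = pts @ axis
    radial2 = np.sum(pts * pts, axis=-1) - axial * axial
    return (np.abs(axial) <= height_mm / 2.0 + 1e-9) & (
        radial2 <= radius_mm * radius_mm + 1e-9
    )


def kernel_offsets(kernel: np.ndarray) -> np.ndarray:
    """Integer index offsets (N, 3) of the True voxels relative to the centre."""
    centre = (np.asarray(kernel.shape) - 1) // 2
    return np.argwhere(kernel) - centre


def sliding_sum(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Sum of ``values`` over the kernel footprint at every centre (zero-padded)."""
    return fftconvolve(values, kernel.astype(float), mode="same")


def sliding_count_inside(mask: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """At each centre, how many kernel voxels fall on True voxels of ``mask``."""
    return sliding_sum(mask.astype(float), kernel)


def fits_inside(mask: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Boolean map of centres where the whole kernel lies inside ``mask``.

    The FFT count is within ~1e-6 of an integer, so a half-voxel threshold
    is exact.
    """
    n = int(kernel.sum())
    return sliding_count_inside(mask, kernel) > n - 0.5


def sliding_mean_sd(
    values: np.ndarray, kernel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and population SD of ``values`` over the kernel at every centre.

    Out-of-grid voxels are treated as absent: statistics are over the
    in-grid footprint (near edges the footprint shrinks).
    """
    ones = np.ones_like(values)
    n = np.maximum(sliding_sum(ones, kernel), 1e-12)
    mean = sliding_sum(values, kernel) / n
    meansq = sliding_sum(values * values, kernel) / n
    var = np.maximum(meansq - mean * mean, 0.0)
    return mean, np.sqrt(var)


def member_indices(
    grid: ImageGrid, centre_idx: np.ndarray, kernel: np.ndarray
) -> np.ndarray:
    """Voxel indices (M, 3) of kernel members around ``centre_idx``, clipped to grid."""
    idx = np.asarray(centre_idx, dtype=int) + kernel_offsets(kernel)
    keep = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    return idx[keep]
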