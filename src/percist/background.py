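"""Background-activity VOIs, statistics and between-scan comparability.

PERCIST measures normal background uptake in a 3 cm diameter sphere in the
right liver lobe, or — when the liver is not usable — a 1 cm x 2 cm
cylinder in the descending aorta.  The background SULmean and SD define the
minimum-measurability threshold for lesions and gate whether two scans can
be compared at all.

Placement rule: among candidate centres where the VOI fits entirely inside
the organ mask, the chosen centre minimises

    score = |VOI mean - organ interquartile mean| + VOI SD

which steers the VOI away from focal lesions (mean pulled off the robust
organ mean) and from noisy regions (high SD).  Ties break on the
lexicographically smallest voxel index, so placement is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._geometry import (
    cylinder_kernel,
    ball_kernel,
    fits_inside,
    member_indices,
    sliding_mean_sd,
)
from .volumes import ScalarVolume

__all__ = [
    "LIVER_SPHERE_DIAMETER_MM",
    "AORTA_CYLINDER_DIAMETER_MM",
    "AORTA_CYLINDER_HEIGHT_MM",
    "BackgroundVOI",
    "BackgroundStats",
    "place_liver_voi",
    "place_aorta_voi",
    "background_stats",
    "check_comparability",
]

LIVER_SPHERE_DIAMETER_MM = 30.0
AORTA_CYLINDER_DIAMETER_MM = 10.0
AORTA_CYLINDER_HEIGHT_MM = 20.0

# threshold = a * SULmean + 2 * SD, per PERCIST 1.0
_THRESHOLD_MEAN_FACTOR = {"liver": 1.5, "aorta": 2.0}

# comparability gates between baseline and follow-up background
COMPARABILITY_MAX_ABS_DIFF_SUL = 0.3
COMPARABILITY_MAX_REL_DIFF = 0.20


@dataclass
class BackgroundVOI:
    """A placed background VOI: shape parameters plus the member voxel set."""

    organ: Literal["liver", "aorta"]
    shape: Literal["sphere", "cylinder"]
    centre_mm: np.ndarray
    member_voxels: np.ndarray  # (N, 3) int voxel indices
    axis: np.ndarray | None = None  # cylinder axis, world unit vector

    def as_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.member_voxels.T)] = True
        return m


@dataclass
class BackgroundStats:
    """Background SULmean / SD and the derived lesion threshold."""

    organ: Literal["liver", "aorta"]
    sul_mean: float
    sd: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "organ": self.organ,
            "sul_mean": self.sul_mean,
            "sd": self.sd,
            "threshold": self.threshold,
        }


def _interquartile_mean(values: np.ndarray) -> float:
    lo, hi = np.percentile(values, [25.0, 75.0])
    sel = values[(values >= lo) & (values <= hi)]
    return float(sel.mean()) if sel.size else float(values.mean())


def _select_centre(
    sul: ScalarVolume,
    organ_mask: np.ndarray,
    kernel: np.ndarray,
    stride: int,
) -> np.ndarray | None:
    """Lowest-score feasible centre, or None when the VOI cannot fit."""
    feasible = fits_inside(organ_mask, kernel)
    if not feasible.any():
        return None
    candidates = feasible.copy()
    if stride > 1:
        sub = np.zeros_like(candidates)
        sub[::stride, ::stride, ::stride] = True
        if (candidates & sub).any():
            candidates &= sub
    mean, sd = sliding_mean_sd(sul.values, kernel)
    robust = _interquartile_mean(sul.values[organ_mask])
    score = np.where(candidates, np.abs(mean - robust) + sd, np.inf)
    best = np.unravel_index(np.argmin(score), score.shape)  # first minimum: lexicographic
    return np.asarray(best, dtype=int)


def place_liver_voi(
    sul: ScalarVolume, liver_mask: np.ndarray, stride: int = 2
) -> BackgroundVOI:
    """Place the 3 cm background sphere fully inside the liver mask.

    ``stride`` subsamples candidate centres for speed (1 = exhaustive).
    Raises when no sphere of the required diameter fits, in which case the
    caller should fall back to the aorta VOI.
    """
    grid = sul.grid
    kernel = ball_kernel(grid.spacing, LIVER_SPHERE_DIAMETER_MM / 2.0)
    centre = _select_centre(sul, liver_mask, kernel, stride)
    if centre is None:
        raise ValueError(
            "liver mask cannot contain a 30 mm background sphere; "
            "fall back to the aorta VOI"
        )
    return BackgroundVOI(
        organ="liver",
        shape="sphere",
        centre_mm=grid.voxel_to_world(centre),
        member_voxels=member_indices(grid, centre, kernel),
    )


def _principal_axis(mask: np.ndarray, grid) -> np.ndarray:
    pts = grid.voxel_to_world(np.argwhere(mask))
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    axis = vt[0]
    return axis if axis[np.argmax(np.abs(axis))] >= 0 else -axis


def place_aorta_voi(
    sul: ScalarVolume, aorta_mask: np.ndarray, stride: int = 2
) -> BackgroundVOI:
    """Place the 1 cm x 2 cm background cylinder inside the aorta mask.

    The cylinder axis follows the principal axis of the mask (the vessel
    direction); the centre is chosen by the same lesion/noise-avoiding
    score as the liver sphere.
    """
    grid = sul.grid
    if not aorta_mask.any():
        raise ValueError("aorta mask is empty")
    axis_world = _principal_axis(aorta_mask, grid)
    # kernel offsets are built on the voxel lattice, so express the axis in
    # grid-aligned coordinates
    axis_grid = grid.direction_matrix.T @ axis_world
    kernel = cylinder_kernel(
        grid.spacing,
        AORTA_CYLINDER_DIAMETER_MM / 2.0,
        AORTA_CYLINDER_HEIGHT_MM,
        axis_grid,
    )
    centre = _select_centre(sul, aorta_mask, kernel, stride)
    if centre is None:
        raise ValueError(
            "aorta mask cannot contain a 10 mm x 20 mm cylinder "
            "(needs a straight segment of at least 20 mm)"
        )
    return BackgroundVOI(
        organ="aorta",
        shape="cylinder",
        centre_mm=grid.voxel_to_world(centre),
        member_voxels=member_indices(grid, centre, kernel),
        axis=axis_world,
    )


def background_stats(sul: ScalarVolume, voi: BackgroundVOI) -> BackgroundStats:
    """SULmean, SD and lesion threshold over the VOI member voxels.

    threshold = 1.5 * SULmean + 2 * SD for the liver and
    2.0 * SULmean + 2 * SD for the aorta, per PERCIST 1.0.
    """
    if voi.member_voxels.size == 0:
        raise ValueError("background VOI is empty")
    vals = sul.values[tuple(voi.member_voxels.T)]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    threshold = _THRESHOLD_MEAN_FACTOR[voi.organ] * mean + 2.0 * sd
    return BackgroundStats(organ=voi.organ, sul_mean=mean, sd=sd, threshold=threshold)


def check_comparability(
    baseline: BackgroundStats, followup: BackgroundStats
) -> dict:
    """PERCIST comparability gate between two scans' background activity.

    Comparable iff the background SULmean differs by less than 0.3 SUL
    units and by less than 20% relative to baseline (both strict).
    """
    if baseline.organ != followup.organ:
        raise ValueError(
            f"background organs differ: {baseline.organ} vs {followup.organ}"
        )
    abs_diff = abs(followup.sul_mean - baseline.sul_mean)
    rel_diff = abs_diff / baseline.sul_mean if baseline.sul_mean > 0 else np.inf
    reasons = []
    if not abs_diff < COMPARABILITY_MAX_ABS_DIFF_SUL:
        reasons.append(
            f"background SULmean differs by {abs_diff:.3f} >= "
            f"{COMPARABILITY_MAX_ABS_DIFF_SUL} SUL units"
        )
    if not rel_diff < COMPARABILITY_MAX_REL_DIFF:
        reasons.append(
            f"background SULmean differs by {100 * rel_diff:.1f}% >= "
            f"{100 * COMPARABILITY_MAX_REL_DIFF:.0f}%"
        )
    return {
        "comparable": not reasons,
        "abs_diff": abs_diff,
        "rel_diff": rel_diff,
        "reasons": reasons,
    }
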