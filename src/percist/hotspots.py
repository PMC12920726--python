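"""Hotspot detection, SULpeak extraction, classification and ranking.

A *hotspot* is a 26-connected component of voxels whose SUL exceeds the
background-derived threshold.  Its SULpeak is the PERCIST lesion metric:
the largest mean SUL over a 1 cm^3 sphere positioned (on voxel centres) to
maximise that mean.  Hotspots overlapping the normal-physiological-activity
segmentation are classified as physiological rather than lesions; the
remaining lesions are ranked by SULpeak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geometry import ball_kernel, sliding_mean_sd
from .volumes import ScalarVolume

__all__ = [
    "PEAK_SPHERE_VOLUME_MM3",
    "PEAK_SPHERE_RADIUS_MM",
    "Hotspot",
    "sul_peak",
    "peak_mean_map",
    "detect_hotspots",
    "classify_hotspots",
    "rank_hotspots",
    "hotspot_table",
]

PEAK_SPHERE_VOLUME_MM3 = 1000.0  # 1 cm^3, fixed by PERCIST
PEAK_SPHERE_RADIUS_MM = (3.0 * PEAK_SPHERE_VOLUME_MM3 / (4.0 * np.pi)) ** (1.0 / 3.0)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Hotspot:
    """One supra-threshold component with its SULpeak and classification."""

    component_id: int
    voxels: np.ndarray  # (N, 3) int indices
    sul_peak: float
    peak_centre_mm: np.ndarray
    peak_centre_idx: np.ndarray
    hotspot_class: Literal["lesion", "physiological", "unclassified"] = "unclassified"
    rank: int | None = None
    confirmed_class: Literal["lesion", "physiological", None] = None
    overlap_fraction: float = 0.0

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def effective_class(self) -> str:
        """User confirmation overrides the automatic class when present."""
        return self.confirmed_class or self.hotspot_class


def peak_mean_map(sul: ScalarVolume) -> np.ndarray:
    """Mean SUL over the 1 cm^3 peak sphere centred at every voxel.

    Near the grid edge the mean is taken over the in-grid part of the
    sphere footprint.
    """
    kernel = ball_kernel(sul.grid.spacing, PEAK_SPHERE_RADIUS_MM)
    mean, _ = sliding_mean_sd(sul.values, kernel)
    return mean


def sul_peak(
    sul: ScalarVolume,
    region_mask: np.ndarray,
    mean_map: np.ndarray | None = None,
    centre_exclusion: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """SULpeak of a candidate region: ``(value, centre_mm, centre_idx)``.

    Sphere centres range over the region dilated by one voxel; the sphere
    mean itself ignores component membership (background voxels inside the
    sphere count), matching the fixed-sphere PERCIST definition.  Ties
    break on the lexicographically smallest centre index.
    ``centre_exclusion`` (optional boolean map) removes centres, e.g. those
    whose sphere majority-overlaps physiological uptake.
    """
    if not region_mask.any():
        raise ValueError("candidate region is empty")
    if mean_map is None:
        mean_map = peak_mean_map(sul)
    candidates = ndimage.binary_dilation(region_mask, structure=_CONN26)
    if centre_exclusion is not None:
        candidates &= ~centre_exclusion
        if not candidates.any():
            raise ValueError("no admissible sphere centre in region")
    score = np.where(candidates, mean_map, -np.inf)
    best = np.unravel_index(np.argmax(score), score.shape)  # first max: lexicographic
    idx = np.asarray(best, dtype=int)
    return float(mean_map[best]), sul.grid.voxel_to_world(idx), idx


def detect_hotspots(
    sul: ScalarVolume,
    threshold: float,
    body_mask: np.ndarray | None = None,
) -> list[Hotspot]:
    """Connected supra-threshold components carrying their SULpeak.

    A voxel participates when its SUL is strictly above the threshold;
    components are kept when their SULpeak is >= the threshold as well, so
    an isolated noisy voxel whose sphere mean falls below the threshold is
    dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    supra = sul.values > threshold
    if body_mask is not None:
        supra &= body_mask
    labels, n = ndimage.label(supra, structure=_CONN26)
    if n == 0:
        return []
    mean_map = peak_mean_map(sul)
    hotspots: list[Hotspot] = []
    for comp_id, sl in enumerate(ndimage.find_objects(labels), start=1):
        comp = labels[sl] == comp_id
        voxels = np.argwhere(comp) + np.array([s.start for s in sl])
        region = np.zeros(sul.grid.shape, dtype=bool)
        region[tuple(voxels.T)] = True
        value, centre_mm, centre_idx = sul_peak(sul, region, mean_map=mean_map)
        if value >= threshold:
            hotspots.append(
                Hotspot(
                    component_id=comp_id,
                    voxels=voxels,
                    sul_peak=value,
                    peak_centre_mm=centre_mm,
                    peak_centre_idx=centre_idx,
                )
            )
    return hotspots


def classify_hotspots(
    hotspots: list[Hotspot], normal_mask: np.ndarray, grid_shape: tuple[int, int, int]
) -> list[Hotspot]:
    """Label each hotspot lesion vs physiological by majority overlap.

    A hotspot is physiological when more than half of its voxels lie
    inside the normal-activity mask.
    """
    if normal_mask.shape != tuple(grid_shape):
        raise ValueError("normal-activity mask is on a different grid")
    for h in hotspots:
        inside = normal_mask[tuple(h.voxels.T)].sum()
        h.overlap_fraction = float(inside) / h.n_voxels
        h.hotspot_class = "physiological" if h.overlap_fraction > 0.5 else "lesion"
    return hotspots


def rank_hotspots(hotspots: list[Hotspot]) -> list[Hotspot]:
    """Order by descending SULpeak; ties by size then centre index."""
    ordered = sorted(
        hotspots,
        key=lambda h: (-h.sul_peak, -h.n_voxels, tuple(h.peak_centre_idx)),
    )
    for rank, h in enumerate(ordered, start=1):
        h.rank = rank
    return ordered


def hotspot_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    """Hotspot list as a tidy table (one row per hotspot)."""
    rows = []
    for h in hotspots:
        rows.append(
            {
                "rank": h.rank,
                "component_id": h.component_id,
                "sul_peak": h.sul_peak,
                "centre_x_mm": h.peak_centre_mm[0],
                "centre_y_mm": h.peak_centre_mm[1],
                "centre_z_mm": h.peak_centre_mm[2],
                "n_voxels": h.n_voxels,
                "class": h.effective_class,
                "overlap_fraction": h.overlap_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "component_id",
            "sul_peak",
            "centre_x_mm",
            "centre_y_mm",
            "centre_z_mm",
            "n_voxels",
            "class",
            "overlap_fraction",
        ],
    )
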