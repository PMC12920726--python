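"""Longitudinal SULpeak comparison: map follow-up lesions into baseline.

For each lesion in the follow-up study, the location of its SULpeak is
mapped to the baseline study through the displacement field.  Within a
search sphere centred on the mapped point — radius given by the per-voxel
alignment uncertainty — the highest non-physiological SULpeak in the
baseline is extracted and the percentage change computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geometry import ball_kernel, sliding_count_inside
from .alignment import DisplacementField
from .hotspots import Hotspot, peak_mean_map
from .volumes import ScalarVolume

__all__ = [
    "LesionPair",
    "map_point",
    "paired_sulpeak",
    "percent_change",
    "build_pairs",
    "pair_table",
]


@dataclass
class LesionPair:
    """A follow-up lesion linked to its baseline SULpeak (when found)."""

    followup_id: int
    followup_sul_peak: float
    mapped_point_mm: np.ndarray
    search_radius_mm: float
    baseline_sul_peak: float | None
    baseline_peak_mm: np.ndarray | None
    percent_change: float | None
    new_lesion: bool = False
    unequivocal_progression: bool = False

    @property
    def absolute_change(self) -> float | None:
        if self.baseline_sul_peak is None:
            return None
        return self.followup_sul_peak - self.baseline_sul_peak


def map_point(field: DisplacementField, point_mm: np.ndarray) -> np.ndarray:
    """Map a source-study point to the target study: p + u(p).

    The displacement is interpolated trilinearly at the point; points
    outside the field grid raise.
    """
    p = np.asarray(point_mm, dtype=float)
    idx = field.grid.world_to_voxel(p)
    if np.any(idx < -0.5) or np.any(idx > np.asarray(field.grid.shape) - 0.5):
        raise ValueError(f"point {p} lies outside the displacement-field grid")
    idx_clip = np.clip(idx, 0, np.asarray(field.grid.shape) - 1.0)
    u = np.array(
        [
            ndimage.map_coordinates(field.u[..., k], idx_clip[:, None], order=1)[0]
            for k in range(3)
        ]
    )
    return p + u


def percent_change(baseline_sul_peak: float, followup_sul_peak: float) -> float:
    """Relative SULpeak change, in percent of the baseline value."""
    if baseline_sul_peak is None or baseline_sul_peak <= 0:
        raise ValueError("percent change undefined for absent or non-positive baseline")
    return 100.0 * (followup_sul_peak - baseline_sul_peak) / baseline_sul_peak


def paired_sulpeak(
    baseline_sul: ScalarVolume,
    baseline_normal_mask: np.ndarray,
    centre_mm: np.ndarray,
    radius_mm: float,
    mean_map: np.ndarray | None = None,
    physiological_fraction: np.ndarray | None = None,
) -> tuple[float | None, np.ndarray | None]:
    """Highest non-physiological SULpeak within the search sphere.

    Candidate peak-sphere centres are the voxel centres within
    ``radius_mm`` of ``centre_mm`` (radius 0 keeps only the nearest
    voxel).  Centres whose 1 cm^3 peak sphere majority-overlaps the
    normal-activity mask are excluded — the same >50% vote used for
    hotspot classification.  Returns ``(None, None)`` when no admissible
    centre exists.
    """
    if radius_mm < 0:
        raise ValueError("search radius must be non-negative")
    grid = baseline_sul.grid
    if mean_map is None:
        mean_map = peak_mean_map(baseline_sul)
    if physiological_fraction is None:
        kernel = ball_kernel(grid.spacing, _peak_radius())
        ones = np.ones(grid.shape)
        physiological_fraction = sliding_count_inside(
            baseline_normal_mask, kernel
        ) / np.maximum(sliding_count_inside(ones.astype(bool), kernel), 1e-12)

    centre_idx = np.asarray(np.round(grid.world_to_voxel(centre_mm)), dtype=int)
    centre_idx = np.clip(centre_idx, 0, np.asarray(grid.shape) - 1)
    search = ball_kernel(grid.spacing, max(radius_mm, 0.0))
    from ._geometry import member_indices

    candidates = member_indices(grid, centre_idx, search)
    frac = physiological_fraction[tuple(candidates.T)]
    admissible = candidates[frac <= 0.5]
    if len(admissible) == 0:
        return None, None
    vals = mean_map[tuple(admissible.T)]
    best = int(np.argmax(vals))
    return float(vals[best]), grid.voxel_to_world(admissible[best])


def _peak_radius() -> float:
    from .hotspots import PEAK_SPHERE_RADIUS_MM

    return PEAK_SPHERE_RADIUS_MM


def build_pairs(
    followup_lesions: list[Hotspot],
    field: DisplacementField,
    uncertainty: ScalarVolume,
    baseline_sul: ScalarVolume,
    baseline_normal_mask: np.ndarray,
) -> list[LesionPair]:
    """One :class:`LesionPair` per follow-up lesion, hottest first.

    The search radius is the alignment uncertainty at the lesion's
    follow-up SULpeak voxel.  Lesions whose search sphere contains no
    admissible baseline centre come back with an absent baseline SULpeak
    and are candidates for the new-lesion flag.
    """
    mean_map = peak_mean_map(baseline_sul)
    kernel = ball_kernel(baseline_sul.grid.spacing, _peak_radius())
    ones = np.ones(baseline_sul.grid.shape, dtype=bool)
    frac = sliding_count_inside(baseline_normal_mask, kernel) / np.maximum(
        sliding_count_inside(ones, kernel), 1e-12
    )
    pairs = []
    for h in sorted(followup_lesions, key=lambda h: -h.sul_peak):
        radius = float(uncertainty.values[tuple(h.peak_centre_idx)])
        mapped = map_point(field, h.peak_centre_mm)
        value, location = paired_sulpeak(
            baseline_sul,
            baseline_normal_mask,
            mapped,
            radius,
            mean_map=mean_map,
            physiological_fraction=frac,
        )
        change = (
            percent_change(value, h.sul_peak) if value is not None and value > 0 else None
        )
        pairs.append(
            LesionPair(
                followup_id=h.component_id,
                followup_sul_peak=h.sul_peak,
                mapped_point_mm=mapped,
                search_radius_mm=radius,
                baseline_sul_peak=value,
                baseline_peak_mm=location,
                percent_change=change,
            )
        )
    return pairs


def pair_table(pairs: list[LesionPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "followup_id": p.followup_id,
                "followup_sul_peak": p.followup_sul_peak,
                "baseline_sul_peak": p.baseline_sul_peak,
                "percent_change": p.percent_change,
                "absolute_change": p.absolute_change,
                "search_radius_mm": p.search_radius_mm,
                "new_lesion": p.new_lesion,
                "unequivocal_progression": p.unequivocal_progression,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "followup_id",
            "followup_sul_peak",
            "baseline_sul_peak",
            "percent_change",
            "absolute_change",
            "search_radius_mm",
            "new_lesion",
            "unequivocal_progression",
        ],
    )
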