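"""Alignment-uncertainty calibration and per-voxel uncertainty maps.

Calibration propagates organ segmentations with the estimated transforms
and measures the Hausdorff distance between the propagated and actual
masks, organ by organ, over a set of study pairs.  The within-organ
uncertainty is the 75th percentile of those distances.  Outside segmented
organs the uncertainty grows linearly with the distance to the nearest
organ boundary at 0.2 mm per mm, starting from that organ's own value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .volumes import ImageGrid, LabelVolume, ScalarVolume

__all__ = [
    "OUTSIDE_GROWTH_RATE_MM_PER_MM",
    "UNCERTAINTY_PERCENTILE",
    "UncertaintyTable",
    "hausdorff",
    "calibrate",
    "uncertainty_map",
]

OUTSIDE_GROWTH_RATE_MM_PER_MM = 0.2
UNCERTAINTY_PERCENTILE = 75.0


@dataclass
class UncertaintyTable:
    """Per-organ Hausdorff-distance samples and the derived uncertainty.

    ``values`` maps organ name to its within-organ uncertainty: the 75th
    percentile (linear interpolation between order statistics) of the
    calibration distances.  Optional ``groups`` pool several organ labels
    into one shared distance list before the percentile is taken.
    """

    distances: dict[str, list[float]] = field(default_factory=dict)

    @property
    def values(self) -> dict[str, float]:
        return {
            organ: float(np.percentile(d, UNCERTAINTY_PERCENTILE))
            for organ, d in self.distances.items()
            if len(d)
        }

    def value_for(self, organ: str) -> float:
        """Uncertainty for an organ; conservative table maximum if absent."""
        vals = self.values
        if organ in vals:
            return vals[organ]
        if not vals:
            raise ValueError("uncertainty table is empty")
        return max(vals.values())

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"distances": self.distances, "values": self.values}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "UncertaintyTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(distances={k: list(map(float, v)) for k, v in d["distances"].items()})


def _boundary_points(mask: np.ndarray, grid: ImageGrid) -> np.ndarray:
    inner = ndimage.binary_erosion(mask)
    boundary = mask & ~inner
    return grid.voxel_to_world(np.argwhere(boundary))


def hausdorff(mask_a: np.ndarray, mask_b: np.ndarray, grid: ImageGrid) -> float:
    """Symmetric Hausdorff distance (mm) between two masks' boundaries."""
    if not mask_a.any() or not mask_b.any():
        raise ValueError("Hausdorff distance of an empty mask is undefined")
    from scipy.spatial import cKDTree

    pa = _boundary_points(mask_a, grid)
    pb = _boundary_points(mask_b, grid)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def calibrate(
    pairs: Iterable[tuple[Mapping[str, np.ndarray], Mapping[str, np.ndarray]]],
    grid: ImageGrid,
    groups: Mapping[str, str] | None = None,
) -> UncertaintyTable:
    """Build an :class:`UncertaintyTable` from propagated/actual mask pairs.

    Each element of ``pairs`` is ``(propagated, actual)``: two dicts of
    organ name -> boolean mask.  Organs absent from a pair are skipped;
    an organ absent from every pair is simply not in the table.  With
    ``groups`` (organ -> group name) distances are pooled per group.
    """
    table = UncertaintyTable()
    for propagated, actual in pairs:
        for organ in propagated:
            if organ not in actual:
                continue
            key = groups.get(organ, organ) if groups else organ
            d = hausdorff(propagated[organ], actual[organ], grid)
            table.distances.setdefault(key, []).append(d)
    return table


def uncertainty_map(
    organ_labels: LabelVolume,
    table: UncertaintyTable,
    groups: Mapping[str, str] | None = None,
) -> ScalarVolume:
    """Per-voxel alignment uncertainty (mm).

    Voxels inside an organ take that organ's 75th-percentile Hausdorff
    value; voxels outside take the nearest organ's value plus 0.2 mm per
    mm of Euclidean distance to the nearest organ voxel.  Organs missing
    from the table fall back to the table-wide maximum.
    """
    labels = organ_labels.labels
    if not (labels > 0).any():
        raise ValueError("label volume contains no organs")
    grid = organ_labels.grid
    base = np.zeros(labels.shape, dtype=float)
    for lab in organ_labels.present_labels:
        name = organ_labels.legend[lab]
        key = groups.get(name, name) if groups else name
        base[labels == lab] = table.value_for(key)
    outside = labels == 0
    dist, nearest = ndimage.distance_transform_edt(
        outside, sampling=grid.spacing, return_indices=True
    )
    values = base[tuple(nearest)]
    values[outside] += OUTSIDE_GROWTH_RATE_MM_PER_MM * dist[outside]
    return ScalarVolume(grid=grid, values=values, kind="uncertainty_mm")
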