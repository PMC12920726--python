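"""Voxel-grid data model, NIfTI I/O, and SUL conversion.

The geometric convention used throughout the package: world coordinates are
in millimetres, voxel indices are 0-based, and the value of a voxel is
located at the voxel centre.  The mapping between voxel indices and world
coordinates is an affine built from an orthonormal direction matrix, the
per-axis spacing, and the world position of voxel (0, 0, 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "LabelVolume",
    "PatientMeta",
    "VolumeKind",
    "compute_lbm",
    "to_sul",
    "read_volume",
    "write_volume",
]

VolumeKind = Literal["activity_kBq_per_mL", "SUL", "HU", "distance_mm", "uncertainty_mm"]
_KINDS = ("activity_kBq_per_mL", "SUL", "HU", "distance_mm", "uncertainty_mm")


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3-D voxel grid: shape, spacing (mm), origin (mm), orientation.

    ``direction`` is a 3x3 orthonormal matrix whose columns are the world
    directions of the voxel axes.  World coordinates of voxel index ``i``
    are ``origin + direction @ (spacing * i)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3, 3) or not np.allclose(d.T @ d, np.eye(3), atol=1e-8):
            raise ValueError("direction matrix must be 3x3 orthonormal")
        if not np.isclose(abs(np.linalg.det(d)), 1.0, atol=1e-8):
            raise ValueError("direction matrix determinant must be +/-1")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "direction", tuple(tuple(float(x) for x in row) for row in d))

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction_matrix @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (``(..., 3)``, may be fractional) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) @ self.direction_matrix.T + np.asarray(self.origin)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world-mm points (``(..., 3)``) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) @ self.direction_matrix / np.asarray(self.spacing)

    @property
    def centre(self) -> np.ndarray:
        """World coordinate of the geometric grid centre."""
        return self.voxel_to_world((np.asarray(self.shape, dtype=float) - 1.0) / 2.0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_family(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        """True if shapes match and spacing/origin/direction agree within tol mm."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class ScalarVolume:
    """Real-valued volume on an :class:`ImageGrid` with a physical kind."""

    grid: ImageGrid
    values: np.ndarray
    kind: VolumeKind = "SUL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.kind not in _KINDS:
            raise ValueError(f"unknown volume kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.kind == "SUL" and np.any(self.values < 0):
            raise ValueError("SUL values must be non-negative")


@dataclass
class LabelVolume:
    """Integer label volume with a legend; label 0 is background."""

    grid: ImageGrid
    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} does not match grid {self.grid.shape}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def present_labels(self) -> list[int]:
        return sorted(set(int(v) for v in np.unique(self.labels)) - {0})


@dataclass(frozen=True)
class PatientMeta:
    """Patient data needed for SUL quantification.

    ``sex`` is restricted to the two categories of the James lean-body-mass
    equations; ``injected_dose_mbq`` is the decay-corrected injected
    activity in MBq.
    """

    sex: Literal["male", "female"]
    weight_kg: float
    height_cm: float
    injected_dose_mbq: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("weight_kg", "height_cm", "injected_dose_mbq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PatientMeta":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            sex=d["sex"],
            weight_kg=float(d["weight_kg"]),
            height_cm=float(d["height_cm"]),
            injected_dose_mbq=float(d["injected_dose_mbq"]),
        )

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "weight_kg": self.weight_kg,
            "height_cm": self.height_cm,
            "injected_dose_mbq": self.injected_dose_mbq,
        }


def compute_lbm(sex: str, weight_kg: float, height_cm: float) -> float:
    """Lean body mass (kg) from the James equations.

    male:   LBM = 1.10 W - 128 (W/H)^2
    female: LBM = 1.07 W - 148 (W/H)^2

    with W in kg and H in cm.  Raises for non-physiological inputs that
    would yield a non-positive mass.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    ratio2 = (weight_kg / height_cm) ** 2
    if sex == "male":
        lbm = 1.10 * weight_kg - 128.0 * ratio2
    elif sex == "female":
        lbm = 1.07 * weight_kg - 148.0 * ratio2
    else:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if lbm <= 0:
        raise ValueError(
            f"non-physiological input: James equation gives LBM={lbm:.2f} kg <= 0"
        )
    return lbm


def to_sul(activity: ScalarVolume, meta: PatientMeta) -> ScalarVolume:
    """Convert an activity-concentration volume (kBq/mL) to SUL.

    SUL(x) = C(x)[Bq/mL] * LBM[g] / dose[Bq], i.e. uptake normalised by
    injected dose per gram of lean body mass, assuming 1 g/mL tissue
    density.  The activity must already be decay-corrected to the
    reference time by the caller.
    """
    if activity.kind != "activity_kBq_per_mL":
        raise ValueError(f"expected an activity volume, got kind={activity.kind!r}")
    lbm_g = compute_lbm(meta.sex, meta.weight_kg, meta.height_cm) * 1000.0
    dose_bq = meta.injected_dose_mbq * 1e6
    sul = activity.values * 1000.0 * lbm_g / dose_bq
    return ScalarVolume(grid=activity.grid, values=np.maximum(sul, 0.0), kind="SUL")


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> ImageGrid:
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("NIfTI affine has a zero-length axis")
    direction = lin / spacing
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-4):
        raise ValueError("NIfTI affine is not orthonormal up to spacing (oblique/sheared grid)")
    # re-orthonormalise exactly so ImageGrid invariants hold
    u, _, vt = np.linalg.svd(direction)
    direction = u @ vt
    return ImageGrid(
        shape=tuple(int(s) for s in shape[:3]),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in affine[:3, 3]),
        direction=tuple(tuple(float(x) for x in row) for row in direction),
    )


def read_volume(
    path: str | Path,
    kind: VolumeKind | None = None,
    legend: str | Path | Mapping[int, str] | None = None,
) -> ScalarVolume | LabelVolume:
    """Read a NIfTI volume.

    If ``legend`` is given (a mapping or a path to a JSON sidecar mapping
    label -> name) the file is read as a :class:`LabelVolume`; otherwise as
    a :class:`ScalarVolume` of the given ``kind`` (default SUL).
    """
    img = nib.load(str(path))
    if img.affine is None:
        raise ValueError(f"{path}: NIfTI file has no affine header")
    grid = _grid_from_affine(np.asarray(img.affine, dtype=float), img.shape)
    data = np.asanyarray(img.dataobj)
    if legend is not None:
        if isinstance(legend, (str, Path)):
            with open(legend) as fh:
                legend = {int(k): v for k, v in json.load(fh).items()}
        return LabelVolume(grid=grid, labels=np.asarray(data).astype(np.int32), legend=dict(legend))
    return ScalarVolume(grid=grid, values=np.asarray(data, dtype=float), kind=kind or "SUL")


def write_volume(volume: ScalarVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; label legends go to a ``.json`` sidecar."""
    path = Path(path)
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.int32)
        legend_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
        with open(legend_path, "w") as fh:
            json.dump({str(k): v for k, v in volume.legend.items()}, fh, indent=1)
    else:
        data = volume.values.astype(np.float64)
    img = nib.Nifti1Image(data, volume.grid.affine)
    nib.save(img, str(path))


def require_same_grid(*volumes: ScalarVolume | LabelVolume, tol: float = 1e-6) -> None:
    """Raise if the volumes are not on the same grid family."""
    ref = volumes[0].grid
    for v in volumes[1:]:
        if not ref.same_family(v.grid, tol=tol):
            raise ValueError("volumes are on mismatched grids")
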