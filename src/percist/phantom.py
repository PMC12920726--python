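"""Synthetic whole-body PET phantom pairs with known ground truth.

The phantom emulates a desk-scale whole-body FDG study: a 96 x 96 x 160
grid at 3 mm isotropic spacing carrying a body envelope (SUL ~1), organs
with characteristic uptake in all six anatomical regions, physiological
high-uptake structures (brain, heart, bladder), spherical lesions, and
additive Gaussian noise.  A paired follow-up study is generated by moving
each organ with a known rigid or affine transform and repainting lesions
with designed SULpeak changes, so alignment, pairing and response
classification can all be scored against truth.

Lesions are uniform spheres with radius >= the SULpeak sphere radius, so
the designed amplitude *is* the designed SULpeak (up to noise) and percent
changes are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .response import ResponseInput, classify_response
from .volumes import ImageGrid, LabelVolume, ScalarVolume

__all__ = [
    "OrganSpec",
    "LesionSpec",
    "PhantomSpec",
    "PhantomPair",
    "default_spec",
    "make_phantom_pair",
    "make_calibration_set",
]

Scenario = Literal["pmr", "pmd_increase", "new_lesion", "smd", "cmr", "identity"]


@dataclass(frozen=True)
class OrganSpec:
    """An analytic organ primitive plus its ground-truth motion."""

    name: str
    primitive: Literal["ellipsoid", "cylinder", "box"]
    centre: tuple[float, float, float]  # mm
    size: tuple[float, float, float]  # semi-axes / (radius, radius, half-height) / half-sides
    uptake: float
    model: Literal["rigid", "affine"] = "affine"
    normal_activity: bool = False
    # ground-truth baseline -> follow-up map T(x) = M x + t
    matrix: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ np.asarray(self.matrix).T + np.asarray(self.translation)

    def inverse_transform_points(self, pts: np.ndarray) -> np.ndarray:
        m = np.linalg.inv(np.asarray(self.matrix))
        return (pts - np.asarray(self.translation)) @ m.T


@dataclass(frozen=True)
class LesionSpec:
    """A uniform spherical lesion anchored to an organ (or to the body)."""

    centre: tuple[float, float, float]  # baseline, mm
    radius_mm: float
    baseline_sul: float | None  # None: absent at baseline (new lesion)
    followup_sul: float | None  # None: absent at follow-up
    organ: str | None = None  # moves with this organ's transform

    @property
    def new(self) -> bool:
        return self.baseline_sul is None and self.followup_sul is not None


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 160)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    organs: tuple[OrganSpec, ...] = ()
    lesions: tuple[LesionSpec, ...] = ()
    background_sul: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(shape=self.shape, spacing=self.spacing)


@dataclass
class PhantomPair:
    """Paired baseline/follow-up phantom studies plus the truth record."""

    baseline_sul: ScalarVolume
    baseline_organs: LabelVolume
    baseline_normal: LabelVolume
    followup_sul: ScalarVolume
    followup_organs: LabelVolume
    followup_normal: LabelVolume
    truth: dict


# ---------------------------------------------------------------- geometry

def _membership(organ: OrganSpec, pts: np.ndarray) -> np.ndarray:
    d = pts - np.asarray(organ.centre)
    s = np.asarray(organ.size, dtype=float)
    if organ.primitive == "ellipsoid":
        return np.sum((d / s) ** 2, axis=-1) <= 1.0
    if organ.primitive == "box":
        return np.all(np.abs(d) <= s, axis=-1)
    if organ.primitive == "cylinder":  # axis along z; size = (r, r, half-height)
        return (d[..., 0] ** 2 + d[..., 1] ** 2 <= s[0] ** 2) & (
            np.abs(d[..., 2]) <= s[2]
        )
    raise ValueError(f"unknown primitive {organ.primitive!r}")


def _world_coords(grid: ImageGrid) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1
    )
    return grid.voxel_to_world(idx)


def _paint_sphere(values: np.ndarray, pts: np.ndarray, centre, radius, amplitude):
    # evaluate only near the sphere for speed
    step = pts[1, 1, 1] - pts[0, 0, 0] if pts.shape[0] > 1 else np.ones(3)
    c = np.asarray(centre, dtype=float)
    lo = np.maximum(((c - radius - pts[0, 0, 0]) / step).astype(int) - 1, 0)
    hi = np.minimum(((c + radius - pts[0, 0, 0]) / step).astype(int) + 2, values.shape)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    inside = np.sum((pts[sl] - c) ** 2, axis=-1) <= radius**2
    values[sl][inside] = amplitude


# --------------------------------------------------------------- defaults

_BASE_ORGANS: tuple[OrganSpec, ...] = (
    OrganSpec("brain", "ellipsoid", (144, 144, 438), (40, 40, 35), 5.0, "affine", True),
    OrganSpec("liver", "ellipsoid", (92, 150, 300), (40, 35, 30), 2.0, "affine"),
    OrganSpec("spleen", "ellipsoid", (198, 150, 310), (18, 16, 16), 1.8, "affine"),
    OrganSpec("left_lung", "ellipsoid", (95, 130, 372), (24, 22, 34), 0.5, "affine"),
    OrganSpec("right_lung", "ellipsoid", (193, 130, 372), (24, 22, 34), 0.5, "affine"),
    OrganSpec("heart", "ellipsoid", (144, 118, 352), (21, 21, 21), 4.0, "affine", True),
    OrganSpec("aorta", "cylinder", (144, 172, 290), (8, 8, 90), 1.6, "affine"),
    OrganSpec("urinary_bladder", "ellipsoid", (144, 144, 192), (16, 16, 16), 6.0, "affine", True),
    OrganSpec("vertebra_1", "box", (144, 205, 225), (12, 12, 18), 1.2, "rigid"),
    OrganSpec("vertebra_2", "box", (144, 205, 285), (12, 12, 18), 1.2, "rigid"),
    OrganSpec("vertebra_3", "box", (144, 205, 345), (12, 12, 18), 1.2, "rigid"),
    OrganSpec("left_humerus", "cylinder", (30, 144, 330), (10, 10, 70), 1.2, "rigid"),
    OrganSpec("right_humerus", "cylinder", (258, 144, 330), (10, 10, 70), 1.2, "rigid"),
    OrganSpec("left_femur", "cylinder", (100, 144, 95), (12, 12, 75), 1.2, "rigid"),
    OrganSpec("right_femur", "cylinder", (188, 144, 95), (12, 12, 75), 1.2, "rigid"),
)

# body envelope primitives (not organs, just where background uptake lives)
_BODY_PARTS: tuple[OrganSpec, ...] = (
    OrganSpec("head_env", "ellipsoid", (144, 144, 438), (52, 52, 42), 0.0),
    OrganSpec("neck_env", "cylinder", (144, 144, 405), (30, 30, 15), 0.0),
    OrganSpec("torso_env", "box", (144, 144, 295), (88, 62, 115), 0.0),
    OrganSpec("larm_env", "cylinder", (30, 144, 330), (22, 22, 80), 0.0),
    OrganSpec("rarm_env", "cylinder", (258, 144, 330), (22, 22, 80), 0.0),
    OrganSpec("lleg_env", "cylinder", (100, 144, 90), (28, 28, 88), 0.0),
    OrganSpec("rleg_env", "cylinder", (188, 144, 90), (28, 28, 88), 0.0),
)

_TARGET_LESION = (95.0, 130.0, 372.0)  # inside left lung
_SECOND_LESION = (193.0, 130.0, 360.0)  # inside right lung
_NEW_LESION = (144.0, 125.0, 260.0)  # torso soft tissue

_SCENARIO_LESIONS: dict[str, tuple[LesionSpec, ...]] = {
    "identity": (
        LesionSpec(_TARGET_LESION, 9.0, 6.0, 6.0, "left_lung"),
        LesionSpec(_SECOND_LESION, 9.0, 5.0, 5.0, "right_lung"),
    ),
    "pmr": (
        LesionSpec(_TARGET_LESION, 9.0, 6.0, 3.6, "left_lung"),
        LesionSpec(_SECOND_LESION, 9.0, 5.0, 3.25, "right_lung"),
    ),
    "pmd_increase": (
        LesionSpec(_TARGET_LESION, 9.0, 6.0, 8.4, "left_lung"),
        LesionSpec(_SECOND_LESION, 9.0, 5.0, 6.5, "right_lung"),
    ),
    "new_lesion": (
        LesionSpec(_TARGET_LESION, 9.0, 6.0, 6.0, "left_lung"),
        LesionSpec(_NEW_LESION, 9.0, None, 5.0, None),
    ),
    "smd": (
        LesionSpec(_TARGET_LESION, 9.0, 6.0, 6.6, "left_lung"),
        LesionSpec(_SECOND_LESION, 9.0, 5.0, 5.2, "right_lung"),
    ),
    "cmr": (LesionSpec(_TARGET_LESION, 9.0, 6.0, None, "left_lung"),),
}


def _random_transform(
    rng: np.random.Generator, model: str, max_translation_mm: float, centre: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Small rigid/affine motion about the organ centre, 2 mm .. max mm."""
    mag = rng.uniform(2.0, max_translation_mm)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift = mag * direction
    angle = np.deg2rad(rng.uniform(-4.0, 4.0))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    if model == "affine":
        scale = np.diag(rng.uniform(0.96, 1.04, size=3))
        mat = rot @ scale
    else:
        mat = rot
    # rotate/scale about the organ centre, then translate
    t = centre - mat @ centre + shift
    return mat, t


def default_spec(
    seed: int = 0,
    scenario: Scenario = "identity",
    moving: bool = False,
    max_translation_mm: float = 8.0,
    noise_sd: float = 0.05,
) -> PhantomSpec:
    """The stock whole-body phantom.

    ``scenario`` fixes the designed lesion changes (and hence the intended
    response class); ``moving=True`` draws a random rigid/affine
    ground-truth transform per organ with translation magnitude in
    [2, ``max_translation_mm``] mm.
    """
    rng = np.random.default_rng(seed)
    grid = PhantomSpec().grid
    world_hi = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    organs = []
    for organ in _BASE_ORGANS:
        if moving:
            centre = np.asarray(organ.centre)
            reach = np.asarray(organ.size, dtype=float)
            corners = centre + reach * np.array(
                [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
            )
            # redraw transforms that would push the organ off the grid
            for _ in range(50):
                mat, t = _random_transform(
                    rng, organ.model, max_translation_mm, centre
                )
                moved = corners @ mat.T + t
                if np.all(moved >= 1.0) and np.all(moved <= world_hi - 1.0):
                    break
            else:
                raise ValueError(
                    f"could not draw an in-grid transform for {organ.name!r}"
                )
            organ = replace(
                organ,
                matrix=tuple(tuple(float(x) for x in row) for row in mat),
                translation=tuple(float(x) for x in t),
            )
        organs.append(organ)
    return PhantomSpec(
        organs=tuple(organs),
        lesions=_SCENARIO_LESIONS[scenario],
        noise_sd=noise_sd,
        seed=seed,
    )


# -------------------------------------------------------------- generation

def _check_no_overlap(masks: dict[str, np.ndarray]) -> None:
    total = np.zeros(next(iter(masks.values())).shape, dtype=np.int8)
    for m in masks.values():
        total += m
    if total.max() > 1:
        names = [n for n, m in masks.items() if (m & (total > 1)).any()]
        raise ValueError(f"phantom organs overlap: {names}")


def _bbox_slices(
    idx: np.ndarray, shape: tuple[int, int, int], margin: int = 3
) -> tuple[slice, slice, slice]:
    lo = np.maximum(np.floor(idx.min(axis=0)).astype(int) - margin, 0)
    hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int) + margin + 1, shape)
    return tuple(slice(l, h) for l, h in zip(lo, hi))


def _propagate_mask(
    base_mask: np.ndarray, organ: OrganSpec, grid: ImageGrid, pts: np.ndarray
) -> np.ndarray:
    """Follow-up mask: baseline mask moved by the truth transform (NN resample)."""
    moved = organ.transform_points(grid.voxel_to_world(np.argwhere(base_mask)))
    sl = _bbox_slices(grid.world_to_voxel(moved), grid.shape)
    sub = pts[sl].reshape(-1, 3)
    back = organ.inverse_transform_points(sub)
    vox = grid.world_to_voxel(back).T
    out = np.zeros(grid.shape, dtype=bool)
    sampled = ndimage.map_coordinates(
        base_mask.astype(np.float32), vox, order=0, mode="constant", cval=0.0
    )
    out[sl] = (sampled > 0.5).reshape(pts[sl].shape[:3])
    return out


def _check_inside(organ: OrganSpec, mask: np.ndarray, grid: ImageGrid) -> None:
    pts = grid.voxel_to_world(np.argwhere(mask))
    moved = organ.transform_points(pts)
    vox = grid.world_to_voxel(moved)
    if np.any(vox < -0.5) or np.any(vox >= np.asarray(grid.shape) - 0.5):
        raise ValueError(
            f"ground-truth transform pushes organ {organ.name!r} outside the grid"
        )


def make_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate a paired baseline/follow-up phantom study from ``spec``.

    Deterministic under the spec seed (bit-identical volumes).
    """
    grid = spec.grid
    pts = _world_coords(grid)
    rng = np.random.default_rng(spec.seed)

    body = np.zeros(grid.shape, dtype=bool)
    for part in _BODY_PARTS:
        body |= _membership(part, pts)

    def organ_mask(o: OrganSpec) -> np.ndarray:
        reach = np.asarray(o.size, dtype=float)
        lo = grid.world_to_voxel(np.asarray(o.centre) - reach - 1.0)
        hi = grid.world_to_voxel(np.asarray(o.centre) + reach + 1.0)
        sl = _bbox_slices(np.stack([lo, hi]), grid.shape, margin=1)
        out = np.zeros(grid.shape, dtype=bool)
        out[sl] = _membership(o, pts[sl])
        return out & body

    base_masks = {o.name: organ_mask(o) for o in spec.organs}
    for o in spec.organs:
        if not base_masks[o.name].any():
            raise ValueError(f"organ {o.name!r} is empty on this grid")
    _check_no_overlap(base_masks)
    for o in spec.organs:
        _check_inside(o, base_masks[o.name], grid)

    legend = {i + 1: o.name for i, o in enumerate(spec.organs)}
    organ_by_name = {o.name: o for o in spec.organs}

    def paint(masks: dict[str, np.ndarray], followup: bool) -> np.ndarray:
        values = np.zeros(grid.shape)
        values[body] = spec.background_sul
        for o in spec.organs:
            values[masks[o.name]] = o.uptake
        for lesion in spec.lesions:
            amp = lesion.followup_sul if followup else lesion.baseline_sul
            if amp is None:
                continue
            centre = np.asarray(lesion.centre, dtype=float)
            if followup and lesion.organ is not None:
                centre = organ_by_name[lesion.organ].transform_points(centre)
            _paint_sphere(values, pts, centre, lesion.radius_mm, amp)
        return values

    def labelise(masks: dict[str, np.ndarray]) -> tuple[LabelVolume, LabelVolume]:
        labels = np.zeros(grid.shape, dtype=np.int32)
        normal = np.zeros(grid.shape, dtype=np.int32)
        normal_legend = {}
        for lab, name in legend.items():
            labels[masks[name]] = lab
            if organ_by_name[name].normal_activity:
                normal[masks[name]] = lab
                normal_legend[lab] = name
        return (
            LabelVolume(grid=grid, labels=labels, legend=legend),
            LabelVolume(grid=grid, labels=normal, legend=normal_legend),
        )

    fu_masks = {
        o.name: _propagate_mask(base_masks[o.name], o, grid, pts) for o in spec.organs
    }

    base_values = paint(base_masks, followup=False)
    fu_values = paint(fu_masks, followup=True)
    if spec.noise_sd > 0:
        base_values = base_values + rng.normal(0.0, spec.noise_sd, grid.shape)
        fu_values = fu_values + rng.normal(0.0, spec.noise_sd, grid.shape)
    base_values = np.maximum(base_values, 0.0)
    fu_values = np.maximum(fu_values, 0.0)

    base_organs, base_normal = labelise(base_masks)
    fu_organs, fu_normal = labelise(fu_masks)

    truth = _truth_record(spec, organ_by_name)
    return PhantomPair(
        baseline_sul=ScalarVolume(grid=grid, values=base_values, kind="SUL"),
        baseline_organs=base_organs,
        baseline_normal=base_normal,
        followup_sul=ScalarVolume(grid=grid, values=fu_values, kind="SUL"),
        followup_organs=fu_organs,
        followup_normal=fu_normal,
        truth=truth,
    )


def _truth_record(spec: PhantomSpec, organ_by_name: dict[str, OrganSpec]) -> dict:
    lesions = []
    for lesion in spec.lesions:
        fu_centre = np.asarray(lesion.centre, dtype=float)
        if lesion.organ is not None:
            fu_centre = organ_by_name[lesion.organ].transform_points(fu_centre)
        change = None
        if lesion.baseline_sul and lesion.followup_sul:
            change = 100.0 * (lesion.followup_sul - lesion.baseline_sul) / lesion.baseline_sul
        lesions.append(
            {
                "baseline_centre_mm": list(lesion.centre),
                "followup_centre_mm": [float(c) for c in fu_centre],
                "baseline_sul": lesion.baseline_sul,
                "followup_sul": lesion.followup_sul,
                "percent_change": change,
                "new": lesion.new,
            }
        )
    base_amps = [l.baseline_sul for l in spec.lesions if l.baseline_sul]
    fu_amps = [l.followup_sul for l in spec.lesions if l.followup_sul and not l.new]
    new_present = any(l.new for l in spec.lesions)
    lesions_present = bool(fu_amps) or new_present
    pct = abs_change = None
    if base_amps and fu_amps:
        pct = 100.0 * (max(fu_amps) - max(base_amps)) / max(base_amps)
        abs_change = max(fu_amps) - max(base_amps)
    intended = classify_response(
        ResponseInput(
            lesions_present=lesions_present,
            new_lesions=new_present,
            percent_change=pct,
            absolute_change=abs_change,
        )
    ).response
    return {
        "transforms": {
            name: {
                "model": o.model,
                "matrix": [list(row) for row in o.matrix],
                "translation": list(o.translation),
            }
            for name, o in organ_by_name.items()
        },
        "lesions": lesions,
        "intended_class": intended,
        "new_lesions": new_present,
        "designed_percent_change": pct,
        "designed_absolute_change": abs_change,
    }


def make_calibration_set(
    n_pairs: int,
    seed: int = 0,
    spec_seed_scenario: Scenario = "identity",
    mode: Literal["estimated", "truth", "none"] = "estimated",
    max_translation_mm: float = 8.0,
    noise_sd: float = 0.05,
) -> list[tuple[dict[str, np.ndarray], dict[str, np.ndarray]]]:
    """Phantom pairs rendered as (propagated, actual) organ-mask dicts.

    Feeds :func:`percist.uncertainty.calibrate`.  ``mode`` selects what is
    propagated onto the follow-up grid: the baseline masks moved by the
    *estimated* per-organ alignment (the realistic residual-error
    calibration), by the *truth* transforms, or not moved at all
    (``none``: the raw between-scan organ displacement).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    from .alignment import icp_align, extract_surface

    out = []
    for i in range(n_pairs):
        spec = default_spec(
            seed=seed + i,
            scenario=spec_seed_scenario,
            moving=True,
            max_translation_mm=max_translation_mm,
            noise_sd=noise_sd,
        )
        pair = make_phantom_pair(spec)
        grid = pair.baseline_organs.grid
        pts = _world_coords(grid)
        organ_by_name = {o.name: o for o in spec.organs}
        propagated: dict[str, np.ndarray] = {}
        actual: dict[str, np.ndarray] = {}
        for lab in pair.baseline_organs.present_labels:
            name = pair.baseline_organs.legend[lab]
            base_mask = pair.baseline_organs.mask(lab)
            fu_mask = pair.followup_organs.mask(lab)
            if not fu_mask.any():
                continue
            actual[name] = fu_mask
            if mode == "none":
                propagated[name] = base_mask
                continue
            if mode == "truth":
                organ = organ_by_name[name]
                propagated[name] = _propagate_mask(base_mask, organ, grid, pts)
                continue
            tr = icp_align(
                extract_surface(fu_mask, grid),
                extract_surface(base_mask, grid),
                model=organ_by_name[name].model,  # type: ignore[arg-type]
                organ=name,
                source_centre=grid.centre,
                target_centre=grid.centre,
            )
            # paint the baseline organ on the follow-up grid: each follow-up
            # voxel x looks up the baseline mask at its mapped location T(x);
            # evaluate only around the actual follow-up organ (the residual
            # alignment error is a few voxels at most)
            sl = _bbox_slices(np.argwhere(fu_mask), grid.shape, margin=6)
            sub = pts[sl].reshape(-1, 3)
            vox = grid.world_to_voxel(tr.apply(sub)).T
            prop = np.zeros(grid.shape, dtype=bool)
            sampled = ndimage.map_coordinates(
                base_mask.astype(np.float32), vox, order=0, mode="constant", cval=0.0
            )
            prop[sl] = (sampled > 0.5).reshape(pts[sl].shape[:3])
            propagated[name] = prop
        out.append((propagated, actual))
    return out
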