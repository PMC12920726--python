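"""PERCIST response classification and the end-to-end study workflow.

The four-way response call follows PERCIST 1.0, evaluated in order:

* **CMR** — no confirmed lesions in the follow-up scan;
* **PMR** — no new lesions, no unequivocally progressing lesion, and the
  target SULpeak decreased by at least 30% and at least 0.8 SUL units;
* **PMD** — the target SULpeak increased by more than 30% and at least
  0.8 SUL units, or any lesion progressed unequivocally, or new lesions
  were indicated;
* **SMD** — none of the above.

"At least" is inclusive (>=) and "more than" exclusive (>); the new-lesion
and unequivocal-progression flags are user inputs, mirroring the manual
review step of a clinical workflow.

``run_baseline``/``run_followup`` chain the full pipeline: SUL conversion,
background VOI and threshold, hotspot detection/classification/ranking,
alignment, uncertainty, lesion pairing and the response call, emitting
JSON-serialisable study reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from . import background as bg
from . import hotspots as hs
from . import longitudinal as lg
from .alignment import align_images
from .uncertainty import UncertaintyTable, uncertainty_map
from .volumes import LabelVolume, PatientMeta, ScalarVolume, to_sul

__all__ = [
    "ResponseInput",
    "ResponseResult",
    "classify_response",
    "StudyInputs",
    "run_baseline",
    "run_followup",
]

ResponseClass = Literal["CMR", "PMR", "PMD", "SMD"]

PMR_MIN_DECREASE_PCT = 30.0
PMD_MIN_INCREASE_PCT = 30.0
MIN_ABSOLUTE_CHANGE_SUL = 0.8


@dataclass(frozen=True)
class ResponseInput:
    """Everything the response rules look at.

    ``percent_change`` and ``absolute_change`` are signed (negative =
    decrease) and compare the target SULpeak between baseline and
    follow-up; they may be None only when no lesion exists at one of the
    time points.
    """

    lesions_present: bool
    new_lesions: bool = False
    unequivocal_progression: bool = False
    percent_change: float | None = None
    absolute_change: float | None = None


@dataclass(frozen=True)
class ResponseResult:
    response: ResponseClass
    rule: str
    inputs: ResponseInput


def classify_response(inp: ResponseInput) -> ResponseResult:
    """Apply the PERCIST response rules in order CMR, PMR, PMD, SMD."""
    if not inp.lesions_present:
        return ResponseResult("CMR", "no lesions in the follow-up scan", inp)
    has_change = inp.percent_change is not None and inp.absolute_change is not None
    if (
        has_change
        and not inp.new_lesions
        and not inp.unequivocal_progression
        and inp.percent_change <= -PMR_MIN_DECREASE_PCT
        and inp.absolute_change <= -MIN_ABSOLUTE_CHANGE_SUL
    ):
        return ResponseResult(
            "PMR",
            "target SULpeak decreased by at least 30% and at least 0.8 SUL units, "
            "with no new or unequivocally progressing lesions",
            inp,
        )
    if inp.new_lesions:
        return ResponseResult("PMD", "new lesions were indicated", inp)
    if inp.unequivocal_progression:
        return ResponseResult("PMD", "a lesion increased unequivocally", inp)
    if (
        has_change
        and inp.percent_change > PMD_MIN_INCREASE_PCT
        and inp.absolute_change >= MIN_ABSOLUTE_CHANGE_SUL
    ):
        return ResponseResult(
            "PMD",
            "target SULpeak increased by more than 30% and at least 0.8 SUL units",
            inp,
        )
    if not has_change:
        raise ValueError(
            "lesions are present at follow-up but the target SULpeak change "
            "is missing and no flag resolves the classification"
        )
    return ResponseResult("SMD", "none of the CMR/PMR/PMD conditions held", inp)


@dataclass
class StudyInputs:
    """One PET-CT study: SUL (or activity) volume, label maps, metadata."""

    pet: ScalarVolume
    organs: LabelVolume
    normal_mask: np.ndarray
    meta: PatientMeta | None = None

    def sul(self) -> ScalarVolume:
        if self.pet.kind == "SUL":
            return self.pet
        if self.meta is None:
            raise ValueError("activity input requires patient metadata for SUL conversion")
        return to_sul(self.pet, self.meta)


def _organ_mask(organs: LabelVolume, name: str) -> np.ndarray:
    for lab, lname in organs.legend.items():
        if lname.lower() == name:
            return organs.mask(lab)
    raise ValueError(f"organ {name!r} not found in label legend")


def _analyse_single_study(
    study: StudyInputs,
    background_organ: Literal["liver", "aorta"],
    class_overrides: Mapping[int, str] | None,
) -> dict:
    sul = study.sul()
    if background_organ == "liver":
        voi = bg.place_liver_voi(sul, _organ_mask(study.organs, "liver"))
    else:
        voi = bg.place_aorta_voi(sul, _organ_mask(study.organs, "aorta"))
    stats = bg.background_stats(sul, voi)
    spots = hs.detect_hotspots(sul, stats.threshold)
    hs.classify_hotspots(spots, study.normal_mask, sul.grid.shape)
    if class_overrides:
        for h in spots:
            if h.component_id in class_overrides:
                h.confirmed_class = class_overrides[h.component_id]  # type: ignore[assignment]
    spots = hs.rank_hotspots(spots)
    lesions = [h for h in spots if h.effective_class == "lesion"]
    return {
        "sul": sul,
        "voi": voi,
        "stats": stats,
        "hotspots": spots,
        "lesions": lesions,
    }


def _target_lesions(lesions: list[hs.Hotspot], n: int) -> list[dict]:
    out = []
    for h in lesions[:n]:
        out.append(
            {
                "component_id": h.component_id,
                "rank": h.rank,
                "sul_peak": h.sul_peak,
                "centre_mm": [float(c) for c in h.peak_centre_mm],
            }
        )
    return out


def run_baseline(
    study: StudyInputs,
    background_organ: Literal["liver", "aorta"] = "liver",
    class_overrides: Mapping[int, str] | None = None,
    n_target_lesions: int = 3,
) -> dict:
    """Baseline workflow: SUL, background threshold, ranked hotspots.

    ``class_overrides`` records the manual hotspot confirmation step:
    component id -> 'lesion' | 'physiological'.
    """
    res = _analyse_single_study(study, background_organ, class_overrides)
    lesions = res["lesions"]
    report = {
        "study": "baseline",
        "background": res["stats"].to_dict(),
        "comparability": None,
        "hotspots": hs.hotspot_table(res["hotspots"]).to_dict(orient="records"),
        "target_lesions": _target_lesions(lesions, n_target_lesions),
        "target_sul_peak": lesions[0].sul_peak if lesions else None,
        "class_overrides": dict(class_overrides or {}),
    }
    if study.meta is not None:
        report["patient"] = study.meta.to_dict()
    return report


def run_followup(
    baseline_study: StudyInputs,
    followup_study: StudyInputs,
    baseline_report: dict,
    uncertainty_table: UncertaintyTable,
    flags: Mapping[str, bool] | None = None,
    background_organ: Literal["liver", "aorta"] = "liver",
    class_overrides: Mapping[int, str] | None = None,
    n_target_lesions: int = 3,
    target_mode: Literal["hottest_per_scan", "paired"] = "hottest_per_scan",
    coarse_levels: tuple[int, ...] = (4, 2),
) -> dict:
    """Follow-up workflow: everything in the baseline plus alignment,
    uncertainty-bounded lesion pairing and the PERCIST response call.

    ``flags`` carries the manual review outcome: ``new_lesions`` and
    ``unequivocal_progression``.  A failed background-comparability check
    is reported but does not abort the run.
    """
    flags = dict(flags or {})
    res = _analyse_single_study(followup_study, background_organ, class_overrides)
    fu_sul: ScalarVolume = res["sul"]
    lesions: list[hs.Hotspot] = res["lesions"]

    base_stats = bg.BackgroundStats(**baseline_report["background"])
    comparability = bg.check_comparability(base_stats, res["stats"])

    alignment = align_images(
        followup_study.organs, baseline_study.organs, coarse_levels=coarse_levels
    )
    umap = uncertainty_map(followup_study.organs, uncertainty_table)
    baseline_sul = baseline_study.sul()
    pairs = lg.build_pairs(
        lesions, alignment.field, umap, baseline_sul, baseline_study.normal_mask
    )

    lesions_present = len(lesions) > 0
    pct = abs_change = None
    if lesions_present:
        if target_mode == "hottest_per_scan":
            base_target = baseline_report.get("target_sul_peak")
            fu_target = lesions[0].sul_peak
            if base_target:
                pct = lg.percent_change(base_target, fu_target)
                abs_change = fu_target - base_target
        else:
            top = pairs[0]
            if top.baseline_sul_peak:
                pct = top.percent_change
                abs_change = top.absolute_change
    result = classify_response(
        ResponseInput(
            lesions_present=lesions_present,
            new_lesions=bool(flags.get("new_lesions", False)),
            unequivocal_progression=bool(flags.get("unequivocal_progression", False)),
            percent_change=pct,
            absolute_change=abs_change,
        )
    )
    report = {
        "study": "followup",
        "background": res["stats"].to_dict(),
        "comparability": comparability,
        "hotspots": hs.hotspot_table(res["hotspots"]).to_dict(orient="records"),
        "target_lesions": _target_lesions(lesions, n_target_lesions),
        "target_sul_peak": lesions[0].sul_peak if lesions else None,
        "lesion_pairs": lg.pair_table(pairs).to_dict(orient="records"),
        "alignment": {
            "transforms": {k: v.to_dict() for k, v in alignment.transforms.items()},
            "skipped_organs": alignment.diagnostics.get("skipped_organs", []),
        },
        "flags": flags,
        "class_overrides": dict(class_overrides or {}),
        "response": {
            "class": result.response,
            "rule": result.rule,
            "percent_change": pct,
            "absolute_change": abs_change,
        },
    }
    if followup_study.meta is not None:
        report["patient"] = followup_study.meta.to_dict()
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Write a study report as JSON (numpy scalars coerced)."""

    def _coerce(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_coerce)
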