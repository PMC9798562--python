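"""Screening-cohort orchestration.

Applies the referral/exclusion cascade to an enrolled roster, drives the
per-participant grading chain (eye selection -> quadrant classification ->
iris typing -> HRAC aggregation) and summarises the included cohort by
gender and decade age band.

Exclusion reasons are applied with first-match precedence in the order
poor image quality, low presenting visual acuity, high intraocular
pressure, suspected glaucomatous neuropathy, other retinal abnormality,
prior ocular surgery, so that each excluded participant is counted exactly
once and the accounting is conserved (included + excluded = enrolled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import pandas as pd

from .enums import AGE_BANDS, AngleClass, Eye, Gender, age_band
from .errors import ValidationError
from .geometry import AngleScan, GeometryConfig, classify_quadrant
from .grading import (
    EyeAssessment,
    ShapeThresholds,
    adjudicate,
    aggregate_hrac,
    classify_iris_configuration,
    select_eye,
)

__all__ = [
    "ParticipantRecord",
    "ExclusionReason",
    "ExclusionAccounting",
    "snellen_to_logmar",
    "logmar_to_snellen",
    "exclusion_reason",
    "apply_exclusions",
    "run_screening",
    "ScreeningResult",
    "PVA_CUTOFF",
    "IOP_CUTOFF",
]

#: Referral threshold on presenting visual acuity, as a Snellen fraction
#: (6/12 = 0.5); participants strictly below it in the better eye are excluded.
PVA_CUTOFF = 0.5

#: Referral threshold on intraocular pressure (mmHg), worse eye, inclusive.
IOP_CUTOFF = 24.0


class ExclusionReason(str, Enum):
    """Exclusion categories, in precedence order."""

    POOR_IMAGE = "poor_image"
    LOW_PVA = "low_pva"
    HIGH_IOP = "high_iop"
    GLAUCOMA_SUSPECT = "glaucoma_suspect"
    RETINAL_ABNORMAL = "retinal_abnormal"
    PRIOR_SURGERY = "prior_surgery"


def snellen_to_logmar(fraction: float) -> float:
    """logMAR equivalent of a Snellen fraction (6/12 = 0.5 -> 0.301)."""
    if fraction <= 0:
        raise ValueError("Snellen fraction must be positive")
    return -math.log10(fraction)


def logmar_to_snellen(logmar: float) -> float:
    return 10.0 ** (-logmar)


@dataclass
class ParticipantRecord:
    """One screened participant.

    ``pva_better_eye`` is stored as a Snellen decimal fraction (6/12 = 0.5);
    fundus and surgery findings arrive as upstream boolean flags -- the
    grading of fundus photographs itself happens outside this package.
    ``hrac_label`` carries a known HRAC status when the roster comes from a
    generator or a completed grading run.
    """

    id: str
    age: float
    gender: Gender
    pva_better_eye: float = 1.0
    iop_od: float = 16.0
    iop_os: float = 16.0
    fundus_glaucoma_suspect: bool = False
    fundus_other_abnormal: bool = False
    prior_ocular_surgery: bool = False
    bilateral_poor_image: bool = False
    hrac_label: bool | None = None

    def __post_init__(self) -> None:
        self.gender = Gender(self.gender)
        failures = []
        if self.age < 40:
            failures.append(f"age: {self.age} < 40")
        for name, iop in (("iop_od", self.iop_od), ("iop_os", self.iop_os)):
            if not 5 < iop < 80:
                failures.append(f"{name}: {iop} outside (5, 80) mmHg")
        if self.pva_better_eye <= 0:
            failures.append(f"pva_better_eye: {self.pva_better_eye} not a positive fraction")
        if failures:
            raise ValidationError(failures, reason="invalid-participant")

    @property
    def iop_worse(self) -> float:
        return max(self.iop_od, self.iop_os)


@dataclass
class ExclusionAccounting:
    """Conserved bookkeeping of the exclusion cascade."""

    n_enrolled: int
    counts: dict[ExclusionReason, int]
    n_included: int

    def __post_init__(self) -> None:
        if self.n_enrolled - sum(self.counts.values()) != self.n_included:
            raise ValidationError(
                [
                    f"accounting not conserved: {self.n_enrolled} enrolled, "
                    f"{sum(self.counts.values())} excluded, {self.n_included} included"
                ],
                reason="accounting-mismatch",
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError(["negative exclusion count"], reason="accounting-mismatch")

    def as_dict(self) -> dict:
        return {
            "n_enrolled": self.n_enrolled,
            "excluded": {r.value: self.counts[r] for r in ExclusionReason},
            "n_excluded": sum(self.counts.values()),
            "n_included": self.n_included,
        }

    def flowchart(self) -> str:
        """Plain-text study flow chart."""
        lines = [f"Enrolled: {self.n_enrolled}", "|"]
        labels = {
            ExclusionReason.POOR_IMAGE: "bilateral poor image quality",
            ExclusionReason.LOW_PVA: "PVA < 6/12 in the better-seeing eye",
            ExclusionReason.HIGH_IOP: f"IOP >= {IOP_CUTOFF:.0f} mmHg",
            ExclusionReason.GLAUCOMA_SUSPECT: "suspected glaucomatous neuropathy",
            ExclusionReason.RETINAL_ABNORMAL: "other retinal abnormality",
            ExclusionReason.PRIOR_SURGERY: "previous ophthalmic surgery",
        }
        for reason in ExclusionReason:
            lines.append(f"|-- excluded, {labels[reason]}: {self.counts[reason]}")
        lines += ["|", f"Included in the analysis: {self.n_included}"]
        return "\n".join(lines)


def exclusion_reason(record: ParticipantRecord) -> ExclusionReason | None:
    """First matching exclusion reason in precedence order, or None."""
    if record.bilateral_poor_image:
        return ExclusionReason.POOR_IMAGE
    if record.pva_better_eye < PVA_CUTOFF:
        return ExclusionReason.LOW_PVA
    if record.iop_worse >= IOP_CUTOFF:
        return ExclusionReason.HIGH_IOP
    if record.fundus_glaucoma_suspect:
        return ExclusionReason.GLAUCOMA_SUSPECT
    if record.fundus_other_abnormal:
        return ExclusionReason.RETINAL_ABNORMAL
    if record.prior_ocular_surgery:
        return ExclusionReason.PRIOR_SURGERY
    return None


def apply_exclusions(
    roster: Sequence[ParticipantRecord],
) -> tuple[list[ParticipantRecord], ExclusionAccounting]:
    """Split the enrolled roster into the included cohort and the accounting."""
    counts = {r: 0 for r in ExclusionReason}
    included: list[ParticipantRecord] = []
    for rec in roster:
        reason = exclusion_reason(rec)
        if reason is None:
            included.append(rec)
        else:
            counts[reason] += 1
    return included, ExclusionAccounting(
        n_enrolled=len(roster), counts=counts, n_included=len(included)
    )


# ---------------------------------------------------------------------------
# end-to-end screening


@dataclass
class ScreeningResult:
    accounting: ExclusionAccounting
    results: pd.DataFrame
    summary: dict = field(default_factory=dict)


AnnotationResolver = Mapping[str, Mapping] | Callable[[str], Mapping | None]


def _resolve(annotations: AnnotationResolver, pid: str):
    if callable(annotations):
        return annotations(pid)
    try:
        return annotations[pid]
    except KeyError:
        return None


def _assess_eye(
    scans: Sequence[AngleScan],
    eye: Eye,
    config: GeometryConfig,
    thresholds: ShapeThresholds,
    manual_grades: Mapping | None,
    pid: str,
) -> EyeAssessment:
    assessments = []
    adjudicated = []
    for scan in scans:
        qa = classify_quadrant(scan, config)
        if qa.angle_class != AngleClass.UNGRADABLE:
            try:
                qa.iris_configuration = classify_iris_configuration(scan, thresholds)
            except Exception:
                qa.iris_configuration = None
        key = (pid, eye.value, scan.quadrant.value)
        if manual_grades and key in manual_grades:
            grades = list(manual_grades[key])
            final = adjudicate(*grades)
            adjudicated.append(scan.quadrant.value)
            if final != "unresolved":
                qa.angle_class = AngleClass(final)
        assessments.append(qa)
    assessment = aggregate_hrac(assessments, eye=eye)
    if adjudicated:
        assessment.notes = assessment.notes + tuple(f"adjudicated:{q}" for q in adjudicated)
    return assessment


def run_screening(
    roster: Sequence[ParticipantRecord],
    annotations: AnnotationResolver,
    config: GeometryConfig | None = None,
    thresholds: ShapeThresholds | None = None,
    manual_grades: Mapping | None = None,
) -> ScreeningResult:
    """Run the full screening analysis over an enrolled roster.

    The exclusion cascade is applied first; each included participant's
    annotation set (``{"OD": [4 AngleScans], "OS": [...]}`` via mapping or
    callable) is then graded: the analysis eye is chosen right-eye-first,
    its four quadrants are classified by the preset-angle rule and typed by
    iris configuration, and the eye-level HRAC call is made. Optional
    ``manual_grades`` maps ``(participant_id, eye, quadrant)`` to a
    sequence of 2-3 grader labels adjudicated into the final angle class.

    Participants without a resolvable annotation, or whose both eyes fail
    the two-gradable-quadrant rule, are counted as ungradable in the
    summary but remain in the results table.
    """
    config = config or GeometryConfig()
    thresholds = thresholds or ShapeThresholds()
    included, accounting = apply_exclusions(roster)

    rows = []
    for rec in included:
        row: dict = {
            "participant_id": rec.id,
            "age": rec.age,
            "age_band": age_band(rec.age),
            "gender": rec.gender.value,
            "eye": None,
            "hrac": None,
            "appositional_closure": None,
            "eye_configuration": None,
            "n_gradable": 0,
            "adjudication_path": "",
        }
        ann = _resolve(annotations, rec.id)
        if ann:
            graded: dict[Eye, EyeAssessment] = {}
            for eye in (Eye.OD, Eye.OS):
                scans = ann.get(eye.value)
                if scans:
                    graded[eye] = _assess_eye(
                        scans, eye, config, thresholds, manual_grades, rec.id
                    )
            chosen = select_eye(graded.get(Eye.OD), graded.get(Eye.OS))
            if chosen is not None and chosen in graded:
                ea = graded[chosen]
                row.update(
                    eye=chosen.value,
                    hrac=ea.hrac if ea.hrac_gradable else None,
                    appositional_closure=ea.appositional_closure,
                    eye_configuration=(
                        ea.eye_configuration.value if ea.eye_configuration else None
                    ),
                    n_gradable=ea.n_gradable,
                    adjudication_path=";".join(n for n in ea.notes if n.startswith("adjudicated")),
                )
                for qa in ea.quadrants:
                    q = qa.quadrant.value
                    row[f"class_{q}"] = qa.angle_class.value
                    row[f"config_{q}"] = (
                        qa.iris_configuration.value if qa.iris_configuration else None
                    )
                    row[f"tia750_{q}"] = qa.tia750
                    row[f"aod750_{q}"] = qa.aod750
        rows.append(row)

    results = pd.DataFrame(rows)
    summary = _summarize(results, accounting)
    return ScreeningResult(accounting=accounting, results=results, summary=summary)


def _summarize(results: pd.DataFrame, accounting: ExclusionAccounting) -> dict:
    if results.empty:
        return {"n_included": 0, "n_graded": 0, "n_hrac": 0}
    graded = results[results["hrac"].notna()]
    n_hrac = int(graded["hrac"].sum()) if len(graded) else 0
    strata = {}
    for gender in (Gender.MALE.value, Gender.FEMALE.value):
        for band in AGE_BANDS:
            cell = graded[(graded["gender"] == gender) & (graded["age_band"] == band)]
            strata[(gender, band)] = (int(cell["hrac"].sum()), len(cell))
    config_counts = (
        graded.loc[graded["hrac"] == True, "eye_configuration"].value_counts().to_dict()  # noqa: E712
    )
    return {
        "n_included": len(results),
        "n_graded": len(graded),
        "n_ungradable": int(len(results) - len(graded)),
        "n_hrac": n_hrac,
        "prevalence": n_hrac / len(graded) if len(graded) else math.nan,
        "by_stratum": strata,
        "hrac_configurations": config_counts,
        "accounting": accounting.as_dict(),
    }
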