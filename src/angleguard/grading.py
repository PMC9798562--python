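"""Eye-level grading logic.

Builds on :mod:`angleguard.geometry`: types the iris configuration of each
quadrant from its contour, aggregates four quadrant assessments into the
eye-level high-risk-of-angle-closure (HRAC) call (narrow and/or closed
angles in >= 3 of 4 quadrants), applies the right-eye-first selection rule,
adjudicates between graders, and calibrates the preset angle threshold from
gonioscopy-anchored trabecular-iris angles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points

from .enums import AngleClass, Eye, IrisConfiguration
from .errors import GradingError
from .geometry import (
    AngleScan,
    QuadrantAssessment,
    _as_line,
    _chord_dir,
    _cross2,
    arc_point,
    normalize_scan,
)

__all__ = [
    "ShapeThresholds",
    "EyeAssessment",
    "CalibrationSet",
    "CalibrationResult",
    "UNRESOLVED",
    "classify_iris_configuration",
    "eye_configuration",
    "aggregate_hrac",
    "select_eye",
    "adjudicate",
    "calibrate_threshold",
]

#: Sentinel returned by :func:`adjudicate` for a three-way grader split.
UNRESOLVED = "unresolved"


@dataclass
class ShapeThresholds:
    """Operational cut-offs for the visual iris-shape taxonomy.

    The taxonomy (flat / bowing / bombe / thick peripheral / mixed) is
    defined visually in clinical grading; these thresholds turn it into a
    reproducible rule. ``curvature_cut`` (um) bounds the signed sagittal
    deviation of the anterior surface from its chord (positive toward the
    cornea => bombe, negative => bowing); ``thickness_cut`` (um) bounds the
    anterior-posterior iris thickness measured ``thickness_offset`` um from
    the iris root.
    """

    curvature_cut: float = 80.0
    thickness_cut: float = 600.0
    thickness_offset: float = 750.0

    def __post_init__(self) -> None:
        if min(self.curvature_cut, self.thickness_cut, self.thickness_offset) <= 0:
            raise ValueError("shape thresholds must be positive")


@dataclass
class EyeAssessment:
    """Four quadrant assessments rolled up to one eye.

    ``hrac_gradable`` is False when fewer than 3 quadrants were gradable and
    fewer than 3 qualified as narrow/closed, i.e. the HRAC status genuinely
    could not be decided (distinct from a definite ``hrac = False``).
    """

    eye: Eye
    quadrants: list[QuadrantAssessment]
    n_gradable: int = 0
    hrac: bool = False
    hrac_gradable: bool = True
    appositional_closure: bool = False
    eye_configuration: IrisConfiguration | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_ungradable(self) -> int:
        return len(self.quadrants) - self.n_gradable


@dataclass
class CalibrationSet:
    """Trabecular-iris angles from gonioscopy-anchored quadrants.

    ``tia_values`` are TIA measurements (degrees) taken on scans whose
    quadrant was graded at the reference gonioscopic narrowness level
    (Scheie N3: only the anterior third of the trabecular meshwork visible).
    """

    tia_values: list[float]
    gonioscopy_grade: str = "N3"

    def __post_init__(self) -> None:
        if len(self.tia_values) == 0:
            raise GradingError("empty-calibration", "calibration set is empty")
        vals = np.asarray(self.tia_values, float)
        if np.any(vals <= 0) or np.any(vals >= 90):
            raise ValueError("calibration TIA values must lie in (0, 90) degrees")


@dataclass
class CalibrationResult:
    threshold: int
    mean: float
    sd: float

    @property
    def summary(self) -> str:
        return f"{self.mean:.1f} ± {self.sd:.1f}"


# ---------------------------------------------------------------------------


def _signed_curvature(scan: AngleScan) -> float:
    """Extremal perpendicular deviation of the anterior iris from its chord.

    Positive toward the cornea (bombe), negative away (bowing); the value
    with the largest magnitude is returned so a posteriorly bowed contour
    yields its (negative) sagitta rather than the ~0 deviation at the ends.
    """
    ant = scan.iris_anterior
    p0 = ant[0]
    u = _chord_dir(ant)
    dev = _cross2(np.broadcast_to(u, ant.shape), ant - p0)
    # orient the sign so that positive points toward the cornea
    cornea_side = math.copysign(1.0, float(_cross2(u, scan.cornea_inner.mean(axis=0) - p0)))
    dev = dev * cornea_side
    return float(dev[np.argmax(np.abs(dev))])


def _iris_thickness(scan: AngleScan, offset: float) -> float:
    """Anterior-posterior iris thickness at ``offset`` um from the root.

    Measured perpendicular to the anterior surface: a ray is cast from the
    anterior point at arc length ``offset`` along both local normals and the
    nearest crossing of the posterior surface is taken; when the ray misses,
    falls back to the point-to-polyline distance.
    """
    a = arc_point(scan.iris_anterior, scan.iris_anterior[0], offset)
    line = _as_line(scan.iris_anterior)
    s = line.project(Point(a))
    # tangent over a +/-150 um window: vertex-level trace noise averages out,
    # while the bias on smooth contours stays well below the threshold margins
    eps = min(150.0, line.length / 3)
    p1 = line.interpolate(max(s - eps, 0.0))
    p2 = line.interpolate(min(s + eps, line.length))
    t = np.array([p2.x - p1.x, p2.y - p1.y])
    t = t / np.linalg.norm(t)
    n = np.array([-t[1], t[0]])
    post = _as_line(scan.iris_posterior)
    span = 5000.0
    ray = LineString([a - n * span, a + n * span])
    hit = ray.intersection(post)
    if hit.is_empty:
        return float(Point(a).distance(post))
    q = nearest_points(hit, Point(a))[0]
    return float(np.hypot(q.x - a[0], q.y - a[1]))


def classify_iris_configuration(
    scan: AngleScan, thresholds: ShapeThresholds | None = None
) -> IrisConfiguration:
    """Type the iris contour of one quadrant.

    Base flags: *bombe* when the signed sagittal deviation exceeds
    ``+curvature_cut``; *bowing* below ``-curvature_cut``; *thick
    peripheral* when the iris thickness at ``thickness_offset`` from the
    root exceeds ``thickness_cut``. Two or more base flags give *mixed*
    (e.g. bombe plus thick peripheral iris co-occurring in one quadrant),
    exactly one gives that label, none gives *flat*. A missing posterior
    surface makes thickness untestable: classification proceeds on
    curvature alone with a warning.
    """
    thresholds = thresholds or ShapeThresholds()
    scan = normalize_scan(scan)
    c = _signed_curvature(scan)
    flags = []
    if c > thresholds.curvature_cut:
        flags.append(IrisConfiguration.BOMBE)
    elif c < -thresholds.curvature_cut:
        flags.append(IrisConfiguration.BOWING)
    if scan.iris_posterior is None:
        warnings.warn(
            "iris_posterior missing: thickness untestable, classifying on curvature only",
            stacklevel=2,
        )
    else:
        t = _iris_thickness(scan, thresholds.thickness_offset)
        if t > thresholds.thickness_cut:
            flags.append(IrisConfiguration.THICK_PERIPHERAL)
    if len(flags) >= 2:
        return IrisConfiguration.MIXED
    if len(flags) == 1:
        return flags[0]
    return IrisConfiguration.FLAT


def eye_configuration(
    quadrant_labels: list[IrisConfiguration | None],
) -> IrisConfiguration:
    """Eye-level iris configuration from the per-quadrant labels.

    Ungradable quadrants (``None``) are ignored. Two or more distinct
    configurations anywhere in the eye -- or any quadrant already mixed --
    define a *mixed* configuration; otherwise the unique label is returned.
    """
    labels = [IrisConfiguration(lbl) for lbl in quadrant_labels if lbl is not None]
    if not labels:
        raise GradingError("no-configuration", "no gradable quadrant configuration")
    distinct = set(labels)
    if IrisConfiguration.MIXED in distinct or len(distinct) >= 2:
        return IrisConfiguration.MIXED
    return labels[0]


def aggregate_hrac(
    assessments: list[QuadrantAssessment], eye: Eye = Eye.OD
) -> EyeAssessment:
    """Roll four quadrant assessments up to the eye-level HRAC call.

    *hrac* is True iff >= 3 quadrants are narrow or closed (an absolute
    count: an eye with only 3 gradable quadrants needs all 3 to qualify);
    *appositional_closure* is True iff any quadrant is closed. When fewer
    than 3 quadrants are gradable and fewer than 3 qualify, the eye is
    flagged not gradable for HRAC rather than HRAC-negative.
    """
    qualifying = sum(
        1 for a in assessments if a.angle_class in (AngleClass.NARROW, AngleClass.CLOSED)
    )
    n_gradable = sum(1 for a in assessments if a.angle_class != AngleClass.UNGRADABLE)
    hrac = qualifying >= 3
    hrac_gradable = hrac or n_gradable >= 3
    config: IrisConfiguration | None
    try:
        config = eye_configuration([a.iris_configuration for a in assessments])
    except GradingError:
        config = None
    return EyeAssessment(
        eye=eye,
        quadrants=list(assessments),
        n_gradable=n_gradable,
        hrac=hrac,
        hrac_gradable=hrac_gradable,
        appositional_closure=any(a.angle_class == AngleClass.CLOSED for a in assessments),
        eye_configuration=config,
        notes=() if hrac_gradable else ("ungradable-for-hrac",),
    )


def _n_ungradable(eye_info) -> int:
    if eye_info is None:
        return 4
    if isinstance(eye_info, EyeAssessment):
        return eye_info.n_ungradable
    return int(eye_info)


def select_eye(od, os) -> Eye | None:
    """Choose the analysis eye: right eye first.

    The right eye is analyzed unless two or more of its quadrants are
    unidentifiable, in which case the left eye is used; if both eyes fail
    that rule the participant is ungradable (``None``), mapping to the
    bilateral-poor-quality exclusion. Arguments may be
    :class:`EyeAssessment` objects, ungradable-quadrant counts, or ``None``
    for a missing eye.
    """
    if _n_ungradable(od) <= 1:
        return Eye.OD
    if _n_ungradable(os) <= 1:
        return Eye.OS
    return None


def adjudicate(g1, g2, g3=None):
    """Combine two independent grades, consulting a third on disagreement.

    Agreement between the first two graders is final. On disagreement the
    third grade is required and the majority label wins; a three-way split
    returns :data:`UNRESOLVED` for manual review. Symmetric in (g1, g2).
    """
    if g1 == g2:
        return g1
    if g3 is None:
        raise GradingError("needs-third-grader", f"graders disagree ({g1} vs {g2})")
    if g3 == g1 or g3 == g2:
        return g3
    return UNRESOLVED


def calibrate_threshold(cal: CalibrationSet) -> CalibrationResult:
    """Preset-angle threshold from gonioscopy-anchored TIA measurements.

    Returns the sample mean rounded half-up to the nearest integer degree
    (the screening rule uses a whole-degree preset), alongside the
    unrounded mean and sample standard deviation.
    """
    vals = np.asarray(cal.tia_values, float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return CalibrationResult(threshold=int(math.floor(mean + 0.5)), mean=mean, sd=sd)
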