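"""Planar angle geometry for anterior-segment OCT cross sections.

A graded quadrant is represented by ordered boundary traces in micrometres:
the inner corneoscleral boundary running anteriorly from the iris recess,
and the anterior/posterior iris surfaces running from the iris root toward
the pupil margin, plus two landmarks (scleral spur, iris recess).

The module computes the two standard angle metrics,

* **TIA750** — trabecular-iris angle: apex at the iris recess, one arm
  through the trabecular-meshwork point 750 um (arc length) anterior to the
  scleral spur, the other arm through the iris surface point met by the
  perpendicular dropped from the TM point;
* **AOD750** — angle opening distance: length of that perpendicular segment
  from the TM point to the anterior iris surface;

and applies the preset-angle screening rule: a wedge of ``tia_threshold``
degrees (default 12) is hinged at the recess along the recess->TM-point ray;
a quadrant is *narrow* when any peripheral-iris point falls strictly inside
the wedge, *closed* when iris and cornea are apposed, *open* otherwise.

All distances here are arc lengths along the polylines, interpolated
linearly within segments, which is the standard convention for
spur-referenced AS-OCT metrics and is stable on curved boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points, substring

from .enums import AngleClass, IrisConfiguration, Quadrant
from .errors import GeometryError

__all__ = [
    "AngleScan",
    "GeometryConfig",
    "QuadrantAssessment",
    "arc_point",
    "compute_tia750",
    "compute_aod750",
    "detect_apposition",
    "classify_quadrant",
    "normalize_scan",
    "validate_scan",
]

#: Landmarks must sit within this distance (um) of their reference trace.
LANDMARK_TOL = 50.0

#: Two points closer than this (um) are treated as coincident when testing
#: for a degenerate angle apex.
DEGENERATE_TOL = 1.0

# Strict-inequality guard for the narrow decision: an iris point exactly on
# the far wedge arm (e.g. a synthetic wedge built at the threshold angle)
# must classify as open despite rounding in the trig that built it.
_ANGLE_EPS = 1e-9


@dataclass
class GeometryConfig:
    """Tunable constants of the preset-angle assessment.

    Parameters
    ----------
    tm_offset
        Arc length (um) from the scleral spur to the trabecular-meshwork
        reference point along the inner corneoscleral boundary. Default 750.
    tia_threshold
        Preset wedge angle in degrees separating narrow from open. Default 12.
    apposition_tol
        Iris--cornea separation (um) at or below which the two tissues are
        considered apposed. Default 10, below typical trace noise.
    eval_window
        Arc length (um) from the recess over which the peripheral iris is
        evaluated. Default 1000, covering the TM region with margin.
    apex_guard
        Arc length (um) from the recess excluded from the apposition and
        wedge point tests. The two traces meet anatomically at the recess,
        so distances near the apex approach zero for *every* angle width;
        the guard restricts the contact test to the trabecular-meshwork
        region the screening rule is about. Default 250.
    """

    tm_offset: float = 750.0
    tia_threshold: float = 12.0
    apposition_tol: float = 10.0
    eval_window: float = 1000.0
    apex_guard: float = 250.0

    def __post_init__(self) -> None:
        if self.tm_offset <= 0 or self.apposition_tol <= 0 or self.eval_window <= 0:
            raise ValueError("tm_offset, apposition_tol and eval_window must be positive")
        if not 0 < self.tia_threshold < 90:
            raise ValueError("tia_threshold must lie in (0, 90) degrees")
        if not 0 <= self.apex_guard < self.eval_window:
            raise ValueError("apex_guard must lie in [0, eval_window)")

    def scaled(self, s: float) -> "GeometryConfig":
        """Config with all length parameters multiplied by ``s`` (angles kept)."""
        return replace(
            self,
            tm_offset=self.tm_offset * s,
            apposition_tol=self.apposition_tol * s,
            eval_window=self.eval_window * s,
            apex_guard=self.apex_guard * s,
        )


@dataclass
class AngleScan:
    """Boundary traces and landmarks of one angle quadrant, in micrometres.

    Traces are ordered (N, 2) arrays: ``cornea_inner`` runs from the iris
    recess anteriorly, ``iris_anterior``/``iris_posterior`` run from the
    iris root toward the pupil margin. ``pixel_scale`` converts stored
    coordinates to um (1.0 when already in um). ``iris_posterior`` may be
    absent, in which case iris-thickness-based shape typing degrades to
    curvature only.
    """

    quadrant: Quadrant
    cornea_inner: np.ndarray
    iris_anterior: np.ndarray
    iris_posterior: np.ndarray | None
    scleral_spur: np.ndarray
    iris_recess: np.ndarray
    pixel_scale: float = 1.0
    gradable: bool = True

    def __post_init__(self) -> None:
        self.cornea_inner = np.asarray(self.cornea_inner, dtype=float)
        self.iris_anterior = np.asarray(self.iris_anterior, dtype=float)
        if self.iris_posterior is not None:
            self.iris_posterior = np.asarray(self.iris_posterior, dtype=float)
        self.scleral_spur = np.asarray(self.scleral_spur, dtype=float)
        self.iris_recess = np.asarray(self.iris_recess, dtype=float)
        self.quadrant = Quadrant(self.quadrant)


@dataclass
class QuadrantAssessment:
    """Result of grading one quadrant."""

    quadrant: Quadrant
    tia750: float = math.nan
    aod750: float = math.nan
    angle_class: AngleClass = AngleClass.UNGRADABLE
    iris_configuration: IrisConfiguration | None = None
    metrics_valid: bool = False
    notes: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# trace helpers


def _as_line(trace: np.ndarray) -> LineString:
    return LineString(np.asarray(trace, dtype=float))


def _chord_dir(trace: np.ndarray) -> np.ndarray:
    v = np.asarray(trace[-1], float) - np.asarray(trace[0], float)
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _cross2(a: np.ndarray, b: np.ndarray):
    """z-component of the 2-D cross product (supports broadcasting)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _clip(line: LineString, a: float, b: float) -> LineString:
    """Substring of ``line`` between arc lengths ``a`` and ``b`` (clamped)."""
    b = min(b, line.length)
    if a >= b:
        raise GeometryError(
            "trace-too-short",
            f"trace of length {line.length:.1f} um cannot be clipped to [{a}, {b}] um",
        )
    return substring(line, a, b)


def _line_vertices(line: LineString, step: float = 25.0) -> np.ndarray:
    """Vertices of ``line`` plus a uniform resampling every ``step`` um."""
    verts = np.asarray(line.coords, dtype=float)
    n_extra = max(int(line.length // step), 1)
    extra = [line.interpolate(s) for s in np.linspace(0.0, line.length, n_extra + 1)]
    return np.vstack([verts, [[p.x, p.y] for p in extra]])


# ---------------------------------------------------------------------------
# validation / normalization


def validate_scan(scan: AngleScan) -> list[str]:
    """Check the structural invariants of a scan; return failure messages.

    An empty list means the scan is valid. Checks: trace sizes (>= 3 points),
    strictly increasing arc-length parameterization (no repeated points),
    scleral spur within :data:`LANDMARK_TOL` of the corneal trace, iris
    recess within tolerance of the starting points of both the corneal and
    anterior-iris traces. Coordinates are checked on the um scale.
    """
    failures: list[str] = []
    s = scan.pixel_scale
    trace_ok: dict[str, bool] = {}
    traces = {"cornea_inner": scan.cornea_inner, "iris_anterior": scan.iris_anterior}
    if scan.iris_posterior is not None:
        traces["iris_posterior"] = scan.iris_posterior
    for name, tr in traces.items():
        tr = np.asarray(tr, float)
        trace_ok[name] = False
        if tr.ndim != 2 or tr.shape[1] != 2:
            failures.append(f"{name}: expected an (N, 2) point list")
            continue
        if len(tr) < 3:
            failures.append(f"{name}: needs >= 3 points, got {len(tr)}")
            continue
        seg = np.linalg.norm(np.diff(tr, axis=0), axis=1)
        if np.any(seg <= 0):
            failures.append(f"{name}: arc-length parameterization not strictly increasing")
            continue
        trace_ok[name] = True
    landmarks_ok = True
    for name, pt in (("scleral_spur", scan.scleral_spur), ("iris_recess", scan.iris_recess)):
        if np.asarray(pt, float).shape != (2,):
            failures.append(f"{name}: expected a 2-D point")
            landmarks_ok = False
    if not landmarks_ok:
        return failures
    if trace_ok["cornea_inner"]:
        cornea = _as_line(scan.cornea_inner * s)
        spur = Point(scan.scleral_spur * s)
        if spur.distance(cornea) > LANDMARK_TOL:
            failures.append(
                f"scleral_spur: {spur.distance(cornea):.1f} um off cornea_inner (tol {LANDMARK_TOL})"
            )
    recess = np.asarray(scan.iris_recess, float) * s
    for name in ("cornea_inner", "iris_anterior"):
        if not trace_ok[name]:
            continue
        d = float(np.linalg.norm(recess - np.asarray(traces[name][0], float) * s))
        if d > LANDMARK_TOL:
            failures.append(f"iris_recess: {d:.1f} um from first point of {name} (tol {LANDMARK_TOL})")
    return failures


def normalize_scan(scan: AngleScan) -> AngleScan:
    """Return the scan in um with the cornea on the positive-y side of the iris.

    Applies ``pixel_scale`` and, when the corneal arm lies clockwise of the
    iris arm (mirror-imaged acquisitions), reflects the y axis so that all
    downstream side conventions (wedge rotation toward the iris, bombe
    curvature positive toward the cornea) hold. Idempotent.
    """
    s = scan.pixel_scale
    cornea = scan.cornea_inner * s
    ant = scan.iris_anterior * s
    post = scan.iris_posterior * s if scan.iris_posterior is not None else None
    spur = scan.scleral_spur * s
    recess = scan.iris_recess * s
    if _cross2(_chord_dir(ant), _chord_dir(cornea)) < 0:
        flip = np.array([1.0, -1.0])
        cornea, ant = cornea * flip, ant * flip
        post = post * flip if post is not None else None
        spur, recess = spur * flip, recess * flip
    return AngleScan(
        quadrant=scan.quadrant,
        cornea_inner=cornea,
        iris_anterior=ant,
        iris_posterior=post,
        scleral_spur=spur,
        iris_recess=recess,
        pixel_scale=1.0,
        gradable=scan.gradable,
    )


# ---------------------------------------------------------------------------
# operations


def arc_point(trace: np.ndarray, origin: np.ndarray, distance: float) -> np.ndarray:
    """Point at polyline arc length ``distance`` anterior to ``origin``.

    ``origin`` is first projected onto the trace (it must lie within
    :data:`LANDMARK_TOL` of it); the returned point lies ``distance`` um
    further along the trace in the direction of increasing index, i.e. away
    from the iris recess, with linear interpolation inside segments.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    line = _as_line(trace)
    p = Point(np.asarray(origin, float))
    if p.distance(line) > LANDMARK_TOL:
        raise GeometryError(
            "landmark-off-trace",
            f"origin is {p.distance(line):.1f} um from the trace (tol {LANDMARK_TOL})",
        )
    target = line.project(p) + distance
    if target > line.length + 1e-9:
        raise GeometryError(
            "trace-too-short",
            f"need arc length {target:.1f} um but trace has {line.length:.1f} um",
        )
    q = line.interpolate(min(target, line.length))
    return np.array([q.x, q.y])


def _tm_point(scan: AngleScan, config: GeometryConfig) -> np.ndarray:
    return arc_point(scan.cornea_inner, scan.scleral_spur, config.tm_offset)


def _iris_arm_point(
    scan: AngleScan, apex: np.ndarray, tm: np.ndarray, config: GeometryConfig
) -> tuple[np.ndarray, bool]:
    """Iris-surface point Q defining the second angle arm.

    Q is the intersection of the anterior iris surface (within the
    evaluation window) with the line through the TM point perpendicular to
    the apex->TM ray; when the perpendicular misses the windowed surface,
    falls back to the surface point nearest the TM point. Returns
    ``(Q, intersected)``.
    """
    u = tm - apex
    nu = np.linalg.norm(u)
    if nu < DEGENERATE_TOL:
        raise GeometryError("degenerate-angle", "apex coincides with the TM point")
    u = u / nu
    n = np.array([-u[1], u[0]])
    iris = _clip(_as_line(scan.iris_anterior), 0.0, config.eval_window)
    span = config.tm_offset + config.eval_window + 5000.0
    perp = LineString([tm - n * span, tm + n * span])
    hit = perp.intersection(iris)
    if not hit.is_empty:
        q = nearest_points(hit, Point(tm))[0]
        return np.array([q.x, q.y]), True
    q = iris.interpolate(iris.project(Point(tm)))
    return np.array([q.x, q.y]), False


def compute_tia750(scan: AngleScan, config: GeometryConfig | None = None) -> float:
    """Trabecular-iris angle in degrees (apex at the iris recess).

    The first arm runs from the recess through the TM point ``tm_offset``
    um anterior to the scleral spur; the second through the iris point met
    by the perpendicular from the TM point (nearest iris point when the
    perpendicular misses the evaluation window). Always non-negative.
    """
    config = config or GeometryConfig()
    scan = normalize_scan(scan)
    apex = scan.iris_recess
    tm = _tm_point(scan, config)
    q, _ = _iris_arm_point(scan, apex, tm, config)
    a, b = tm - apex, q - apex
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < DEGENERATE_TOL or nb < DEGENERATE_TOL:
        raise GeometryError("degenerate-angle", "angle apex coincides with an arm point")
    cosang = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def compute_aod750(scan: AngleScan, config: GeometryConfig | None = None) -> float:
    """Angle opening distance (um): perpendicular TM-point-to-iris segment.

    Returns 0 when the iris is apposed to the cornea at the TM point
    (separation at or below ``apposition_tol``). Raises ``aod-undefined``
    when the perpendicular does not meet the iris inside the evaluation
    window; the quadrant remains classifiable by the preset-angle rule.
    """
    config = config or GeometryConfig()
    scan = normalize_scan(scan)
    tm = _tm_point(scan, config)
    iris = _clip(_as_line(scan.iris_anterior), 0.0, config.eval_window)
    if Point(tm).distance(iris) <= config.apposition_tol:
        return 0.0
    q, intersected = _iris_arm_point(scan, scan.iris_recess, tm, config)
    if not intersected:
        raise GeometryError(
            "aod-undefined",
            "perpendicular from the TM point misses the iris inside the evaluation window",
        )
    return float(np.linalg.norm(tm - q))


def detect_apposition(scan: AngleScan, config: GeometryConfig | None = None) -> bool:
    """True when iris and cornea are apposed in the trabecular-meshwork region.

    The minimum distance between the anterior iris surface and the inner
    corneoscleral boundary is taken with both traces restricted to arc
    length within ``[apex_guard, eval_window]`` of the recess, and compared
    with ``apposition_tol``. The guard excludes the anatomical contact of
    the two traces at the recess itself, which would otherwise flag every
    quadrant.
    """
    config = config or GeometryConfig()
    scan = normalize_scan(scan)
    cornea = _clip(_as_line(scan.cornea_inner), config.apex_guard, config.eval_window)
    iris = _clip(_as_line(scan.iris_anterior), config.apex_guard, config.eval_window)
    return cornea.distance(iris) <= config.apposition_tol


def classify_quadrant(scan: AngleScan, config: GeometryConfig | None = None) -> QuadrantAssessment:
    """Grade one quadrant by the preset-angle rule.

    Order of decision: ungradable scans stay ungradable; apposition makes
    the quadrant *closed*; otherwise the preset wedge (``tia_threshold``
    degrees, hinged at the recess on the recess->TM-point arm, opening
    toward the iris) makes the quadrant *narrow* when any windowed iris
    point lies strictly inside it, *open* otherwise. TIA750/AOD750 are
    filled in when computable; any geometry error downgrades the quadrant
    to ungradable with the reason recorded in ``notes``.
    """
    config = config or GeometryConfig()
    if not scan.gradable:
        return QuadrantAssessment(quadrant=scan.quadrant, notes=("marked-ungradable",))
    scan = normalize_scan(scan)
    notes: list[str] = []
    try:
        apposed = detect_apposition(scan, config)
        tm = _tm_point(scan, config)
    except GeometryError as err:
        return QuadrantAssessment(quadrant=scan.quadrant, notes=(err.reason,))

    tia = math.nan
    try:
        tia = compute_tia750(scan, config)
    except GeometryError as err:
        notes.append(f"tia750:{err.reason}")
    aod = math.nan
    try:
        aod = compute_aod750(scan, config)
    except GeometryError as err:
        notes.append(f"aod750:{err.reason}")

    if apposed:
        cls = AngleClass.CLOSED
        if math.isnan(aod):
            aod = 0.0
    else:
        apex = scan.iris_recess
        u = tm - apex
        nu = np.linalg.norm(u)
        if nu < DEGENERATE_TOL:
            return QuadrantAssessment(quadrant=scan.quadrant, notes=("degenerate-angle",))
        u = u / nu
        try:
            window = _clip(_as_line(scan.iris_anterior), config.apex_guard, config.eval_window)
        except GeometryError as err:
            return QuadrantAssessment(quadrant=scan.quadrant, notes=(err.reason,))
        pts = _line_vertices(window)
        w = pts - apex
        # angular coordinate measured from the TM arm toward the iris side
        # (iris below the cornea after normalization => negative signed angle)
        theta = -np.degrees(np.arctan2(_cross2(u, w), w @ u))
        inside = (theta > _ANGLE_EPS) & (theta < config.tia_threshold - _ANGLE_EPS)
        cls = AngleClass.NARROW if bool(np.any(inside)) else AngleClass.OPEN

    return QuadrantAssessment(
        quadrant=scan.quadrant,
        tia750=tia,
        aod750=aod,
        angle_class=cls,
        metrics_valid=math.isfinite(tia) and math.isfinite(aod),
        notes=tuple(notes),
    )
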