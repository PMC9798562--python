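"""Shared fixtures: parametric wedge scans and independent geometric oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from angleguard.enums import Quadrant
from angleguard.geometry import AngleScan


def make_wedge(
    angle_deg: float,
    n: int = 200,
    length: float = 3000.0,
    spur_arc: float = 0.0,
    iris_offset: float = 0.0,
    with_posterior: bool = False,
    thickness: float = 450.0,
) -> AngleScan:
    """Straight-armed wedge: cornea along +x, iris at ``angle_deg`` below it.

    ``spur_arc`` places the scleral spur at that arc length along the cornea
    (0 = at the recess); ``iris_offset`` translates the iris arm
    perpendicular to itself (parallel-offset scans).
    """
    t = np.linspace(0.0, length, n)
    u_c = np.array([1.0, 0.0])
    a = math.radians(angle_deg)
    u_i = np.array([math.cos(a), -math.sin(a)])
    n_i = np.array([-u_i[1], u_i[0]])  # toward the cornea
    anterior = t[:, None] * u_i - iris_offset * n_i
    posterior = anterior - thickness * n_i if with_posterior else None
    return AngleScan(
        quadrant=Quadrant.TEMPORAL,
        cornea_inner=t[:, None] * u_c,
        iris_anterior=anterior,
        iris_posterior=posterior,
        scleral_spur=np.array([spur_arc, 0.0]),
        iris_recess=np.zeros(2),
    )


def circular_arc(p0, p1, sagitta: float, n: int) -> np.ndarray:
    """Circular arc from p0 to p1 bulging ``sagitta`` to the left of p0->p1."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    h = float(sagitta)
    if h == 0:
        return np.linspace(0, 1, n)[:, None] * (p1 - p0) + p0
    chord = p1 - p0
    c = np.linalg.norm(chord)
    u = chord / c
    nvec = np.array([-u[1], u[0]])
    if h < 0:
        nvec, h = -nvec, -h
    radius = (c * c / 4 + h * h) / (2 * h)
    center = (p0 + p1) / 2 - (radius - h) * nvec
    v0 = p0 - center
    v1 = p1 - center
    sweep = 2 * math.asin(min(c / (2 * radius), 1.0))
    sign = math.copysign(1.0, v0[0] * v1[1] - v0[1] * v1[0])
    angles = np.linspace(0.0, sign * sweep, n)
    cos, sin = np.cos(angles), np.sin(angles)
    return center + np.stack([cos * v0[0] - sin * v0[1], sin * v0[0] + cos * v0[1]], axis=1)


def polyline_arclengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Uniform-arc-length resampling (independent of shapely)."""
    s = polyline_arclengths(points)
    si = np.linspace(0.0, s[-1], n)
    return np.stack(
        [np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])], axis=1
    )


def clip_polyline(points: np.ndarray, a: float, b: float, n: int = 4000) -> np.ndarray:
    """Dense samples of a polyline restricted to arc length in [a, b]."""
    s = polyline_arclengths(points)
    si = np.linspace(a, min(b, s[-1]), n)
    return np.stack(
        [np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])], axis=1
    )


def brute_min_distance(trace_a: np.ndarray, trace_b: np.ndarray, n: int = 1500) -> float:
    """Brute-force pairwise minimum distance between two dense resamplings."""
    pa = resample_polyline(trace_a, n)
    pb = resample_polyline(trace_b, n)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return float(d.min())


def oracle_tia(
    iris: np.ndarray,
    apex=(0.0, 0.0),
    tm=None,
    cornea_dir_deg: float = 17.5,
    tm_offset: float = 750.0,
    eval_window: float = 1000.0,
    n_dense: int = 10_000,
) -> float:
    """Dense numeric trabecular-iris-angle oracle (no shapely).

    Samples the iris at ``n_dense`` points (restricted to the evaluation
    window), locates the crossing of the perpendicular through the TM point
    nearest to it by sign-change interpolation (nearest point fallback),
    and returns the apex angle in degrees.
    """
    apex = np.asarray(apex, float)
    u = np.array([math.cos(math.radians(cornea_dir_deg)), math.sin(math.radians(cornea_dir_deg))])
    tm = apex + tm_offset * u if tm is None else np.asarray(tm, float)
    pts = clip_polyline(iris, 0.0, eval_window, n_dense)
    f = (pts - tm) @ u
    crossings = []
    sign_change = np.where(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
    for i in sign_change:
        w = f[i] / (f[i] - f[i + 1])
        crossings.append(pts[i] + w * (pts[i + 1] - pts[i]))
    exact = np.where(f == 0)[0]
    crossings.extend(pts[i] for i in exact)
    if crossings:
        q = min(crossings, key=lambda p: np.linalg.norm(p - tm))
    else:
        q = pts[np.argmin(np.linalg.norm(pts - tm, axis=1))]
    a = tm - apex
    b = q - apex
    cosang = np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1, 1)
    return math.degrees(math.acos(cosang))


@pytest.fixture
def wedge():
    return make_wedge


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
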