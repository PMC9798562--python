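"""Geometry-core tests: arc-length points, TIA750/AOD750, apposition,
preset-angle classification, and their invariance properties."""

import math

import numpy as np
import pytest

from angleguard.enums import AngleClass, Quadrant
from angleguard.errors import GeometryError
from angleguard.geometry import (
    AngleScan,
    GeometryConfig,
    arc_point,
    classify_quadrant,
    compute_aod750,
    compute_tia750,
    detect_apposition,
    normalize_scan,
    validate_scan,
)
from angleguard.synthetic import generate_appositional_scan

from conftest import brute_min_distance, circular_arc, make_wedge, oracle_tia


class TestArcPoint:
    def test_straight_trace(self):
        trace = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0]])
        np.testing.assert_allclose(arc_point(trace, [0, 0], 750.0), [750.0, 0.0])

    def test_right_angle_polyline(self):
        trace = np.array([[0.0, 0.0], [500.0, 0.0], [500.0, 500.0]])
        np.testing.assert_allclose(arc_point(trace, [0, 0], 750.0), [500.0, 250.0])

    def test_quarter_circle_matches_analytic_arc_length(self):
        # circle of radius 1000 centered at (0, 1000), starting at the origin:
        # 750 um of arc corresponds to a central angle of 0.75 rad
        theta = np.linspace(-math.pi / 2, 0.0, 600)
        trace = np.stack([1000 * np.cos(theta), 1000 + 1000 * np.sin(theta)], axis=1)
        expected = np.array(
            [1000 * math.sin(0.75), 1000 - 1000 * math.cos(0.75)]
        )
        got = arc_point(trace, [0, 0], 750.0)
        assert np.linalg.norm(got - expected) < 1.0

    def test_projection_of_off_trace_origin(self):
        trace = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0]])
        got = arc_point(trace, [100.0, 20.0], 750.0)  # 20 um off, within tolerance
        np.testing.assert_allclose(got, [850.0, 0.0])

    def test_errors(self):
        trace = np.array([[0.0, 0.0], [500.0, 0.0], [600.0, 0.0]])
        with pytest.raises(GeometryError, match="trace-too-short"):
            arc_point(trace, [0, 0], 750.0)
        with pytest.raises(GeometryError, match="landmark-off-trace"):
            arc_point(trace, [100.0, 200.0], 100.0)
        with pytest.raises(ValueError):
            arc_point(trace, [0, 0], -5.0)


class TestTia750:
    @pytest.mark.parametrize("angle", [20.0, 12.0, 5.0, 33.7])
    def test_straight_wedge_closed_form(self, angle):
        assert compute_tia750(make_wedge(angle)) == pytest.approx(angle, abs=1e-6)

    def test_spur_away_from_recess_keeps_wedge_angle(self):
        # with straight arms the apex ray through the TM point is the corneal
        # arm itself, wherever the spur sits on it
        assert compute_tia750(make_wedge(17.0, spur_arc=400.0)) == pytest.approx(17.0, abs=1e-6)

    def test_bombe_arc_against_dense_oracle(self):
        # circular-arc anterior surface: root at the recess, chord 3000 um,
        # sagitta +400 um toward the cornea, corneal arm at 35/2 degrees
        half_wedge = 17.5
        u_i = np.array(
            [math.cos(math.radians(half_wedge - 8.0)), math.sin(math.radians(half_wedge - 8.0))]
        )
        iris = circular_arc([0, 0], 3000 * u_i, sagitta=400.0, n=1500)
        t = np.linspace(0, 3000, 800)
        u_c = np.array([math.cos(math.radians(half_wedge)), math.sin(math.radians(half_wedge))])
        scan = AngleScan(
            quadrant=Quadrant.TEMPORAL,
            cornea_inner=t[:, None] * u_c,
            iris_anterior=iris,
            iris_posterior=None,
            scleral_spur=np.zeros(2),
            iris_recess=np.zeros(2),
        )
        expected = oracle_tia(iris, cornea_dir_deg=half_wedge)
        assert compute_tia750(scan) == pytest.approx(expected, abs=0.1)

    def test_degenerate_apex(self):
        scan = make_wedge(10.0)
        scan.iris_recess = np.array([750.0, 0.0])  # apex on the TM point
        with pytest.raises(GeometryError, match="degenerate-angle"):
            compute_tia750(scan)


class TestAod750:
    def test_right_triangle_closed_form(self):
        # spur at the recess, straight arms at 12 degrees: AOD = 750 tan(12)
        got = compute_aod750(make_wedge(12.0))
        assert got == pytest.approx(750 * math.tan(math.radians(12.0)), abs=1e-6)

    def test_appositional_contact_is_zero(self):
        assert compute_aod750(generate_appositional_scan()) == 0.0

    def test_parallel_offset(self):
        got = compute_aod750(make_wedge(0.0, iris_offset=30.0))
        assert got == pytest.approx(30.0, abs=1e-9)

    def test_undefined_outside_window(self):
        # at 45 degrees the perpendicular meets the iris beyond 1000 um of arc
        with pytest.raises(GeometryError, match="aod-undefined"):
            compute_aod750(make_wedge(45.0))
        # but a wider evaluation window recovers it
        wide = GeometryConfig(eval_window=2500.0)
        got = compute_aod750(make_wedge(45.0), wide)
        assert got == pytest.approx(750 * math.tan(math.radians(45.0)), rel=1e-6)


class TestApposition:
    def test_small_offset_within_tolerance(self):
        assert detect_apposition(make_wedge(0.0, iris_offset=5.0)) is True

    def test_wide_wedge(self):
        assert detect_apposition(make_wedge(20.0)) is False

    def test_contact_beyond_window_not_flagged(self):
        # iris dips away then touches the cornea only at arc length ~1200 um
        cornea = np.linspace(0, 3000, 300)[:, None] * np.array([1.0, 0.0])
        xs = np.linspace(0, 600, 60)
        down = np.stack([xs, -xs * math.tan(math.radians(6.0))], axis=1)
        xs2 = np.linspace(610, 1199, 60)
        up = np.stack(
            [xs2, np.interp(xs2, [600, 1200], [down[-1, 1], 0.0])], axis=1
        )
        tail = np.array([[1200.0, 0.0], [2000.0, -200.0], [3000.0, -500.0]])
        iris = np.vstack([down, up, tail])
        scan = AngleScan(
            quadrant=Quadrant.TEMPORAL,
            cornea_inner=cornea,
            iris_anterior=iris,
            iris_posterior=None,
            scleral_spur=np.zeros(2),
            iris_recess=np.zeros(2),
        )
        config = GeometryConfig()
        # brute-force oracle over the guarded window confirms the separation
        from conftest import clip_polyline

        iris_win = clip_polyline(iris, config.apex_guard, config.eval_window)
        cornea_win = clip_polyline(cornea, config.apex_guard, config.eval_window)
        assert brute_min_distance(iris_win, cornea_win) > config.apposition_tol
        assert detect_apposition(scan, config) is False
        # widening the window past the contact point flags it
        assert detect_apposition(scan, GeometryConfig(eval_window=1500.0)) is True


class TestClassifyQuadrant:
    def test_reference_cases(self):
        assert classify_quadrant(make_wedge(20.0)).angle_class == AngleClass.OPEN
        assert classify_quadrant(make_wedge(8.0)).angle_class == AngleClass.NARROW
        assert classify_quadrant(generate_appositional_scan()).angle_class == AngleClass.CLOSED

    def test_threshold_tie_classifies_open(self):
        assert classify_quadrant(make_wedge(12.0)).angle_class == AngleClass.OPEN

    def test_ungradable_passthrough(self):
        scan = make_wedge(20.0)
        scan.gradable = False
        qa = classify_quadrant(scan)
        assert qa.angle_class == AngleClass.UNGRADABLE
        assert not qa.metrics_valid

    def test_geometry_error_downgrades_to_ungradable(self):
        # cornea too short to reach the TM point: quadrant is not classifiable
        scan = make_wedge(20.0, length=400.0)
        qa = classify_quadrant(scan)
        assert qa.angle_class == AngleClass.UNGRADABLE
        assert qa.notes

    def test_metrics_filled(self):
        qa = classify_quadrant(make_wedge(8.0))
        assert qa.tia750 == pytest.approx(8.0, abs=1e-6)
        assert qa.aod750 == pytest.approx(750 * math.tan(math.radians(8.0)), abs=1e-6)
        assert qa.metrics_valid


class TestInvariance:
    def test_rigid_motion(self, rng):
        """TIA/AOD do not change under rotation + translation of all points."""
        config = GeometryConfig()
        for _ in range(25):
            angle = rng.uniform(4.0, 35.0)
            scan = make_wedge(angle)
            tia0 = compute_tia750(scan, config)
            aod0 = compute_aod750(scan, config)
            phi = rng.uniform(0, 2 * math.pi)
            rot = np.array(
                [[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]]
            )
            shift = rng.uniform(-5000, 5000, size=2)
            moved = AngleScan(
                quadrant=scan.quadrant,
                cornea_inner=scan.cornea_inner @ rot.T + shift,
                iris_anterior=scan.iris_anterior @ rot.T + shift,
                iris_posterior=None,
                scleral_spur=rot @ scan.scleral_spur + shift,
                iris_recess=rot @ scan.iris_recess + shift,
            )
            assert compute_tia750(moved, config) == pytest.approx(tia0, abs=1e-6)
            assert compute_aod750(moved, config) == pytest.approx(aod0, abs=1e-6)

    def test_uniform_scaling(self, rng):
        """TIA is scale-invariant and AOD scales linearly when the metric
        offsets (TM offset, window) are scaled with the anatomy."""
        config = GeometryConfig()
        for _ in range(10):
            angle = rng.uniform(4.0, 35.0)
            s = rng.uniform(0.3, 3.0)
            scan = make_wedge(angle)
            scaled = AngleScan(
                quadrant=scan.quadrant,
                cornea_inner=scan.cornea_inner * s,
                iris_anterior=scan.iris_anterior * s,
                iris_posterior=None,
                scleral_spur=scan.scleral_spur * s,
                iris_recess=scan.iris_recess * s,
            )
            assert compute_tia750(scaled, config.scaled(s)) == pytest.approx(
                compute_tia750(scan, config), abs=1e-6
            )
            assert compute_aod750(scaled, config.scaled(s)) == pytest.approx(
                compute_aod750(scan, config) * s, rel=1e-9
            )

    def test_mirror_image_normalization(self):
        """A y-flipped (mirror) acquisition grades identically after ingest."""
        scan = make_wedge(8.0)
        flip = np.array([1.0, -1.0])
        mirrored = AngleScan(
            quadrant=scan.quadrant,
            cornea_inner=scan.cornea_inner * flip,
            iris_anterior=scan.iris_anterior * flip,
            iris_posterior=None,
            scleral_spur=scan.scleral_spur * flip,
            iris_recess=scan.iris_recess * flip,
        )
        assert classify_quadrant(mirrored).angle_class == AngleClass.NARROW
        assert compute_tia750(mirrored) == pytest.approx(8.0, abs=1e-6)

    def test_aod_monotone_in_wedge_angle(self):
        """On the straight-iris family AOD750 strictly increases with angle."""
        config = GeometryConfig(eval_window=4000.0)
        angles = np.linspace(1.0, 59.0, 40)
        aods = [compute_aod750(make_wedge(a, length=6000.0), config) for a in angles]
        assert np.all(np.diff(aods) > 0)

    def test_polyline_converges_to_analytic_circle(self):
        """TIA on a circular-arc iris converges to the dense oracle value."""
        half_wedge = 17.5
        u_i = np.array(
            [math.cos(math.radians(half_wedge - 6.0)), math.sin(math.radians(half_wedge - 6.0))]
        )
        u_c = np.array([math.cos(math.radians(half_wedge)), math.sin(math.radians(half_wedge))])
        dense_iris = circular_arc([0, 0], 3000 * u_i, sagitta=250.0, n=20_000)
        expected = oracle_tia(dense_iris, cornea_dir_deg=half_wedge, n_dense=50_000)
        errors = []
        for n in (50, 200, 1000):
            scan = AngleScan(
                quadrant=Quadrant.TEMPORAL,
                cornea_inner=np.linspace(0, 3000, n)[:, None] * u_c,
                iris_anterior=circular_arc([0, 0], 3000 * u_i, sagitta=250.0, n=n),
                iris_posterior=None,
                scleral_spur=np.zeros(2),
                iris_recess=np.zeros(2),
            )
            errors.append(abs(compute_tia750(scan) - expected))
        assert errors[-1] < 0.1
        assert errors[-1] <= errors[0] + 1e-9


class TestValidation:
    def test_valid_scan_passes(self):
        assert validate_scan(make_wedge(15.0)) == []

    def test_failures_are_reported_per_field(self):
        scan = make_wedge(15.0)
        scan.scleral_spur = np.array([750.0, 400.0])  # far off the cornea
        scan.iris_anterior = scan.iris_anterior[:2]  # too short
        msgs = validate_scan(scan)
        assert any("scleral_spur" in m for m in msgs)
        assert any("iris_anterior" in m for m in msgs)

    def test_pixel_scale_applied(self):
        scan = make_wedge(12.0)
        half = AngleScan(
            quadrant=scan.quadrant,
            cornea_inner=scan.cornea_inner / 2,
            iris_anterior=scan.iris_anterior / 2,
            iris_posterior=None,
            scleral_spur=scan.scleral_spur / 2,
            iris_recess=scan.iris_recess / 2,
            pixel_scale=2.0,
        )
        norm = normalize_scan(half)
        np.testing.assert_allclose(norm.cornea_inner, scan.cornea_inner)
        assert compute_tia750(half) == pytest.approx(12.0, abs=1e-6)
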