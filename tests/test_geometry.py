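import numpy as np
import pytest
from hypothesis import given, strategies as hst
from scipy.optimize import least_squares

from camhip.geometry import (
    Circle,
    DegenerateGeometryError,
    alpha_angle,
    classify_cam,
    departure_point,
    fit_circle,
    measure_hip,
    neck_narrowest,
)
from camhip.shape_io import N_POINTS, FemurOutline, LandmarkScheme


def _outline_from_parts(parts: dict[int, np.ndarray]) -> FemurOutline:
    """Custom outline with given coordinates at given indices; the remaining
    indices are parked on a distant arc so they cannot interfere."""
    pts = np.zeros((N_POINTS, 2))
    ang = np.linspace(0, np.pi, N_POINTS)
    pts[:, 0] = 500 + 50 * np.cos(ang)
    pts[:, 1] = 500 + 50 * np.sin(ang)
    for idx, xy in parts.items():
        pts[idx] = xy
    return FemurOutline(points=pts, side="left")


class TestFitCircle:
    def test_exact_four_point_circle(self):
        c = fit_circle(np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float))
        np.testing.assert_allclose(c.center, [0, 0], atol=1e-12)
        assert c.radius == pytest.approx(1.0, abs=1e-12)
        assert c.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_from_arc_samples(self):
        ang = np.linspace(0.3, 4.0, 14)
        pts = np.column_stack([3 + 5 * np.cos(ang), -2 + 5 * np.sin(ang)])
        c = fit_circle(pts)
        np.testing.assert_allclose(c.center, [3, -2], atol=1e-9)
        assert c.radius == pytest.approx(5.0, abs=1e-9)

    def test_noisy_fit_matches_independent_lsq_oracle(self, rng):
        ang = np.linspace(0.1, 5.5, 14)
        r = 5.0 * (1 + rng.normal(0, 0.05, size=14))
        pts = np.column_stack([3 + r * np.cos(ang), -2 + r * np.sin(ang)])
        mine = fit_circle(pts)

        def resid(p):
            return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

        best = None
        for x0 in ([3, -2, 5], [0, 0, 3], [5, 0, 8], [2, -4, 4]):
            sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
            if best is None or sol.cost < best.cost:
                best = sol
        np.testing.assert_allclose(mine.center, best.x[:2], atol=1e-6)
        assert mine.radius == pytest.approx(best.x[2], abs=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            fit_circle(pts)

    def test_residual_grows_with_noise(self, rng):
        ang = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        rms = []
        for sd in (0.0, 0.05, 0.2):
            r = 5.0 + rng.normal(0, sd, size=30)
            pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
            rms.append(fit_circle(pts).rms_residual)
        assert rms[0] <= rms[1] <= rms[2]


class TestNeckNarrowest:
    def test_parallel_lines(self):
        xa = np.linspace(0, 10, 14)
        xb = np.linspace(0, 10, 13)
        out = _outline_from_parts(
            {
                **{2 + i: np.array([x, 4.0]) for i, x in enumerate(xa)},
                **{37 + i: np.array([x, 0.0]) for i, x in enumerate(xb)},
            }
        )
        mid, width = neck_narrowest(out)
        assert width == pytest.approx(4.0, abs=1e-12)
        assert mid[1] == pytest.approx(2.0, abs=1e-12)

    def test_hourglass_analytic_minimum(self):
        # V-shaped jaws meeting a minimum gap of 3 at x = 5
        xa = np.array([0, 1, 2, 3, 4, 4.5, 5, 5.5, 6, 7, 8, 8.5, 9, 10.0])
        xb = np.array([0, 1, 2, 3, 4, 4.5, 5, 5.5, 6, 7, 8, 9, 10.0])
        out = _outline_from_parts(
            {
                **{2 + i: np.array([x, np.abs(x - 5) + 1.5]) for i, x in enumerate(xa)},
                **{37 + i: np.array([x, -np.abs(x - 5) - 1.5]) for i, x in enumerate(xb)},
            }
        )
        mid, width = neck_narrowest(out, densify=8)
        assert width == pytest.approx(3.0, abs=1e-9)
        assert mid[0] == pytest.approx(5.0, abs=10.0 / 12 / 8)

    def test_width_non_increasing_in_densify(self, make_outline):
        out, _ = make_outline(cam_onset_deg=75.0)
        widths = [neck_narrowest(out, densify=d)[1] for d in (1, 4, 16)]
        assert widths[0] >= widths[1] >= widths[2]


class TestDeparture:
    def test_arc_then_radial_spike(self):
        theta_star = np.radians(70.0)
        circ = Circle(center=np.array([0.0, 0.0]), radius=10.0)
        on = lambda t, r=10.0: np.array([r * np.sin(t), -r * np.cos(t)])
        parts = {i: on(np.radians(a)) for i, a in zip(range(19, 33),
                                                      np.linspace(175, 110, 14))}
        parts.update({33: on(np.radians(95)), 34: on(np.radians(80)),
                      35: on(theta_star), 36: on(theta_star, 13.0)})
        out = _outline_from_parts(parts)
        dep = departure_point(out, circ)
        assert dep is not None
        ang = np.degrees(np.arctan2(dep[0], -dep[1]))
        assert ang == pytest.approx(70.0, abs=1e-9)  # radial spike: exact crossing

    def test_contour_inside_tolerance_gives_no_departure(self):
        circ = Circle(center=np.array([0.0, 0.0]), radius=10.0)
        ang = np.linspace(0, np.pi, 17)
        parts = {i: 9.99 * np.array([np.cos(a), np.sin(a)])
                 for i, a in zip(range(33, 50), ang)}
        pts = np.zeros((N_POINTS, 2))
        pts[:] = 5.0  # everything well inside
        for idx, xy in parts.items():
            pts[idx] = xy
        out = FemurOutline(points=pts, side="left")
        assert departure_point(out, circ) is None


class TestAlphaAngle:
    def test_sixty_degree_construction(self):
        circ = Circle(center=np.array([0.0, 0.0]), radius=5.0)
        dep = 5.0 * np.array([np.sin(np.radians(60)), -np.cos(np.radians(60))])
        assert alpha_angle(circ, np.array([0.0, -10.0]), dep) == pytest.approx(60.0)

    def test_collinear_departure_is_zero(self):
        circ = Circle(center=np.array([0.0, 0.0]), radius=5.0)
        assert alpha_angle(circ, np.array([0.0, -10.0]),
                           np.array([0.0, -5.0])) == pytest.approx(0.0)

    def test_degenerate_point_at_centre(self):
        circ = Circle(center=np.array([1.0, 1.0]), radius=5.0)
        with pytest.raises(DegenerateGeometryError):
            alpha_angle(circ, np.array([1.0, 1.0]), np.array([0.0, 0.0]))

    @given(
        angle=hst.floats(-np.pi, np.pi),
        tx=hst.floats(-50, 50),
        ty=hst.floats(-50, 50),
        scale=hst.floats(0.1, 20),
    )
    def test_invariant_under_similarity_transforms(self, angle, tx, ty, scale):
        circ = Circle(center=np.array([2.0, 1.0]), radius=4.0)
        mid = np.array([2.0, -9.0])
        dep = circ.center + 4.0 * np.array([np.sin(1.1), -np.cos(1.1)])
        base = alpha_angle(circ, mid, dep)
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        T = lambda p: scale * (R @ p) + np.array([tx, ty])
        moved = alpha_angle(
            Circle(center=T(circ.center), radius=scale * 4.0), T(mid), T(dep)
        )
        assert moved == pytest.approx(base, abs=1e-8)


class TestMeasureHip:
    def test_cam_outline_recovered(self, make_outline):
        out, truth = make_outline(cam_onset_deg=75.0, cam_amplitude=3.0, jitter_sd=0.0)
        res = measure_hip(out)
        assert res.alpha_deg == pytest.approx(truth, abs=1.0)
        assert res.cam is True
        assert "no-departure" not in res.qc_flags

    def test_subthreshold_onset_is_not_cam(self, make_outline):
        out, _ = make_outline(cam_onset_deg=45.0)
        assert measure_hip(out).cam is False

    def test_alpha_increases_with_onset_slope_one(self, make_outline):
        onsets = [50.0, 70.0, 90.0]
        alphas = [measure_hip(make_outline(cam_onset_deg=o)[0]).alpha_deg
                  for o in onsets]
        slopes = np.diff(alphas) / np.diff(onsets)
        assert np.all(slopes > 0)
        np.testing.assert_allclose(slopes, 1.0, atol=0.05)

    def test_departure_robust_to_subtolerance_jitter(self, make_outline):
        out, _ = make_outline(cam_onset_deg=75.0, jitter_sd=0.05, seed=7)
        assert measure_hip(out).alpha_deg == pytest.approx(75.0, abs=1.0)


@pytest.mark.parametrize(
    "alpha,expected",
    [(60.0, True), (59.9, False), (53.9, False), (75.0, True)],
)
def test_classify_cam_threshold_inclusive(alpha, expected):
    assert classify_cam(alpha) is expected
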