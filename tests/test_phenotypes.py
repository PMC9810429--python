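"""Phenotype extraction: edges, power-law fits, bending angle, forces,
drag coefficient, lodging resistance, and the per-second time series."""

import numpy as np
import pytest

from lodgesim import phenotypes as ph
from lodgesim import units
from lodgesim.morphotypes import SilhouetteFrame, render_silhouette


def _line_fit(theta_deg):
    return ph.PowerLawFit(c=np.tan(np.radians(theta_deg)), d=1.0)


class TestExtractEdge:
    def test_empty_mask_rejected(self):
        frame = SilhouetteFrame(np.zeros((50, 50)), 1.0, (45, 5), 4.0)
        with pytest.raises(ValueError, match="empty mask"):
            ph.extract_edge(frame)

    def test_two_blobs_rejected(self):
        img = np.zeros((50, 50))
        img[5:15, 5:15] = 1.0
        img[30:40, 30:40] = 1.0
        frame = SilhouetteFrame(img, 1.0, (45, 5), 4.0)
        with pytest.raises(ValueError, match="disconnected: 2 components"):
            ph.extract_edge(frame)

    def test_vertical_stem_edge_constant(self):
        cl = np.column_stack([np.zeros(60), np.linspace(0, 300, 60)])
        frame = render_silhouette(cl, image_size=(260, 200), mm_per_pixel=2.0,
                                  stem_width_mm=8.0)
        prof = ph.extract_edge(frame, correct_stem_width=False)
        # uncorrected windward edge sits half a stem width upwind of the axis
        # (away from the rounded cap at the tip)
        flank = prof.y <= 295.0
        assert np.allclose(prof.x[flank], -4.0, atol=1.0)

    def test_power_law_edge_on_curve(self):
        d, x_top = 0.6, 60.0
        c = 380.0 / x_top**d
        x = np.linspace(0, x_top, 500)
        cl = np.column_stack([x, c * x**d])
        frame = render_silhouette(cl, image_size=(480, 420), mm_per_pixel=1.5,
                                  stem_width_mm=10.0)
        prof = ph.extract_edge(frame)
        # corrected edge points lie on the centerline curve within a pixel
        interp = c * np.clip(prof.x, 0, None) ** d
        mask = prof.x > 1.0
        assert np.percentile(np.abs(prof.y[mask] - interp[mask]), 90) < 1.5


class TestFitPowerLaw:
    def test_exact_on_clean_points(self):
        x = np.linspace(0.1, 100, 200)
        fit = ph.fit_power_law(ph.EdgeProfile(np.column_stack([x, 2 * x**0.5])))
        assert fit.c == pytest.approx(2.0, abs=1e-6)
        assert fit.d == pytest.approx(0.5, abs=1e-6)

    def test_linear_case(self):
        x = np.linspace(0.1, 50, 100)
        fit = ph.fit_power_law(ph.EdgeProfile(np.column_stack([x, x])))
        assert fit.c == pytest.approx(1.0, abs=1e-6)
        assert fit.d == pytest.approx(1.0, abs=1e-6)

    def test_noisy_exponent_recovery(self):
        rng = np.random.default_rng(123)
        x = np.linspace(0.5, 120, 500)
        y = 2 * x**0.5 + rng.normal(0, 0.5, len(x))
        keep = y > 0
        fit = ph.fit_power_law(ph.EdgeProfile(np.column_stack([x[keep], y[keep]])))
        assert fit.d == pytest.approx(0.5, abs=0.02)

    def test_upright_stem_rejected(self):
        pts = np.column_stack([np.zeros(30), np.linspace(0, 300, 30)])
        with pytest.raises(ValueError, match="downstream excursion"):
            ph.fit_power_law(ph.EdgeProfile(pts))

    def test_too_few_points_rejected(self):
        pts = np.array([[1.0, 1.0], [2.0, 1.5], [3.0, 1.9]])
        with pytest.raises(ValueError, match="at least"):
            ph.fit_power_law(ph.EdgeProfile(pts))


class TestBendingAngle:
    def test_straight_line_50_degrees(self):
        assert ph.bending_angle(_line_fit(50.0), 1000.0) == pytest.approx(50.0, abs=1e-6)

    def test_near_vertical_limit(self):
        fit = ph.PowerLawFit(c=1e3, d=1.0)
        assert ph.bending_angle(fit, 1000.0) > 89.9

    def test_dual_method_arc_length_oracle(self):
        # adaptive quadrature vs dense polyline arc length agree within 0.1 deg
        fit = ph.PowerLawFit(c=2.0, d=0.6)
        H = 1000.0
        theta_quad = ph.bending_angle(fit, H)
        x = np.linspace(0, 2000, 400000)
        y = fit(x)
        s = np.concatenate([[0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
        i0 = np.searchsorted(s, H / 2)
        theta_poly = np.degrees(np.arctan2(y[i0], x[i0]))
        assert theta_quad == pytest.approx(theta_poly, abs=0.1)

    def test_short_curve_rejected_with_attained_length(self):
        fit = _line_fit(45.0)
        with pytest.raises(ValueError, match="arc length"):
            ph.bending_angle(fit, 1000.0, x_max=10.0)


class TestFrontalArea:
    def test_vertical_stem_rectangle(self):
        prof = ph.EdgeProfile(np.column_stack([np.zeros(50), np.linspace(0, 800, 50)]))
        assert ph.frontal_area_ub([prof], 100.0) == pytest.approx(8.0e4)

    def test_halving_extent_halves_area(self):
        p1 = ph.EdgeProfile(np.column_stack([np.zeros(50), np.linspace(0, 800, 50)]))
        p2 = ph.EdgeProfile(np.column_stack([np.zeros(50), np.linspace(0, 400, 50)]))
        assert ph.frontal_area_ub([p2], 100.0) == pytest.approx(
            0.5 * ph.frontal_area_ub([p1], 100.0)
        )

    def test_area_upper_bound_never_raises_cd(self):
        # C_d computed with any A' >= A can only decrease
        f_w, v = 5.88e4, 8000.0
        a = 8.0e4
        for factor in (1.0, 1.5, 3.0):
            assert ph.drag_coefficient(f_w, a * factor, v) <= \
                ph.drag_coefficient(f_w, a, v) + 1e-15

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ph.frontal_area_ub([], 100.0)


class TestForceFromLoadcell:
    def test_zero_force(self):
        assert ph.force_from_loadcell(0.0, 50.0, 1000.0) == 0.0

    def test_perpendicular_at_90_degrees(self):
        assert ph.force_from_loadcell(1e6, 90.0, 1000.0) == pytest.approx(1e6)

    def test_linear_in_fs(self):
        a = ph.force_from_loadcell(1e6, 50.0, 1000.0)
        b = ph.force_from_loadcell(3e6, 50.0, 1000.0)
        assert b == pytest.approx(3 * a, rel=1e-12)

    def test_against_numerical_virtual_work(self):
        # discretized deformed stem: equate work of the follower force and the
        # horizontal force over a small rigid rotation about the base
        fit = ph.PowerLawFit(c=2.0, d=0.6)
        H = 1000.0
        f_s = 1e6
        f_w = ph.force_from_loadcell(f_s, 50.0, H, fit=fit)
        x0, y0 = ph.half_length_point(fit, H)
        dphi = 1e-7
        # rotate the half-length point downwind by dphi about the origin
        du = np.array([y0, -x0]) * dphi
        fp = fit.slope(x0)
        n_hat = np.array([fp, -1.0]) / np.hypot(fp, 1.0)  # normal, downwind
        work_follower = f_s * float(n_hat @ du)
        work_horizontal = f_w * du[0]
        assert work_horizontal == pytest.approx(work_follower, rel=1e-6)

    def test_invalid_reference_angle(self):
        with pytest.raises(ValueError, match="theta_ref"):
            ph.force_from_loadcell(1.0, 120.0, 1000.0)


class TestDragCoefficient:
    def test_identity(self):
        v, a = 9000.0, 5.0e4
        f = 0.5 * units.RHO_AIR * a * v**2
        assert ph.drag_coefficient(f, a, v) == pytest.approx(1.0, rel=1e-12)

    def test_hand_value(self):
        # F_w = 0.0588 N, A = 8e4 mm^2, v = 8 m/s -> C_d ~ 0.0187
        assert ph.drag_coefficient(5.88e4, 8.0e4, 8000.0) == pytest.approx(
            0.0187, abs=3e-4
        )

    def test_inverse_proportional_to_area(self):
        c1 = ph.drag_coefficient(1e4, 4e4, 8000.0)
        c2 = ph.drag_coefficient(1e4, 2e4, 8000.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError, match="zero wind"):
            ph.drag_coefficient(1.0, 1.0, 0.0)


class TestLodgingResistance:
    def test_rigid_upright_gives_zero(self):
        # f(x0) = H/2 exactly: no lever arm surrendered
        fit = ph.PowerLawFit(c=1e3, d=1.0)
        v, tag = ph.lodging_resistance(fit, 1000.0)
        assert v == pytest.approx(0.0, abs=1e-3)
        assert tag == "lever-arm-deficit"

    def test_straight_line_at_50_degrees(self):
        v, _ = ph.lodging_resistance(_line_fit(50.0), 1000.0)
        assert v == pytest.approx(1.0 - np.sin(np.radians(50.0)), abs=1e-6)

    def test_unknown_definition_rejected(self):
        with pytest.raises(ValueError, match="unknown CL_r definition"):
            ph.lodging_resistance(_line_fit(50.0), 1000.0, definition="torque-ratio")

    def test_bounded_for_random_profiles(self, rng):
        for _ in range(30):
            d = float(rng.uniform(0.3, 1.2))
            theta = float(rng.uniform(20.0, 85.0))
            x_ref = float(rng.uniform(50.0, 500.0))
            c = x_ref * np.tan(np.radians(theta)) / x_ref**d
            fit = ph.PowerLawFit(c=c, d=d)
            v, _ = ph.lodging_resistance(fit, float(rng.uniform(400.0, 1200.0)))
            assert 0.0 <= v <= 1.0


class TestTimeseries:
    def _frames_for_thetas(self, thetas_deg, H, frame_rate=4):
        frames = []
        for k, th in enumerate(thetas_deg):
            # straight stem at angle th, rendered
            s = np.linspace(0, 0.9 * H, 200)
            cl = np.column_stack([s * np.cos(np.radians(th)),
                                  s * np.sin(np.radians(th))])
            for j in range(frame_rate):
                frames.append(render_silhouette(
                    cl, image_size=(400, 400), mm_per_pixel=3.0,
                    stem_width_mm=9.0, anchor_rc=(380, 30),
                    timestamp=k + j / frame_rate,
                ))
        return frames

    def test_constant_angle_sequence(self):
        H = 900.0
        frames = self._frames_for_thetas([60.0] * 6, H)
        log = np.column_stack([np.arange(6.0), [4, 4, 8, 12, 12, 12]])
        rec = ph.phenotype_timeseries(frames, log, H, 100.0, f_s_un=1e6,
                                      frame_rate=4)
        assert rec.theta_max == pytest.approx(60.0, abs=2.0)
        assert rec.recovery_theta == pytest.approx(0.0, abs=2.0)
        assert not rec.reference_reached  # never bent to 50 deg

    def test_dip_and_recover(self):
        H = 900.0
        thetas = [70, 60, 45, 45, 49, 49]
        frames = self._frames_for_thetas(thetas, H)
        log = np.column_stack([np.arange(6.0), [4, 8, 12, 12, 4, 0]])
        rec = ph.phenotype_timeseries(frames, log, H, 100.0, f_s_un=1e6,
                                      frame_rate=4)
        assert rec.reference_reached
        # plateau at 12 m/s covers the two 45-degree seconds
        assert rec.theta_max == pytest.approx(45.0, abs=2.0)
        assert rec.recovery_theta == pytest.approx(4.0, abs=2.0)
        assert rec.c_d > 0
        assert 0.0 <= rec.cl_r <= 1.0

    def test_misaligned_logs_rejected(self):
        H = 900.0
        frames = self._frames_for_thetas([60.0] * 2, H)
        log = np.column_stack([np.arange(2.0) + 10.0, [4, 8]])
        with pytest.raises(ValueError, match="misaligned"):
            ph.phenotype_timeseries(frames, log, H, 100.0, frame_rate=4)
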