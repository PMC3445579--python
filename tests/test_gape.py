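"""Optimum-gape geometry: tooth-line fitting, the angle construction, and
its invariance properties."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metriomorph import PipelineConfig
from metriomorph.errors import DomainError, GeometryError, ValidationError
from metriomorph.gape import (
    LandmarkSet,
    fit_tooth_line,
    optimum_gape,
    prey_depth_at_length,
)
from metriomorph.synthetic import MandibleSimSpec, gen_mandible


class TestFitToothLine:
    def test_collinear_horizontal(self):
        line = fit_tooth_line(np.array([[0, 2], [5, 2], [10, 2]]))
        np.testing.assert_allclose(np.abs(line.direction), [1, 0], atol=1e-12)
        assert line.perpendicular_distance([3, 2]) == pytest.approx(0, abs=1e-12)
        assert line.rms_residual == pytest.approx(0, abs=1e-12)

    def test_two_point_case(self):
        line = fit_tooth_line(np.array([[0, 0], [10, 0]]))
        assert line.perpendicular_distance([5, 3]) == pytest.approx(3)

    def test_tls_matches_eigendecomposition_oracle(self):
        pts = np.array([[0, 0.1], [5, -0.1], [10, 0.1]])
        line = fit_tooth_line(pts)
        # independent oracle: smallest eigenvalue of the scatter matrix is
        # the sum of squared perpendicular residuals
        centred = pts - pts.mean(axis=0)
        eigvals = np.linalg.eigvalsh(centred.T @ centred)
        expected_rms = math.sqrt(eigvals[0] / len(pts))
        assert line.rms_residual == pytest.approx(expected_rms, abs=1e-12)

    def test_orientation_follows_tip_order(self):
        # anterior first, posterior last: direction points posteriorwards
        line = fit_tooth_line(np.array([[10, 0], [0, 0]]))
        assert line.direction[0] < 0

    def test_coincident_points_degenerate(self):
        with pytest.raises(GeometryError):
            fit_tooth_line(np.array([[1, 1], [1, 1], [1, 1]]))


class TestOptimumGape:
    def test_glenoid_on_tooth_line_gives_zero(self):
        lm = LandmarkSet(
            "flat",
            tooth_tips=np.array([[30, 0], [20, 0], [10, 0]]),
            glenoid=np.array([0, 0]),
            mandible_length_override=40,
        )
        gm = optimum_gape(lm)
        assert gm.gape_angle_deg == pytest.approx(0, abs=1e-12)
        assert gm.prey_depth_cm == pytest.approx(0, abs=1e-12)

    def test_hand_trigonometry_example(self):
        # horizontal tooth row at height 7.04 ending at x=36.21; glenoid at
        # the origin; mandible 88 cm: angle atan(7.04/36.21), fraction 0.08
        lm = LandmarkSet(
            "ms",
            tooth_tips=np.array([[70, 7.04], [50, 7.04], [36.21, 7.04]]),
            glenoid=np.array([0, 0]),
            mandible_length_override=88,
        )
        gm = optimum_gape(lm)
        assert gm.gape_angle_deg == pytest.approx(
            math.degrees(math.atan(7.04 / 36.21))
        )
        cfg = PipelineConfig()
        assert cfg.round_angle(gm.gape_angle_deg) == 11.0
        assert cfg.round_fraction(gm.prey_depth_fraction) == 0.08
        assert gm.prey_depth_cm == pytest.approx(7.04)

    def test_generator_round_trip_noiseless(self):
        spec = MandibleSimSpec(
            true_gape_angle_deg=24,
            posterior_tooth_offset_fraction=0.45,
            mandible_length_cm=132.2,
        )
        lm, truth = gen_mandible(spec)
        gm = optimum_gape(lm)
        assert gm.gape_angle_deg == pytest.approx(24, abs=1e-9)
        assert gm.prey_depth_fraction == pytest.approx(
            0.45 * math.tan(math.radians(24)), abs=1e-9
        )
        assert truth.prey_depth_fraction == pytest.approx(
            gm.prey_depth_fraction, abs=1e-9
        )

    def test_glenoid_anterior_of_posterior_tooth_rejected(self):
        lm = LandmarkSet(
            "bad",
            tooth_tips=np.array([[30, 5], [20, 5]]),
            glenoid=np.array([25, 0]),
            mandible_length_override=40,
        )
        with pytest.raises(GeometryError):
            optimum_gape(lm)

    def test_missing_mandible_length_rejected(self):
        lm = LandmarkSet(
            "nolen",
            tooth_tips=np.array([[30, 5], [20, 5]]),
            glenoid=np.array([0, 0]),
        )
        with pytest.raises(ValidationError):
            optimum_gape(lm)

    def test_metric_internal_consistency(self):
        lm, _ = gen_mandible(MandibleSimSpec(seed=3, landmark_noise_sd=0.01))
        gm = optimum_gape(lm)
        assert gm.prey_depth_fraction == pytest.approx(
            gm.prey_depth_cm / gm.mandible_length_cm, abs=1e-9
        )
        assert gm.standardized_depth_cm == pytest.approx(
            gm.prey_depth_fraction * gm.reference_length_cm, abs=1e-9
        )


class TestInvariances:
    @staticmethod
    def _transformed(lm: LandmarkSet, rotation_deg: float, shift, scale=1.0):
        a = math.radians(rotation_deg)
        R = scale * np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        shift = np.asarray(shift, float)
        return LandmarkSet(
            lm.specimen_id,
            tooth_tips=lm.tooth_tips @ R.T + shift,
            glenoid=R @ lm.glenoid + shift,
            dentary_tip_anterior=R @ lm.dentary_tip_anterior + shift,
            retroarticular_posterior=R @ lm.retroarticular_posterior + shift,
            mandible_length_override=lm.mandible_length_override * scale,
        )

    @settings(max_examples=30, deadline=None)
    @given(
        angle=st.floats(5, 40),
        rot=st.floats(-180, 180),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
    )
    def test_rigid_motion_invariance(self, angle, rot, dx, dy):
        lm, _ = gen_mandible(
            MandibleSimSpec(true_gape_angle_deg=angle, seed=1, landmark_noise_sd=0.01)
        )
        gm = optimum_gape(lm)
        gm2 = optimum_gape(self._transformed(lm, rot, (dx, dy)))
        assert gm2.gape_angle_deg == pytest.approx(gm.gape_angle_deg, abs=1e-9)
        assert gm2.prey_depth_cm == pytest.approx(gm.prey_depth_cm, abs=1e-9)
        assert gm2.prey_depth_fraction == pytest.approx(
            gm.prey_depth_fraction, abs=1e-9
        )

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.01, 100))
    def test_scale_equivariance(self, scale):
        lm, _ = gen_mandible(MandibleSimSpec(seed=2, landmark_noise_sd=0.01))
        gm = optimum_gape(lm)
        gm2 = optimum_gape(self._transformed(lm, 0, (0, 0), scale=scale))
        assert gm2.gape_angle_deg == pytest.approx(gm.gape_angle_deg, rel=1e-9)
        assert gm2.prey_depth_fraction == pytest.approx(
            gm.prey_depth_fraction, rel=1e-9
        )
        assert gm2.prey_depth_cm == pytest.approx(scale * gm.prey_depth_cm, rel=1e-9)

    def test_angle_monotone_in_offset(self):
        angles = []
        for h in (1.0, 2.0, 4.0, 8.0):
            lm = LandmarkSet(
                "mono",
                tooth_tips=np.array([[40, h], [20, h]]),
                glenoid=np.array([0, 0]),
                mandible_length_override=50,
            )
            angles.append(optimum_gape(lm).gape_angle_deg)
        assert all(a < b for a, b in zip(angles, angles[1:]))


class TestPreyDepthAtLength:
    @pytest.mark.parametrize(
        "fraction, length, expected",
        [(0.21, 60, 12.6), (0.15, 87.5, 13.13), (0.0, 100, 0.0)],
    )
    def test_examples(self, fraction, length, expected):
        cfg = PipelineConfig()
        assert cfg.round_depth(prey_depth_at_length(fraction, length)) == expected

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            prey_depth_at_length(-0.1, 60)
        with pytest.raises(DomainError):
            prey_depth_at_length(0.2, 0)
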