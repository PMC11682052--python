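"""Edge physics: friction, minor losses, Bernoulli correction, wall shear."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipsnet.anatomy import BLOOD, VesselSegment
from tipsnet.hydraulics import (
    EdgeLossModel,
    cross_section_area,
    friction_factor,
    frictional_drop,
    minor_loss,
    reynolds,
    segment_drop,
    static_pressure_correction,
    wall_shear,
)

flows = st.floats(1e-8, 5e-4, allow_nan=False)
si_diameters = st.floats(0.002, 0.03, allow_nan=False)


def q_at(v: float, d: float) -> float:
    return v * cross_section_area(d)


class TestArea:
    @pytest.mark.parametrize(
        "d, expected",
        [(2.0 / math.sqrt(math.pi), 1.0), (0.008, 5.0265e-5), (0.01645, 2.1253e-4)],
    )
    def test_values(self, d, expected):
        assert cross_section_area(d) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cross_section_area(0.0)


class TestReynolds:
    def test_shunt_transition_value(self):
        # 1.2 m/s in the 8 mm stent sits at the laminar-turbulent transition.
        assert reynolds(q_at(1.2, 0.008), 0.008) == pytest.approx(2907.4, abs=0.5)

    def test_zero_flow(self):
        assert reynolds(0.0, 0.01) == 0.0

    def test_mpv_is_laminar(self):
        assert reynolds(q_at(0.37, 0.01645), 0.01645) == pytest.approx(1843.3, abs=0.5)


class TestFrictionFactor:
    def test_laminar_formula(self):
        assert friction_factor(64.0) == pytest.approx(1.0)

    def test_blasius_above_threshold(self):
        assert friction_factor(2907.0) == pytest.approx(0.043035, rel=1e-4)

    def test_laminar_side_of_threshold(self):
        assert friction_factor(2300.0) == pytest.approx(64.0 / 2300.0)

    def test_zero_and_negative_rejected(self):
        with pytest.raises(ValueError):
            friction_factor(0.0)
        with pytest.raises(ValueError):
            friction_factor(-1.0)


class TestFrictionalDrop:
    def test_laminar_matches_poiseuille(self):
        q, d, length = 1e-6, 0.01, 0.1
        expected = 128 * BLOOD.dynamic_viscosity * length * q / (math.pi * d**4)
        assert frictional_drop(q, d, length) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(1.4260, rel=1e-4)

    def test_shunt_drop_near_two_mmhg(self):
        drop = frictional_drop(q_at(1.2, 0.008), 0.008, 0.060)
        assert drop == pytest.approx(246.3, rel=1e-3)  # ~1.85 mmHg

    def test_zero_flow(self):
        assert frictional_drop(0.0, 0.008, 0.06) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(q=flows, d=si_diameters, length=st.floats(0.01, 0.2))
    def test_monotone_in_flow_and_length(self, q, d, length):
        assert frictional_drop(1.5 * q, d, length) > frictional_drop(q, d, length) >= 0
        assert frictional_drop(q, d, 1.5 * length) > frictional_drop(q, d, length)

    @settings(derandomize=True, max_examples=100)
    @given(q=flows, d=si_diameters, length=st.floats(0.01, 0.2))
    def test_decreasing_in_diameter(self, q, d, length):
        assert frictional_drop(q, 1.2 * d, length) < frictional_drop(q, d, length)

    def test_odd_in_flow(self):
        q = q_at(1.2, 0.008)
        assert frictional_drop(-q, 0.008, 0.06) == -frictional_drop(q, 0.008, 0.06)


class TestMinorLoss:
    def test_zero_coefficient(self):
        assert minor_loss(1e-4, 0.008, 0.0) == 0.0

    @pytest.mark.parametrize("k, expected", [(0.45, 343.4), (0.25, 190.8)])
    def test_handbook_values_at_shunt_velocity(self, k, expected):
        assert minor_loss(q_at(1.2, 0.008), 0.008, k) == pytest.approx(expected, rel=1e-3)


class TestStaticCorrection:
    def test_equal_diameters(self):
        assert static_pressure_correction(1e-4, 0.01, 0.01) == 0.0

    def test_mpv_to_shunt_contraction(self):
        # Acceleration from the MPV lumen into the 8 mm stent at the
        # solved shunt flow.
        drop = static_pressure_correction(6.087e-5, 0.01645, 0.008)
        assert drop == pytest.approx(733.74, rel=1e-4)

    def test_antisymmetric_under_diameter_swap(self):
        a = static_pressure_correction(5e-5, 0.016, 0.008)
        b = static_pressure_correction(5e-5, 0.008, 0.016)
        assert a == -b


class TestWallShear:
    def test_laminar_value(self):
        assert wall_shear(q_at(0.37, 0.01645), 0.01645) == pytest.approx(0.6298, rel=1e-3)

    def test_turbulent_shunt_value(self):
        assert wall_shear(q_at(1.21, 0.008), 0.008) == pytest.approx(8.33, rel=1e-2)

    def test_zero_flow(self):
        assert wall_shear(0.0, 0.01) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(q=flows, d=si_diameters)
    def test_laminar_friction_form_equals_viscous_form(self, q, d):
        # (f/8) rho V^2 with f = 64/Re is identically 8 mu V / d.
        v = q / cross_section_area(d)
        re = reynolds(q, d)
        f = 64.0 / re
        assert f * BLOOD.density * v * v / 8.0 == pytest.approx(
            8.0 * BLOOD.dynamic_viscosity * v / d, rel=1e-12
        )


class TestSegmentDrop:
    def test_combines_all_terms(self):
        seg = VesselSegment(
            "shunt", 0.008, 0.060, loss_coefficients=(0.45, 0.25),
            upstream_diameter=0.01645,
        )
        q = 6.087e-5
        drop, _ = segment_drop(seg, q)
        expected = (
            frictional_drop(q, 0.008, 0.060)
            + minor_loss(q, 0.008, 0.45)
            + minor_loss(q, 0.008, 0.25)
            + static_pressure_correction(q, 0.01645, 0.008)
        )
        assert drop == pytest.approx(expected, rel=1e-12)

    def test_derivative_matches_finite_difference(self):
        seg = VesselSegment(
            "shunt", 0.008, 0.060, loss_coefficients=(0.7,), upstream_diameter=0.016
        )
        q, h = 6e-5, 1e-11
        _, deriv = segment_drop(seg, q)
        fd = (segment_drop(seg, q + h)[0] - segment_drop(seg, q - h)[0]) / (2 * h)
        assert deriv == pytest.approx(fd, rel=1e-4)

    def test_zero_flow_derivative_is_poiseuille_coefficient(self):
        seg = VesselSegment("v", 0.01, 0.1)
        drop, deriv = segment_drop(seg, 0.0)
        assert drop == 0.0
        assert deriv == pytest.approx(
            128 * BLOOD.dynamic_viscosity * 0.1 / (math.pi * 0.01**4), rel=1e-12
        )

    def test_odd_function_of_flow(self):
        seg = VesselSegment(
            "shunt", 0.008, 0.06, loss_coefficients=(0.7,), upstream_diameter=0.016
        )
        assert segment_drop(seg, -6e-5)[0] == -segment_drop(seg, 6e-5)[0]

    @settings(derandomize=True, max_examples=100)
    @given(q=flows)
    def test_losses_nonnegative_for_forward_flow(self, q):
        seg = VesselSegment(
            "shunt", 0.008, 0.06, loss_coefficients=(0.45, 0.25),
            upstream_diameter=0.016,
        )
        assert segment_drop(seg, q)[0] >= 0

    def test_custom_regime_threshold(self):
        q = q_at(1.2, 0.008)  # Re ~ 2907
        lam = EdgeLossModel(regime_threshold=3000.0)
        drop_lam = frictional_drop(q, 0.008, 0.06, model=lam)
        drop_turb = frictional_drop(q, 0.008, 0.06)
        assert drop_lam != drop_turb
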