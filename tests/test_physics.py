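"""Doppler/flow/geometry conversion contracts and inverse-pair properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopplerflow.physics import (
    DegenerateGeometryError,
    FlowState,
    InvalidGeometryError,
    TransducerConfig,
    VesselGeometry,
    doppler_shift,
    entrance_length,
    flow_from_vmax,
    lumen_area,
    velocity_from_shift,
    vmax_from_flow,
)

CFG = TransducerConfig()  # 20 MHz, 45 deg, 1570 m/s


class TestDopplerShift:
    def test_zero_velocity_gives_zero_shift(self):
        assert doppler_shift(0.0, CFG) == 0.0

    def test_perpendicular_beam_gives_zero_shift(self):
        cfg = TransducerConfig(beam_angle_deg=90.0)
        assert doppler_shift(5.0, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_reference_peak_velocity(self):
        # v_max for the 34.15 mL/min grid point; hand evaluation of
        # 2 * 0.0632 * 20e6 * cos(45 deg) / 1570 = 1138.6 Hz
        assert doppler_shift(6.32, CFG) == pytest.approx(1138.6, abs=0.5)

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            doppler_shift(-1.0, CFG)


class TestVelocityFromShift:
    @pytest.mark.parametrize(
        "shift_hz, expected_cm_s, tol",
        [
            (400.0, 2.2, 0.05),  # device test tone
            (129.0, 0.72, 0.005),  # radio interference line
            (0.0, 0.0, 0.0),
        ],
    )
    def test_reference_inversions(self, shift_hz, expected_cm_s, tol):
        assert velocity_from_shift(shift_hz, CFG) == pytest.approx(
            expected_cm_s, abs=tol + 1e-12
        )

    def test_degenerate_geometry_rejected(self):
        cfg = TransducerConfig(beam_angle_deg=90.0)
        with pytest.raises(DegenerateGeometryError):
            velocity_from_shift(100.0, cfg)


class TestGeometry:
    def test_reference_mock_vessel(self):
        geom = VesselGeometry(outer_diameter_mm=5.33, wall_thickness_mm=0.29)
        assert geom.inner_diameter_mm == pytest.approx(4.75)
        assert lumen_area(geom) == pytest.approx(0.177, abs=0.001)
        assert geom.nominal_lumen_area_cm2 == 0.18

    def test_zero_wall_is_exact_circle(self):
        geom = VesselGeometry(outer_diameter_mm=8.0, wall_thickness_mm=0.0)
        assert lumen_area(geom) == pytest.approx(math.pi * 0.4**2)

    def test_wall_swallowing_lumen_rejected(self):
        with pytest.raises(InvalidGeometryError):
            VesselGeometry(outer_diameter_mm=5.33, wall_thickness_mm=2.7)

    @pytest.mark.parametrize(
        "od_mm, wall_mm, expected_cm",
        [
            (4.7, 0.0, 4.70),  # ten inner diameters for the bench tube
            (10.0, 0.0, 10.0),
            (5.33, 0.29, 4.75),
        ],
    )
    def test_entrance_length(self, od_mm, wall_mm, expected_cm):
        geom = VesselGeometry(outer_diameter_mm=od_mm, wall_thickness_mm=wall_mm)
        assert entrance_length(geom) == pytest.approx(expected_cm)


class TestFlowConversions:
    def test_zero_flow_round_trips(self):
        assert flow_from_vmax(0.0, 0.18) == 0.0
        assert vmax_from_flow(0.0, 0.18) == 0.0

    def test_reference_spatial_average_velocity(self):
        # 34.15 mL/min through 0.18 cm^2 -> v_bar ~ 3.2 cm/s
        v_bar = vmax_from_flow(34.15, 0.18) / 2.0
        assert v_bar == pytest.approx(3.2, abs=0.05)

    def test_peak_velocity_to_flow(self):
        assert flow_from_vmax(6.32, 0.18) == pytest.approx(34.1, abs=0.1)

    def test_linearity_in_flow(self):
        assert vmax_from_flow(17.075, 0.18) == pytest.approx(
            vmax_from_flow(34.15, 0.18) / 2.0
        )

    def test_flow_state_consistency(self):
        st_ = FlowState.from_flow(15.0, 0.18)
        assert st_.spatial_average_velocity_cm_s == st_.peak_velocity_cm_s / 2.0
        assert flow_from_vmax(st_.peak_velocity_cm_s, 0.18) == pytest.approx(15.0)


@given(
    v=st.floats(0.01, 500.0),
    f0=st.floats(1e6, 50e6),
    angle=st.floats(0.0, 89.0),
    c=st.floats(1400.0, 1700.0),
)
@settings(max_examples=200, deadline=None)
def test_doppler_inverse_pair(v, f0, angle, c):
    cfg = TransducerConfig(carrier_frequency=f0, beam_angle_deg=angle, sound_speed=c)
    assert velocity_from_shift(doppler_shift(v, cfg), cfg) == pytest.approx(
        v, rel=1e-9
    )


@given(q=st.floats(0.0, 500.0), a=st.floats(0.01, 5.0))
@settings(max_examples=200, deadline=None)
def test_flow_vmax_inverse_pair(q, a):
    assert flow_from_vmax(vmax_from_flow(q, a), a) == pytest.approx(q, abs=1e-9)


@given(
    v=st.floats(0.01, 100.0),
    scale=st.floats(1.1, 4.0),
    angle=st.floats(0.0, 89.0),
)
@settings(max_examples=100, deadline=None)
def test_doppler_shift_monotone_and_homogeneous(v, scale, angle):
    cfg = TransducerConfig(beam_angle_deg=angle)
    f1 = doppler_shift(v, cfg)
    assert doppler_shift(v * scale, cfg) == pytest.approx(f1 * scale, rel=1e-9)
    steeper = TransducerConfig(beam_angle_deg=min(angle + 1.0, 89.5))
    assert doppler_shift(v, steeper) < f1 or angle >= 89.5
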