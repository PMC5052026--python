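"""Closed-form Doppler, flow, and vessel-geometry conversions.

The continuous-wave Doppler shift for a scatterer moving at velocity ``v``
toward a transmit/receive transducer pair at beam angle ``theta`` is

    f_d = 2 * v * f0 * cos(theta) / c

with carrier frequency ``f0`` and sound speed ``c`` in the medium.  Under
laminar (parabolic) flow with uniform insonation of the lumen the spatial
average velocity is half the peak velocity, ``v_bar = v_max / 2``, and the
volumetric flow rate is ``Q = v_bar * A`` for lumen cross-section ``A``.

All public interfaces use the field's reporting units (Hz, cm/s, mL/min,
cm², mm); computation is carried out in SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TransducerConfig",
    "VesselGeometry",
    "FlowState",
    "DegenerateGeometryError",
    "InvalidGeometryError",
    "doppler_shift",
    "velocity_from_shift",
    "lumen_area",
    "flow_from_vmax",
    "vmax_from_flow",
    "entrance_length",
    "NOMINAL_LUMEN_AREA_CM2",
]

#: Two-decimal lumen area of the reference mock vessel (OD 5.33 mm, wall
#: 0.29 mm).  The exact area is ~0.1772 cm²; device-replication paths carry
#: the rounded 0.18 cm² so that reported flows match the device's convention.
NOMINAL_LUMEN_AREA_CM2 = 0.18


class DegenerateGeometryError(ValueError):
    """Beam perpendicular to flow: no velocity component along the beam."""


class InvalidGeometryError(ValueError):
    """Vessel wall geometry leaves no open lumen."""


@dataclass(frozen=True)
class TransducerConfig:
    """CW Doppler transducer operating point.

    Parameters
    ----------
    carrier_frequency : float
        Ultrasound carrier ``f0`` in Hz.  Default 20 MHz.
    beam_angle_deg : float
        Angle between the beam and the flow axis, degrees in [0, 90]
        (90 is degenerate for inversion).  Default 45.
    sound_speed : float
        Speed of sound ``c`` in the medium, m/s.  Default 1570 (blood /
        blood-mimicking phantom).
    """

    carrier_frequency: float = 20e6
    beam_angle_deg: float = 45.0
    sound_speed: float = 1570.0

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0:
            raise ValueError("carrier_frequency must be positive")
        if not 0.0 <= self.beam_angle_deg <= 90.0:
            raise ValueError("beam_angle_deg must lie in [0, 90]")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")

    @property
    def cos_angle(self) -> float:
        return math.cos(math.radians(self.beam_angle_deg))


@dataclass(frozen=True)
class VesselGeometry:
    """Thin-walled cylindrical vessel (mock vessel or vein).

    Dimensions in millimetres; derived quantities expose both the exact
    lumen area and the two-decimal nominal value used for flow reporting.
    """

    outer_diameter_mm: float = 5.33
    wall_thickness_mm: float = 0.29

    def __post_init__(self) -> None:
        if self.outer_diameter_mm <= 0:
            raise InvalidGeometryError("outer diameter must be positive")
        if self.wall_thickness_mm < 0:
            raise InvalidGeometryError("wall thickness must be non-negative")
        if self.wall_thickness_mm >= self.outer_diameter_mm / 2:
            raise InvalidGeometryError(
                "wall thickness >= outer radius leaves no lumen"
            )

    @property
    def inner_diameter_mm(self) -> float:
        return self.outer_diameter_mm - 2.0 * self.wall_thickness_mm

    @property
    def inner_diameter_cm(self) -> float:
        return self.inner_diameter_mm / 10.0

    @property
    def lumen_area_cm2(self) -> float:
        """Exact lumen cross-section pi*(ID/2)^2 in cm²."""
        r_cm = self.inner_diameter_cm / 2.0
        return math.pi * r_cm * r_cm

    @property
    def nominal_lumen_area_cm2(self) -> float:
        """Lumen area rounded to two decimals (flow-reporting convention)."""
        return round(self.lumen_area_cm2, 2)


def doppler_shift(velocity_cm_s: float, cfg: TransducerConfig | None = None) -> float:
    """Doppler shift in Hz for a scatterer velocity in cm/s.

    Raises
    ------
    ValueError
        If ``velocity_cm_s`` is negative (the receive chain is
        unidirectional; reverse flow is not represented).
    """
    if cfg is None:
        cfg = TransducerConfig()
    if velocity_cm_s < 0:
        raise ValueError("velocity must be non-negative")
    v_m_s = velocity_cm_s / 100.0
    return 2.0 * v_m_s * cfg.carrier_frequency * cfg.cos_angle / cfg.sound_speed


def velocity_from_shift(shift_hz: float, cfg: TransducerConfig | None = None) -> float:
    """Invert the Doppler equation: shift in Hz -> velocity in cm/s."""
    if cfg is None:
        cfg = TransducerConfig()
    if shift_hz < 0:
        raise ValueError("shift must be non-negative")
    if shift_hz == 0:
        return 0.0
    cos_t = cfg.cos_angle
    if cfg.beam_angle_deg >= 90.0 or cos_t <= 0.0:
        raise DegenerateGeometryError(
            "beam perpendicular to flow: nonzero shift has no velocity solution"
        )
    v_m_s = shift_hz * cfg.sound_speed / (2.0 * cfg.carrier_frequency * cos_t)
    return v_m_s * 100.0


def lumen_area(geom: VesselGeometry) -> float:
    """Exact lumen cross-sectional area in cm²."""
    return geom.lumen_area_cm2


def flow_from_vmax(v_max_cm_s: float, area_cm2: float) -> float:
    """Volumetric flow Q in mL/min from peak velocity, laminar profile.

    Q = (v_max/2) * A * 60, with v in cm/s and A in cm².
    """
    if v_max_cm_s < 0:
        raise ValueError("v_max must be non-negative")
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    return (v_max_cm_s / 2.0) * area_cm2 * 60.0


def vmax_from_flow(flow_ml_min: float, area_cm2: float) -> float:
    """Peak velocity in cm/s from volumetric flow, laminar profile.

    v_bar = Q / (60*A); v_max = 2 * v_bar.
    """
    if flow_ml_min < 0:
        raise ValueError("flow must be non-negative")
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    v_bar = flow_ml_min / (60.0 * area_cm2)
    return 2.0 * v_bar


def entrance_length(geom: VesselGeometry) -> float:
    """Straight-tube entrance length (cm) for the parabolic profile to develop.

    Ten inner diameters suffice for ~90% profile development.
    """
    return 10.0 * geom.inner_diameter_cm


@dataclass(frozen=True)
class FlowState:
    """Consistent (Q, v_bar, v_max) triple for a bound lumen area."""

    volumetric_flow_ml_min: float
    spatial_average_velocity_cm_s: float
    peak_velocity_cm_s: float
    area_cm2: float

    @classmethod
    def from_flow(cls, flow_ml_min: float, area_cm2: float) -> "FlowState":
        v_max = vmax_from_flow(flow_ml_min, area_cm2)
        return cls(flow_ml_min, v_max / 2.0, v_max, area_cm2)

    @classmethod
    def from_vmax(cls, v_max_cm_s: float, area_cm2: float) -> "FlowState":
        q = flow_from_vmax(v_max_cm_s, area_cm2)
        return cls(q, v_max_cm_s / 2.0, v_max_cm_s, area_cm2)
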