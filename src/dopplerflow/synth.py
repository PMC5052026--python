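"""Seeded synthetic baseband CW Doppler signal generator.

Emulates two recording conditions of the implanted monitor without any
hardware: (i) a bench flow phantom — a syringe pump driving blood-mimicking
fluid at a constant reference rate through a 0.18 cm² mock vessel — and
(ii) femoral-vein recordings with flow / occlusion / release segments,
ventilator amplitude modulation, a narrowband 129 Hz radio-interference
line, a white receiver-noise floor, and 10-bit ADC quantization.

Signal model
------------
Under uniform insonation of the lumen and laminar unidirectional flow, the
scatterer velocity density across the cross-section is uniform on
[0, v_max].  The baseband record for a segment is therefore synthesised as
a superposition of K random-phase tones whose Doppler frequencies
correspond to velocities spread over [0, v_max] (stratified-uniform draws,
one per equal-width stratum, so the spectral-support edge is within one
stratum width of v_max), with Rayleigh-distributed amplitudes — the
standard random-phasor model for Doppler speckle.  The magnitude spectrum
then occupies approximately [0, f_max] with f_max = doppler_shift(v_max).

The receive chain is homodyne and unidirectional: a single real channel,
no quadrature, no negative shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .physics import TransducerConfig, VesselGeometry, doppler_shift, vmax_from_flow
from .physics import NOMINAL_LUMEN_AREA_CM2

__all__ = [
    "NoiseModel",
    "AcquisitionModel",
    "FlowProfile",
    "SignalRecord",
    "SegmentAnnotation",
    "AliasingError",
    "quantize",
    "generate_segment",
    "generate_protocol",
    "DEFAULT_SIGNAL_RMS_V",
]

#: Doppler signal RMS at the ADC for a flowing segment, volts.  The absolute
#: signal level at the ADC is not fixed by the receive-chain parameters, so
#: it is a free model parameter; the default is set from the noise budget
#: (9.8 mV white floor + 10 mV interference tone -> total sigma ~12.1 mV) so
#: that a flow segment's sample standard deviation is about three times an
#: occlusion segment's under the default NoiseModel.
DEFAULT_SIGNAL_RMS_V = 0.035


class AliasingError(ValueError):
    """Requested flow puts the Doppler band edge at or above Nyquist."""


class InsufficientDataError(ValueError):
    """Record too short for the requested analysis."""


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise sources referred to the ADC input.

    white_noise_rms is the broadband receiver noise floor (input-referred
    0.39 µV scaled by the 88 dB chain gain by default).  The interference
    term is the narrowband line at the radio packet repetition rate
    (7.74 ms period -> ~129 Hz).  The ventilator term amplitude-modulates
    the flow signal (venous return varies with intrathoracic pressure)
    at the ventilator breathing rate.
    """

    white_noise_rms: float = 0.39e-6 * 10 ** (88.0 / 20.0)  # ~9.8 mV
    interference_frequency: float = 129.0
    interference_amplitude: float = 0.010
    ventilator_rate_cpm: float = 11.5
    ventilator_mod_depth: float = 0.3

    def __post_init__(self) -> None:
        if self.white_noise_rms < 0 or self.interference_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0.0 <= self.ventilator_mod_depth <= 1.0:
            raise ValueError("ventilator_mod_depth must lie in [0, 1]")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free configuration (quantization still applies downstream)."""
        return cls(
            white_noise_rms=0.0,
            interference_amplitude=0.0,
            ventilator_mod_depth=0.0,
        )


@dataclass(frozen=True)
class AcquisitionModel:
    """Sampling and quantization of the receive chain.

    adc_range_v is the one-sided rail: the differential ADC spans
    ±adc_range_v (2.5 V span with the 1.25 V internal reference).
    """

    sample_rate: float = 16400.0
    adc_bits: int = 10
    adc_range_v: float = 1.25
    receiver_gain_db: float = 88.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.adc_bits < 2:
            raise ValueError("adc_bits must be at least 2")

    @property
    def lsb_v(self) -> float:
        """Quantization step: full span / 2^bits (2.441 mV at defaults)."""
        return 2.0 * self.adc_range_v / (2**self.adc_bits)


@dataclass(frozen=True)
class SegmentAnnotation:
    label: str
    start_s: float
    end_s: float


@dataclass(frozen=True)
class FlowProfile:
    """Ordered (label, duration, flow) segments plus the vessel geometry.

    Labels follow the monitoring protocol: 'flow', 'occlusion', 'release';
    occlusion segments carry (near-)zero flow.
    """

    segments: tuple[tuple[str, float, float], ...]
    geometry: VesselGeometry = field(default_factory=VesselGeometry)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile must contain at least one segment")
        for label, duration, flow in self.segments:
            if duration <= 0:
                raise ValueError(f"segment {label!r}: duration must be positive")
            if flow < 0:
                raise ValueError(f"segment {label!r}: flow must be non-negative")

    @classmethod
    def protocol(
        cls,
        flow_ml_min: float = 20.0,
        release_ml_min: float | None = None,
        segment_duration_s: float = 60.0,
        geometry: VesselGeometry | None = None,
    ) -> "FlowProfile":
        """The standard flow -> occlusion -> release monitoring pattern."""
        release = flow_ml_min * 0.9 if release_ml_min is None else release_ml_min
        return cls(
            segments=(
                ("flow", segment_duration_s, flow_ml_min),
                ("occlusion", segment_duration_s, 0.0),
                ("release", segment_duration_s, release),
            ),
            geometry=geometry or VesselGeometry(),
        )


@dataclass(frozen=True)
class SignalRecord:
    """A sampled baseband Doppler waveform plus acquisition metadata.

    samples are volts at the ADC (already quantized when produced by the
    generator); provenance snapshots the generating configuration and seed.
    """

    samples: np.ndarray
    sample_rate: float
    provenance: dict = field(default_factory=dict)
    annotations: tuple[SegmentAnnotation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def segment(self, annotation: SegmentAnnotation) -> "SignalRecord":
        """Extract one annotated segment as a standalone record."""
        i0 = int(round(annotation.start_s * self.sample_rate))
        i1 = int(round(annotation.end_s * self.sample_rate))
        return SignalRecord(
            samples=self.samples[i0:i1],
            sample_rate=self.sample_rate,
            provenance={**self.provenance, "segment": annotation.label},
        )

    def segments(self) -> list[tuple[SegmentAnnotation, "SignalRecord"]]:
        return [(a, self.segment(a)) for a in self.annotations]


def quantize(samples: np.ndarray, acq: AcquisitionModel) -> np.ndarray:
    """Mid-tread quantization to the ADC grid, clipped at the rails."""
    lsb = acq.lsb_v
    q = np.round(np.asarray(samples, dtype=np.float64) / lsb) * lsb
    return np.clip(q, -acq.adc_range_v, acq.adc_range_v)


def _scatterer_band(
    v_max_cm_s: float,
    n_scatterers: int,
    cfg: TransducerConfig,
    rng: np.random.Generator,
    times: np.ndarray,
    stratified: bool = True,
) -> np.ndarray:
    """Random-phasor tone superposition over the Doppler band [0, f_max].

    Velocities are stratified-uniform on [0, v_max] (one draw per stratum)
    so the realised band edge is within v_max/K of the nominal edge;
    amplitudes Rayleigh, phases uniform.  Returned with unit RMS.
    """
    k = n_scatterers
    u = rng.uniform(size=k)
    if stratified:
        velocities = (np.arange(k) + u) / k * v_max_cm_s
    else:
        velocities = u * v_max_cm_s
    freqs = np.array([doppler_shift(v, cfg) for v in velocities])
    amps = rng.rayleigh(scale=1.0, size=k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    # sum of k tones; built in blocks to bound memory for long records
    out = np.zeros_like(times)
    block = 64
    for i in range(0, k, block):
        f = freqs[i : i + block, None]
        a = amps[i : i + block, None]
        p = phases[i : i + block, None]
        out += (a * np.sin(2.0 * np.pi * f * times[None, :] + p)).sum(axis=0)
    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out /= rms
    return out


def generate_segment(
    flow_ml_min: float,
    duration_s: float,
    geometry: VesselGeometry | None = None,
    cfg: TransducerConfig | None = None,
    noise: NoiseModel | None = None,
    acq: AcquisitionModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    signal_rms_v: float = DEFAULT_SIGNAL_RMS_V,
    n_scatterers: int = 128,
    area_cm2: float | None = None,
    label: str | None = None,
    stratified: bool = True,
) -> SignalRecord:
    """Generate one constant-flow baseband segment.

    The record is the Doppler tone superposition scaled to
    ``signal_rms_v`` (zero when the flow is zero), amplitude-modulated by
    the ventilator term, plus the interference tone and white noise, then
    quantized by the acquisition model.

    Raises
    ------
    AliasingError
        If the Doppler band edge f_max reaches Nyquist.
    """
    if flow_ml_min < 0:
        raise ValueError("flow must be non-negative")
    geometry = geometry or VesselGeometry()
    cfg = cfg or TransducerConfig()
    noise = noise or NoiseModel()
    acq = acq or AcquisitionModel()
    area = NOMINAL_LUMEN_AREA_CM2 if area_cm2 is None else area_cm2

    v_max = vmax_from_flow(flow_ml_min, area)
    f_max = doppler_shift(v_max, cfg)
    if f_max >= acq.sample_rate / 2.0:
        raise AliasingError(
            f"Doppler band edge {f_max:.0f} Hz >= Nyquist "
            f"{acq.sample_rate / 2.0:.0f} Hz"
        )

    seed_seq = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(seed_seq)

    n = int(round(duration_s * acq.sample_rate))
    t = np.arange(n) / acq.sample_rate

    if flow_ml_min > 0 and signal_rms_v > 0:
        signal = signal_rms_v * _scatterer_band(
            v_max, n_scatterers, cfg, rng, t, stratified=stratified
        )
    else:
        signal = np.zeros(n)

    if noise.ventilator_mod_depth > 0:
        vent_phase = rng.uniform(0.0, 2.0 * np.pi)
        rate_hz = noise.ventilator_rate_cpm / 60.0
        signal = signal * (
            1.0
            + noise.ventilator_mod_depth * np.sin(2.0 * np.pi * rate_hz * t + vent_phase)
        )

    x = signal
    if noise.interference_amplitude > 0:
        x = x + noise.interference_amplitude * np.sin(
            2.0 * np.pi * noise.interference_frequency * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.white_noise_rms > 0:
        x = x + rng.normal(0.0, noise.white_noise_rms, size=n)

    samples = quantize(x, acq)
    provenance = {
        "seed": seed_seq.entropy,
        "flow_ml_min": flow_ml_min,
        "duration_s": duration_s,
        "area_cm2": area,
        "signal_rms_v": signal_rms_v,
        "n_scatterers": n_scatterers,
        "sample_rate": acq.sample_rate,
        "noise": {
            "white_noise_rms": noise.white_noise_rms,
            "interference_frequency": noise.interference_frequency,
            "interference_amplitude": noise.interference_amplitude,
            "ventilator_rate_cpm": noise.ventilator_rate_cpm,
            "ventilator_mod_depth": noise.ventilator_mod_depth,
        },
    }
    annotations = ()
    if label is not None:
        annotations = (SegmentAnnotation(label, 0.0, n / acq.sample_rate),)
    return SignalRecord(samples, acq.sample_rate, provenance, annotations)


def generate_protocol(
    profile: FlowProfile,
    cfg: TransducerConfig | None = None,
    noise: NoiseModel | None = None,
    acq: AcquisitionModel | None = None,
    seed: int = 0,
    **segment_kwargs,
) -> SignalRecord:
    """Concatenate seeded segments for a full monitoring protocol.

    Child seeds are spawned deterministically from ``seed``; annotations
    tile the record at the cumulative segment boundaries.
    """
    acq = acq or AcquisitionModel()
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(profile.segments))

    chunks: list[np.ndarray] = []
    annotations: list[SegmentAnnotation] = []
    t0 = 0.0
    for (label, duration, flow), child in zip(profile.segments, children):
        rec = generate_segment(
            flow,
            duration,
            geometry=profile.geometry,
            cfg=cfg,
            noise=noise,
            acq=acq,
            seed=child,
            **segment_kwargs,
        )
        chunks.append(rec.samples)
        annotations.append(SegmentAnnotation(label, t0, t0 + rec.duration_s))
        t0 += rec.duration_s

    samples = np.concatenate(chunks)
    provenance = {
        "seed": seed,
        "profile": [list(s) for s in profile.segments],
        "sample_rate": acq.sample_rate,
    }
    return SignalRecord(samples, acq.sample_rate, provenance, tuple(annotations))
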