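"""Signal interchange (WAV/CSV), annotations, and the flat config schema.

WAV is the interchange format for baseband Doppler records (the signal is
audible-band); 16-bit PCM with full scale mapped to ±adc_range volts, the
mapping recorded in a JSON sidecar so the WAV itself stays standard.  CSV
(`time_s,volts`) is provided for inspectability.  Segment annotations ride
in a sidecar CSV (`label,start_s,end_s`).

Configuration is a flat namespaced key-value document (YAML mapping);
unknown keys are rejected and every default named by the other modules is
overridable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .budget import PowerConfig, RadioConfig, SarConfig
from .estimator import StftParams
from .physics import TransducerConfig, VesselGeometry
from .synth import AcquisitionModel, NoiseModel, SegmentAnnotation, SignalRecord

__all__ = [
    "SignalFormatError",
    "UnknownConfigKeyError",
    "read_signal",
    "write_signal",
    "load_config",
    "merged_config",
    "DEFAULT_CONFIG",
]


class SignalFormatError(ValueError):
    """Malformed signal file."""


class UnknownConfigKeyError(KeyError):
    """Config document contains a key outside the schema."""


_FULL_SCALE_DEFAULT_V = 1.25  # matches the ADC rail


def _sidecar_meta(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _sidecar_annotations(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".annotations.csv")


def write_signal(record: SignalRecord, path: str | Path, fmt: str | None = None) -> Path:
    """Write a record to WAV (16-bit PCM) or CSV, with sidecars.

    The volts-to-full-scale mapping and provenance go to
    ``<path>.meta.json``; annotations, if present, to
    ``<path>.annotations.csv``.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "wav":
        full_scale = _FULL_SCALE_DEFAULT_V
        scaled = np.clip(record.samples / full_scale, -1.0, 1.0)
        pcm = np.round(scaled * 32767.0).astype(np.int16)
        wavfile.write(path, int(round(record.sample_rate)), pcm)
        meta = {
            "full_scale_volts": full_scale,
            "sample_rate": record.sample_rate,
            "provenance": _jsonable(record.provenance),
        }
        _sidecar_meta(path).write_text(json.dumps(meta, indent=2))
    elif fmt == "csv":
        df = pd.DataFrame({"time_s": record.times, "volts": record.samples})
        df.to_csv(path, index=False)
    else:
        raise SignalFormatError(f"unsupported signal format {fmt!r}")
    if record.annotations:
        pd.DataFrame(
            [
                {"label": a.label, "start_s": a.start_s, "end_s": a.end_s}
                for a in record.annotations
            ]
        ).to_csv(_sidecar_annotations(path), index=False)
    return path


def read_signal(path: str | Path, fmt: str | None = None) -> SignalRecord:
    """Read a WAV or CSV record, picking up sidecar metadata/annotations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    provenance: dict = {}
    if fmt == "wav":
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise SignalFormatError("expected a single-channel WAV")
        full_scale = _FULL_SCALE_DEFAULT_V
        meta_path = _sidecar_meta(path)
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            full_scale = float(meta.get("full_scale_volts", full_scale))
            provenance = meta.get("provenance", {})
        if data.dtype == np.int16:
            samples = data.astype(np.float64) / 32767.0 * full_scale
        else:
            samples = data.astype(np.float64) * full_scale
        sample_rate = float(rate)
    elif fmt == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            raise SignalFormatError(f"cannot parse {path}: {exc}") from exc
        for col in ("time_s", "volts"):
            if col not in df.columns:
                raise SignalFormatError(f"CSV missing required column {col!r}")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise SignalFormatError("CSV must contain at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise SignalFormatError(f"non-monotone time axis at row {bad + 1}")
        sample_rate = 1.0 / float(np.median(dt))
        samples = df["volts"].to_numpy(dtype=float)
    else:
        raise SignalFormatError(f"unsupported signal format {fmt!r}")

    annotations: tuple[SegmentAnnotation, ...] = ()
    ann_path = _sidecar_annotations(path)
    if ann_path.exists():
        adf = pd.read_csv(ann_path)
        annotations = tuple(
            SegmentAnnotation(str(r.label), float(r.start_s), float(r.end_s))
            for r in adf.itertuples()
        )
    return SignalRecord(samples, sample_rate, provenance, annotations)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# --- flat config schema ----------------------------------------------------

DEFAULT_CONFIG: dict[str, float | int | str] = {
    "physics.carrier_frequency": 20e6,
    "physics.beam_angle_deg": 45.0,
    "physics.sound_speed": 1570.0,
    "geometry.outer_diameter_mm": 5.33,
    "geometry.wall_thickness_mm": 0.29,
    "geometry.area_cm2": 0.18,
    "synth.sample_rate": 16400.0,
    "synth.adc_bits": 10,
    "synth.adc_range_v": 1.25,
    "synth.receiver_gain_db": 88.0,
    "synth.signal_rms_v": 0.035,
    "synth.n_scatterers": 128,
    "synth.white_noise_rms": 0.39e-6 * 10 ** (88.0 / 20.0),
    "synth.interference_frequency": 129.0,
    "synth.interference_amplitude": 0.010,
    "synth.ventilator_rate_cpm": 11.5,
    "synth.ventilator_mod_depth": 0.3,
    "estimator.frame_length": 2048,
    "estimator.hop": 256,
    "estimator.window": "hann",
    "estimator.zero_padding": 2,
    "estimator.k": 6.0,
    "estimator.edge_correction_bins": 1.0,
    "estimator.dynamic_range_db": 35.0,
    "estimator.filter_window": 9,
    "features.margin": 0.10,
    "budget.tx_power_dbm": 10.0,
    "budget.receiver_sensitivity_dbm": -86.0,
    "budget.carrier_hz": 915e6,
    "budget.distance_m": 1.0,
    "budget.fat_path_cm": 0.0,
    "budget.muscle_path_cm": 0.0,
    "budget.sar_per_watt": 468.2,
    "budget.sar_limit": 1.6,
    "budget.packet_on_ms": 5.02,
    "budget.packet_period_ms": 7.74,
    "budget.tx_power_delivered_mw": 10.0,
    "budget.averaging_window_min": 6.0,
    "budget.battery_capacity_mah": 400.0,
    "budget.active_current_ma": 120.0,
    "budget.adc_bits": 10,
    "budget.adc_span_v": 2.5,
    "calibration.replicates": 3,
    "calibration.duration_s": 10.0,
    "calibration.pump_tolerance": 0.01,
}


def load_config(path: str | Path) -> dict:
    """Load a flat YAML config; unknown keys are rejected."""
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise SignalFormatError("config must be a flat key-value mapping")
    unknown = set(doc) - set(DEFAULT_CONFIG)
    if unknown:
        raise UnknownConfigKeyError(
            f"unknown config keys: {sorted(unknown)}"
        )
    return dict(doc)


def merged_config(overrides: dict | None = None) -> dict:
    """Defaults overlaid with validated overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if overrides:
        unknown = set(overrides) - set(DEFAULT_CONFIG)
        if unknown:
            raise UnknownConfigKeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(overrides)
    return cfg


def build_transducer(cfg: dict) -> TransducerConfig:
    return TransducerConfig(
        carrier_frequency=cfg["physics.carrier_frequency"],
        beam_angle_deg=cfg["physics.beam_angle_deg"],
        sound_speed=cfg["physics.sound_speed"],
    )


def build_geometry(cfg: dict) -> VesselGeometry:
    return VesselGeometry(
        outer_diameter_mm=cfg["geometry.outer_diameter_mm"],
        wall_thickness_mm=cfg["geometry.wall_thickness_mm"],
    )


def build_noise(cfg: dict) -> NoiseModel:
    return NoiseModel(
        white_noise_rms=cfg["synth.white_noise_rms"],
        interference_frequency=cfg["synth.interference_frequency"],
        interference_amplitude=cfg["synth.interference_amplitude"],
        ventilator_rate_cpm=cfg["synth.ventilator_rate_cpm"],
        ventilator_mod_depth=cfg["synth.ventilator_mod_depth"],
    )


def build_acquisition(cfg: dict) -> AcquisitionModel:
    return AcquisitionModel(
        sample_rate=cfg["synth.sample_rate"],
        adc_bits=int(cfg["synth.adc_bits"]),
        adc_range_v=cfg["synth.adc_range_v"],
        receiver_gain_db=cfg["synth.receiver_gain_db"],
    )


def build_stft(cfg: dict) -> StftParams:
    return StftParams(
        frame_length=int(cfg["estimator.frame_length"]),
        hop=int(cfg["estimator.hop"]),
        window=cfg["estimator.window"],
        zero_padding=int(cfg["estimator.zero_padding"]),
    )


def build_radio(cfg: dict) -> RadioConfig:
    losses = []
    if cfg["budget.fat_path_cm"] > 0:
        losses.append(("fat", 0.21, cfg["budget.fat_path_cm"]))
    if cfg["budget.muscle_path_cm"] > 0:
        losses.append(("muscle", 1.5, cfg["budget.muscle_path_cm"]))
    return RadioConfig(
        tx_power_dbm=cfg["budget.tx_power_dbm"],
        receiver_sensitivity_dbm=cfg["budget.receiver_sensitivity_dbm"],
        carrier_hz=cfg["budget.carrier_hz"],
        distance_m=cfg["budget.distance_m"],
        tissue_losses=tuple(losses),
    )


def build_sar(cfg: dict) -> SarConfig:
    return SarConfig(
        sar_per_watt=cfg["budget.sar_per_watt"],
        sar_limit=cfg["budget.sar_limit"],
        packet_on_ms=cfg["budget.packet_on_ms"],
        packet_period_ms=cfg["budget.packet_period_ms"],
        tx_power_delivered_mw=cfg["budget.tx_power_delivered_mw"],
        averaging_window_min=cfg["budget.averaging_window_min"],
    )


def build_power(cfg: dict) -> PowerConfig:
    return PowerConfig(
        battery_capacity_mah=cfg["budget.battery_capacity_mah"],
        active_current_ma=cfg["budget.active_current_ma"],
        adc_bits=int(cfg["budget.adc_bits"]),
        adc_span_v=cfg["budget.adc_span_v"],
    )
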