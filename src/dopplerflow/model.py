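"""Model/Results interface over the flow-estimation pipeline.

``CWDopplerFlowModel`` wraps a baseband :class:`~dopplerflow.synth.SignalRecord`
with the transducer configuration and vessel geometry; ``fit()`` runs the
spectrogram-envelope pipeline and returns a :class:`FlowResults` carrying
the point estimates, the per-frame envelope diagnostics, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimator import (
    FlowEstimate,
    SpectrogramEnvelope,
    Spectrogram,
    StftParams,
    estimate_flow,
    extract_envelope,
    smooth_envelope,
    stft_magnitude,
)
from .physics import NOMINAL_LUMEN_AREA_CM2, TransducerConfig, VesselGeometry

__all__ = ["CWDopplerFlowModel", "FlowResults"]


class CWDopplerFlowModel:
    """Flow-velocity model for a single baseband Doppler record.

    Parameters
    ----------
    record : SignalRecord
        The sampled baseband waveform.
    transducer : TransducerConfig, optional
        Doppler operating point (default 20 MHz, 45 degrees, 1570 m/s).
    area_cm2 : float, optional
        Lumen cross-section used for Q = v_bar * A.  Defaults to the
        0.18 cm² nominal mock-vessel area.
    stft_params, k, edge_correction_bins, filter_window :
        Pipeline tuning; see :mod:`dopplerflow.estimator`.
    """

    def __init__(
        self,
        record,
        transducer: TransducerConfig | None = None,
        area_cm2: float = NOMINAL_LUMEN_AREA_CM2,
        stft_params: StftParams | None = None,
        *,
        k: float = 6.0,
        edge_correction_bins: float = 1.0,
        dynamic_range_db: float = 35.0,
        filter_window: int = 9,
    ):
        self.record = record
        self.transducer = transducer or TransducerConfig()
        self.area_cm2 = area_cm2
        self.stft_params = stft_params or StftParams()
        self.k = k
        self.edge_correction_bins = edge_correction_bins
        self.dynamic_range_db = dynamic_range_db
        self.filter_window = filter_window

    def fit(self, force_filter: str | None = None) -> "FlowResults":
        """Run the pipeline; returns the fitted :class:`FlowResults`."""
        spec = stft_magnitude(self.record, self.stft_params)
        env = extract_envelope(
            spec,
            k=self.k,
            edge_correction_bins=self.edge_correction_bins,
            dynamic_range_db=self.dynamic_range_db,
        )
        estimate = estimate_flow(
            self.record,
            self.transducer,
            self.area_cm2,
            self.stft_params,
            k=self.k,
            edge_correction_bins=self.edge_correction_bins,
            dynamic_range_db=self.dynamic_range_db,
            filter_window=self.filter_window,
            force_filter=force_filter,
        )
        smoothed = smooth_envelope(env, estimate.filter_used, estimate.filter_window)
        return FlowResults(self, estimate, spec, env, smoothed)


@dataclass
class FlowResults:
    """Fitted flow estimate plus spectrogram/envelope diagnostics."""

    model: CWDopplerFlowModel
    estimate: FlowEstimate
    spectrogram: Spectrogram
    envelope: SpectrogramEnvelope
    smoothed_envelope: SpectrogramEnvelope

    @property
    def v_max_cm_s(self) -> float:
        return self.estimate.v_max_cm_s

    @property
    def spatial_average_velocity_cm_s(self) -> float:
        return self.estimate.spatial_average_velocity_cm_s

    @property
    def volumetric_flow_ml_min(self) -> float:
        return self.estimate.volumetric_flow_ml_min

    @property
    def filter_used(self) -> str:
        return self.estimate.filter_used

    def envelope_std_hz(self) -> float:
        """Frame-to-frame spread of the smoothed envelope (stability check)."""
        return float(np.std(self.smoothed_envelope.envelope_hz))

    def as_dict(self) -> dict:
        return {
            "v_max_cm_s": self.v_max_cm_s,
            "spatial_average_velocity_cm_s": self.spatial_average_velocity_cm_s,
            "volumetric_flow_ml_min": self.volumetric_flow_ml_min,
            "filter_used": self.filter_used,
            "filter_window": self.estimate.filter_window,
            "envelope_std_hz": self.envelope_std_hz(),
            "n_frames": int(self.envelope.frame_times.size),
        }

    def summary(self) -> str:
        e = self.estimate
        p = self.model.stft_params
        lines = [
            "CW Doppler flow estimate",
            "------------------------",
            f"Peak velocity v_max        {e.v_max_cm_s:9.3f} cm/s",
            f"Spatial average velocity   {e.spatial_average_velocity_cm_s:9.3f} cm/s",
            f"Volumetric flow Q          {e.volumetric_flow_ml_min:9.2f} mL/min",
            f"Lumen area A               {self.model.area_cm2:9.3f} cm^2",
            f"Envelope filter            {e.filter_used} (window {e.filter_window})",
            f"Frames / spread            {self.envelope.frame_times.size:d} frames, "
            f"{self.envelope_std_hz():.1f} Hz std",
            f"STFT                       frame {p.frame_length}, hop {p.hop}, "
            f"{p.window}, pad x{p.zero_padding}",
        ]
        return "\n".join(lines)
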