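"""Occlusion-discrimination features and baseline-relative patency calls.

A flow estimate near zero does not by itself establish an occlusion: noise
modulated by the ventilator produces a nonzero waveform amplitude while
the flow stays near zero.  These features quantify the raw waveform's
amplitude — the time-domain envelope RMS voltage — per protocol segment,
alongside the flow estimate, and interpret a new reading only relative to
previously established flow and no-flow baselines.

Note the deliberate asymmetry with flow estimation: RMS envelope
computation always uses the moving-maximum smoother, so a noisy occluded
segment can show a substantial RMS voltage even though its flow estimate
stays near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import hilbert

from .estimator import FlowEstimate, StftParams, estimate_flow
from .physics import NOMINAL_LUMEN_AREA_CM2, TransducerConfig
from .synth import InsufficientDataError, SignalRecord

__all__ = [
    "SegmentStats",
    "PatencyAssessment",
    "InvalidBaselineError",
    "rms_envelope",
    "segment_stats",
    "assess_patency",
]


class InvalidBaselineError(ValueError):
    """Flow baseline must exceed the no-flow baseline."""


@dataclass(frozen=True)
class SegmentStats:
    """Per-segment raw-sample statistics plus amplitude and flow features."""

    label: str
    mean_voltage: float
    std_voltage: float
    rms_envelope_voltage: float
    flow_estimate: FlowEstimate


@dataclass(frozen=True)
class PatencyAssessment:
    """Baseline-relative verdict on vessel patency."""

    baseline_flow_rms: float
    baseline_noflow_rms: float
    observed_rms: float
    verdict: str  # 'flow' | 'no-flow' | 'indeterminate'
    margin: float


def rms_envelope(
    record: SignalRecord,
    *,
    hop: int = 256,
    filter_window: int = 9,
) -> float:
    """RMS voltage of the smoothed time-domain amplitude envelope.

    The amplitude envelope is the magnitude of the analytic signal,
    block-averaged over ``hop``-sample frames, smoothed with a
    moving-maximum filter (always the maximum variant), and reduced to a
    single RMS value in volts.
    """
    if record.n_samples == 0:
        raise InsufficientDataError("empty record")
    env = np.abs(hilbert(record.samples))
    n_blocks = env.size // hop
    if n_blocks >= 1:
        env = env[: n_blocks * hop].reshape(n_blocks, hop).mean(axis=1)
    if filter_window > 1 and env.size > 1:
        env = maximum_filter1d(env, size=filter_window, mode="nearest")
    return float(np.sqrt(np.mean(env**2)))


def segment_stats(
    record: SignalRecord,
    cfg: TransducerConfig | None = None,
    area_cm2: float = NOMINAL_LUMEN_AREA_CM2,
    params: StftParams | None = None,
    **estimator_kwargs,
) -> list[SegmentStats]:
    """Raw mean/std, envelope RMS, and flow estimate per annotated segment.

    Segmentation comes from the record's annotations (ground truth, the
    analogue of visual segmentation); records without annotations are
    rejected.
    """
    if not record.annotations:
        raise ValueError("record carries no segment annotations")
    out: list[SegmentStats] = []
    for annotation, seg in record.segments():
        x = seg.samples
        est = estimate_flow(seg, cfg, area_cm2, params, **estimator_kwargs)
        out.append(
            SegmentStats(
                label=annotation.label,
                mean_voltage=float(np.mean(x)),
                std_voltage=float(np.std(x)),
                rms_envelope_voltage=rms_envelope(seg),
                flow_estimate=est,
            )
        )
    return out


def assess_patency(
    baseline_flow_rms: float,
    baseline_noflow_rms: float,
    observed_rms: float,
    *,
    margin: float = 0.10,
) -> PatencyAssessment:
    """Classify an observed envelope RMS against per-subject baselines.

    The verdict depends only on where ``observed_rms`` falls between the
    no-flow and flow baselines: above the midpoint by more than
    ``margin``/2 of the span -> 'flow'; below by the same -> 'no-flow';
    inside the band -> 'indeterminate'.  Scaling all three voltages by a
    common positive gain leaves the verdict unchanged.
    """
    if baseline_flow_rms <= baseline_noflow_rms:
        raise InvalidBaselineError(
            "flow baseline must exceed the no-flow baseline"
        )
    span = baseline_flow_rms - baseline_noflow_rms
    position = (observed_rms - baseline_noflow_rms) / span
    lo, hi = 0.5 - margin / 2.0, 0.5 + margin / 2.0
    if position > hi:
        verdict = "flow"
    elif position < lo:
        verdict = "no-flow"
    else:
        verdict = "indeterminate"
    return PatencyAssessment(
        baseline_flow_rms, baseline_noflow_rms, observed_rms, verdict, margin
    )
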