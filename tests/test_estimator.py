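"""Estimation pipeline: STFT, envelope, order-statistic smoothing, two-pass rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopplerflow.estimator import (
    FLOW_FILTER_BOUNDARY_ML_MIN,
    SpectrogramEnvelope,
    StftParams,
    UndefinedRelativeError,
    estimate_flow,
    extract_envelope,
    relative_error,
    smooth_envelope,
    stft_magnitude,
)
from dopplerflow.model import CWDopplerFlowModel
from dopplerflow.physics import doppler_shift, velocity_from_shift, vmax_from_flow
from dopplerflow.synth import (
    InsufficientDataError,
    NoiseModel,
    SignalRecord,
    generate_segment,
)

FS = 16400.0


def tone_record(freq_hz, duration_s=2.0, amp=0.1, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return SignalRecord(amp * np.sin(2 * np.pi * freq_hz * t), fs)


class TestStft:
    def test_pure_tone_peaks_at_tone_frequency(self):
        spec = stft_magnitude(tone_record(400.0))
        peak_freqs = spec.frequencies[np.argmax(spec.magnitude, axis=0)]
        assert np.all(np.abs(peak_freqs - 400.0) <= spec.bin_spacing_hz)

    def test_zero_record_gives_zero_magnitudes(self):
        rec = SignalRecord(np.zeros(8000), FS)
        spec = stft_magnitude(rec)
        assert np.all(spec.magnitude == 0.0)

    def test_white_noise_is_spectrally_flat(self):
        rng = np.random.default_rng(0)
        rec = SignalRecord(rng.normal(0, 0.1, 80000), FS)
        spec = stft_magnitude(rec)
        mean_per_bin = spec.magnitude.mean(axis=1)[1:-1]
        db_spread = 20 * np.log10(mean_per_bin / mean_per_bin.mean())
        assert np.all(np.abs(db_spread) < 3.0)

    def test_too_short_record_rejected(self):
        with pytest.raises(InsufficientDataError):
            stft_magnitude(SignalRecord(np.zeros(100), FS))

    def test_frame_times_at_hop_spacing(self):
        spec = stft_magnitude(tone_record(200.0, 1.0))
        dt = np.diff(spec.frame_times)
        assert np.allclose(dt, spec.params.hop / FS)


class TestEnvelope:
    def test_flat_band_edge_recovered_within_one_analysis_bin(self, no_noise):
        flow = 34.15
        rec = generate_segment(flow, 4.0, noise=no_noise, seed=3)
        spec = stft_magnitude(rec)
        env = extract_envelope(spec)
        f_max = doppler_shift(vmax_from_flow(flow, 0.18))
        assert np.all(np.abs(env.envelope_hz - f_max) <= spec.analysis_bin_hz)

    def test_zero_record_gives_zero_envelope(self):
        env = extract_envelope(stft_magnitude(SignalRecord(np.zeros(8000), FS)))
        assert np.all(env.envelope_hz == 0.0)

    def test_interference_line_reads_as_slow_velocity(self):
        # zero flow, default noise: the 129 Hz radio line survives
        # thresholding and converts to ~0.72 cm/s downstream
        rec = generate_segment(0.0, 4.0, seed=5)
        env = extract_envelope(stft_magnitude(rec))
        med = float(np.median(env.envelope_hz))
        assert med == pytest.approx(129.0, abs=8.0)
        assert velocity_from_shift(med) == pytest.approx(0.72, abs=0.05)


def brute_force_order_stat(x, window, op):
    half = window // 2
    padded = np.concatenate([np.repeat(x[0], half), x, np.repeat(x[-1], half)])
    return np.array([op(padded[i : i + window]) for i in range(len(x))])


class TestSmoothing:
    def test_window_one_is_identity(self):
        env = SpectrogramEnvelope(np.arange(5.0), np.array([0, 5, 0, 0, 5.0]), "t")
        out = smooth_envelope(env, "moving_min", 1)
        np.testing.assert_array_equal(out.envelope_hz, env.envelope_hz)

    def test_constant_envelope_unchanged_by_max(self):
        env = SpectrogramEnvelope(np.arange(6.0), np.full(6, 3.0), "t")
        out = smooth_envelope(env, "moving_max", 3)
        np.testing.assert_array_equal(out.envelope_hz, np.full(6, 3.0))

    def test_min_then_max_on_peaky_envelope(self):
        x = np.array([0, 5, 0, 0, 5, 0.0])
        env = SpectrogramEnvelope(np.arange(6.0), x, "t")
        mn = smooth_envelope(env, "moving_min", 3)
        np.testing.assert_array_equal(
            mn.envelope_hz, brute_force_order_stat(x, 3, np.min)
        )
        mx = smooth_envelope(mn, "moving_max", 3)
        np.testing.assert_array_equal(
            mx.envelope_hz, brute_force_order_stat(mn.envelope_hz, 3, np.max)
        )

    def test_even_window_rejected(self):
        env = SpectrogramEnvelope(np.arange(4.0), np.arange(4.0), "t")
        with pytest.raises(ValueError):
            smooth_envelope(env, "moving_min", 4)

    @given(
        values=st.lists(st.floats(0, 1000), min_size=1, max_size=50),
        window=st.sampled_from([1, 3, 5, 7, 9]),
        mode=st.sampled_from(["moving_min", "moving_max"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, values, window, mode):
        x = np.array(values)
        env = SpectrogramEnvelope(np.arange(len(x), dtype=float), x, "t")
        out = smooth_envelope(env, mode, window)
        op = np.min if mode == "moving_min" else np.max
        np.testing.assert_array_equal(
            out.envelope_hz, brute_force_order_stat(x, window, op)
        )


class TestEstimateFlow:
    def test_zero_record_estimates_zero_with_min_filter(self):
        est = estimate_flow(SignalRecord(np.zeros(32800), FS))
        assert est.volumetric_flow_ml_min == 0.0
        assert est.filter_used == "moving_min"

    def test_low_flow_keeps_min_filter(self, no_noise):
        rec = generate_segment(2.0, 4.0, noise=no_noise, seed=11)
        est = estimate_flow(rec)
        assert est.filter_used == "moving_min"
        assert est.volumetric_flow_ml_min <= FLOW_FILTER_BOUNDARY_ML_MIN

    def test_high_flow_switches_to_max_filter(self, no_noise):
        rec = generate_segment(20.0, 4.0, noise=no_noise, seed=11)
        est = estimate_flow(rec)
        assert est.filter_used == "moving_max"

    def test_doubling_flow_doubles_vmax(self, no_noise):
        a = estimate_flow(generate_segment(10.0, 4.0, noise=no_noise, seed=21))
        b = estimate_flow(generate_segment(20.0, 4.0, noise=no_noise, seed=22))
        assert b.v_max_cm_s / a.v_max_cm_s == pytest.approx(2.0, rel=0.02)

    def test_estimate_internally_consistent(self, no_noise):
        est = estimate_flow(generate_segment(15.0, 4.0, noise=no_noise, seed=4))
        assert est.spatial_average_velocity_cm_s == pytest.approx(
            est.v_max_cm_s / 2.0
        )

    def test_default_noise_changes_high_flow_estimates_little(self, no_noise):
        # broadband noise floor should not move the band edge materially
        clean = estimate_flow(generate_segment(20.0, 4.0, noise=no_noise, seed=31))
        noisy = estimate_flow(generate_segment(20.0, 4.0, seed=31))
        assert noisy.volumetric_flow_ml_min == pytest.approx(
            clean.volumetric_flow_ml_min, rel=0.07
        )


class TestModelInterface:
    def test_fit_matches_functional_pipeline(self, no_noise):
        rec = generate_segment(15.0, 4.0, noise=no_noise, seed=6)
        res = CWDopplerFlowModel(rec).fit()
        est = estimate_flow(rec)
        assert res.volumetric_flow_ml_min == est.volumetric_flow_ml_min
        assert res.filter_used == est.filter_used

    def test_summary_reports_flow(self, no_noise):
        rec = generate_segment(15.0, 4.0, noise=no_noise, seed=6)
        res = CWDopplerFlowModel(rec).fit()
        assert "Volumetric flow" in res.summary()
        assert res.as_dict()["n_frames"] > 0


class TestRelativeError:
    @pytest.mark.parametrize(
        "est, ref, expected",
        [(34.2, 34.15, 0.1464), (5.0, 5.0, 0.0), (6.6, 6.0, 10.0)],
    )
    def test_arithmetic(self, est, ref, expected):
        assert relative_error(est, ref) == pytest.approx(expected, abs=1e-3)

    def test_zero_reference_is_undefined(self):
        with pytest.raises(UndefinedRelativeError):
            relative_error(0.4, 0.0)
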