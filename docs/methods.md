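# Methods

## Physical model

A CW Doppler probe with separate transmit/receive elements insonates a
vessel at beam angle θ. Backscatter from red cells (or phantom scatterers)
moving at velocity v returns shifted by f_d = 2·v·f₀·cosθ/c. The receive
chain is homodyne and unidirectional: the baseband record is a single real
channel, and only non-negative shifts are represented. Defaults are the
device operating point: f₀ = 20 MHz, θ = 45°, c = 1570 m/s.

Under uniform insonation and fully developed laminar (parabolic) flow, the
cross-sectional velocity profile v(r) = v_max·(1 − r²/R²) implies (i) a
uniform density of scatterer velocities on [0, v_max], so the baseband
spectrum is a flat-topped band with edge f_max = f_d(v_max); and (ii) a
spatial average velocity v̄ = v_max/2, so the volumetric flow is
Q = v̄·A. The reference mock vessel (OD 5.33 mm, wall 0.29 mm) has exact
lumen area 0.1772 cm²; the two-decimal value 0.18 cm² is carried on all
flow-reporting paths (`NOMINAL_LUMEN_AREA_CM2`) so reported flows match the
device's own convention. An entrance length of ten inner diameters is the
rule used for the parabolic profile to develop on the bench.

## Synthetic-data generator

`generate_segment` synthesises one constant-flow segment as a random-phasor
(speckle) model: K = 128 tones with Doppler frequencies corresponding to
velocities spread over [0, v_max], Rayleigh amplitudes, uniform phases.
Velocities are **stratified-uniform** — one uniform draw per equal-width
stratum — so each velocity is uniform within its stratum while the realised
band edge stays within v_max/K of nominal. (Plain iid draws make the band
edge itself fluctuate by several percent at K = 128, which would confound
generator variance with estimator error; an `stratified=False` switch
restores iid sampling.) The tone sum is normalised to a configurable RMS at
the ADC, default 35 mV: the absolute Doppler signal level at the ADC is not
fixed by the receive-chain parameters, so it is a free model parameter; 35 mV
is chosen from the noise budget (white floor 9.8 mV = 0.39 µV input-referred
× 88 dB gain; interference tone 10 mV peak → total noise σ ≈ 12.1 mV) so a
flow segment's sample standard deviation is about three times an occlusion
segment's, the qualitative flow/no-flow contrast the features layer is built
to detect.

Noise terms: white Gaussian receiver noise (default 9.8 mV RMS); a pure
interference tone at 129 Hz, the radio packet repetition rate (1/7.74 ms) —
injected as a tone rather than a pulse train because the artifact manifests
as a narrowband line; and ventilator amplitude modulation
(1 + m·sin(2π·rate·t)) applied to the flow signal only (respiration
modulates venous return, not the receiver noise), default 11.5 cycles/min,
depth 0.3. Everything is then mid-tread quantized to the 10-bit ±1.25 V ADC
grid (LSB 2.441 mV) and clipped at the rails.

`generate_protocol` concatenates segments (e.g. flow → occlusion → release)
with deterministic child seeds spawned from the record seed and annotations
tiling the record exactly.

What the generator does **not** emulate: cardiac pulsatility waveform shape,
wall/clutter signal, spectral broadening from beam geometry, probe-coupling
dropouts, motor spurs of a real pump, and any amplitude-vs-flow dependence
of backscattered power. Passing tests therefore demonstrate correctness of
the pipeline under the stated band model, not performance on real tissue
recordings; the bench-hardware error magnitudes reported for real devices at
low flows (driven by these unmodeled effects) are intentionally not
reproduced.

A note on quantization realism: the ADC model is undithered. A narrowband
signal (very low flow, or an interference tone alone) with no white noise
produces strong deterministic distortion spurs — as a real undithered
converter would. With the default white floor (≈4 LSB) the converter is
effectively dithered and spur-free. The estimator's dynamic-range clamp
(below) exists for exactly the noise-free corner.

## Flow estimator

Pipeline: Hann-windowed STFT (frame 2048 samples, hop 256, ×2 zero padding
at the 16.4 kHz default rate → 8 Hz analysis resolution, 4 Hz bin spacing);
per-frame maximum-frequency envelope; moving minimum/maximum smoothing
(window 9 frames); the mean smoothed envelope is the Doppler shift of
v_max; then v̄ = v_max/2 and Q = v̄·A.

The sample rate default, 16 400 Hz, follows from the device display's
window arithmetic (244 samples ≙ 14.9 ms); the frame length is chosen so
that the 8 Hz analysis bin is well below the ~14 Hz resolution needed for
≈1 % accuracy at the highest calibrated band edge (≈1139 Hz).

**Envelope definition.** Per frame, the envelope is the highest frequency
bin whose magnitude exceeds a detection threshold; frames with no bin above
threshold report 0 Hz (so fully occluded records estimate zero rather than
being dropped). The threshold is

    max( k × median(upper-quartile bins),  frame peak × 10^(−DR/20) )

with k = 6 and DR = 35 dB. The first term is a robust white-noise-floor
estimate (the top quarter of the band is assumed signal-free; the Doppler
band must stay below ¾ Nyquist). k = 6 keeps the probability of a single
Rayleigh-distributed noise bin crossing the threshold below ~10⁻¹¹ per bin;
smaller multipliers admit isolated false crossings that the moving-maximum
smoother then propagates across its whole window. The second term is a
dynamic-range clamp: content further below the frame peak than the receive
chain's ~35 dB input dynamic range is not a resolvable signal. It also
rejects the narrow ADC-distortion spurs described above, which can exceed
any multiple of the white floor on noise-free narrowband input.

**Band-edge correction.** The threshold crossing at the band edge rides on
the analysis window's mainlobe skirt and overshoots the true edge by one to
two analysis bins. A fixed correction of 1.0 analysis bin
(sample_rate/frame_length) is subtracted, calibrated once against the
generator's known band edge; the residual per-frame envelope error is then
within ±1 analysis bin. The correction is config-exposed
(`edge_correction_bins`) and can be set to 0 for the raw crossing.

**Filter selection.** Estimation is two-pass: a moving-minimum pass first;
if the resulting Q exceeds 3.00 mL/min the estimate is recomputed with a
moving maximum and that result is reported. The minimum filter suppresses
upward peaking for near-zero flows; the maximum filter tracks the band edge
once a band is present. Both filters are sliding order statistics with
edge replication and an odd window. `force_filter` bypasses the rule for
calibration sweeps.

With the default noise model, a fully occluded record still reads a small
apparent flow (≈3.9 mL/min): the 129 Hz interference line legitimately
survives thresholding and converts to ≈0.72 cm/s. This reproduces the
false-positive hazard that motivates baseline-relative patency assessment
rather than absolute readings.

## Occlusion features

`rms_envelope` computes the magnitude of the analytic signal (amplitude
envelope in volts), block-averages it over the STFT hop, smooths with a
moving **maximum** (always — this deliberate asymmetry with flow estimation
means ventilator-modulated noise inflates the RMS of occluded segments
while their flow estimate stays near zero), and reports the RMS. An
amplitude (voltage) envelope is used rather than the time-frequency
envelope because an RMS in volts requires one; the spectral machinery
remains available separately.

`segment_stats` takes segmentation from record annotations (ground truth,
the stand-in for visual segmentation) and reports per segment the raw
sample mean (≈0 for the zero-mean signal model) and standard deviation,
the envelope RMS, and the flow estimate. `assess_patency` classifies an
observed RMS only by its position between per-subject flow and no-flow
baselines, with a configurable indeterminate band (default 10 % of the
span); the verdict is invariant to overall gain.

## Budgets

Pure closed forms: FSPL = 20·log₁₀(4πdf/c); link margin = TX −
sensitivity − FSPL − Σ(tissue dB/cm × cm) with published fat
(0.21 dB/cm) and muscle (1.5 dB/cm) coefficients and skin neglected; radio
duty cycle 5.02/7.74 ms = 64.9 %; SAR-limited continuous power
(1.6 W/kg)/(468.2 W/kg per W) ≈ 3.4 mW; maximum observation time
(allowed/average power) × 6 min averaging window, capped at the window.
`rounded_chain=True` reproduces the budget-table arithmetic that rounds the
intermediate powers (3.4 mW / 6.49 mW → 3 min 8.6 s); the default carries
full precision (3 min 9.7 s).

## Calibration

`run_calibration` replays the bench protocol on seeded phantoms: the grid
0–10 mL/min in 1 mL/min steps then 15–34.15 in 5 mL/min steps (the maximum
set by a 50 mL syringe), default 3 replicates × 10 s per rate, absolute
error always and relative error only for nonzero references (undefined at
zero), a relative-error band from the ±1 % pump tolerance, and a
least-squares linear fit of estimate vs reference. An injectable
`estimator` callable lets an identity oracle validate the fit path. The
hardware linear-fit anchors reported for real devices are hardware-specific
and are not targets for synthetic runs; the analogous fit is printed for
comparison only.

`filter_selection_sweep` is the reference-aware optimisation of smoother
variant and window per rate (argmin |error|); it requires the true rate and
cannot be applied blind.

## Problem sizes and determinism

Default test and acceptance runs use 10 s records (≈164 k samples, ≈630
STFT frames) for calibration-grade estimates and 2–6 s records for
statistical replicates; these lengths give stable envelopes (the smoothed
envelope's frame-to-frame spread is typically < 1 bin on noiseless input).
All randomness flows through `numpy.random.SeedSequence`; protocol and
calibration runs spawn child seeds deterministically, and record provenance
snapshots the generating configuration and seed.

## Known limitations

- Single real channel: no directional (quadrature) estimation, no reverse
  flow.
- The envelope threshold assumes the upper quarter of the analysis band is
  signal-free; flows whose band edge approaches ¾ Nyquist need a higher
  sample rate.
- Low flows (band edge within a few analysis bins of DC) carry relative
  errors of several percent from finite spectral resolution, mirroring the
  low-flow behaviour of the physical system; absolute errors remain small.
- The flow/no-flow amplitude contrast (σ ratio ≈ 3) is a consequence of the
  chosen default amplitudes, not a prediction; on real recordings the
  contrast must be established per subject via baselines.
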