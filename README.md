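# dopplerflow

Desk-scale toolkit for wireless implantable continuous-wave (CW) Doppler
blood-flow monitoring. After free-flap or other microvascular surgery, the
patency of the venous anastomosis must be watched for days; a miniature
implanted CW Doppler probe clipped to the vessel reports a baseband audio
signal whose spectrum encodes the blood velocity distribution in the lumen.
This package reimplements the computational core of such a monitor so that
every stage can be developed, tested, and benchmarked on a desk, without
hardware:

- **`physics`** — closed-form conversions built on the Doppler equation
  f_d = 2·v·f₀·cosθ/c (default f₀ = 20 MHz, θ = 45°, c = 1570 m/s) and the
  laminar-flow relation Q = v̄·A with v̄ = v_max/2.
- **`synth`** — a seeded generator of synthetic baseband Doppler records
  emulating a syringe-pump flow phantom (constant rates, 0.18 cm² mock
  vessel) and femoral-vein recordings (flow → occlusion → release segments,
  ventilator amplitude modulation, a 129 Hz radio-interference line, white
  receiver noise, 10-bit ADC quantization).
- **`estimator` / `model`** — the flow pipeline: STFT, per-frame
  maximum-frequency envelope, moving minimum/maximum smoothing, mean
  envelope → v_max → v̄ → Q, wrapped in a statsmodels-style
  `CWDopplerFlowModel(record).fit() → FlowResults`.
- **`features`** — occlusion discrimination: per-segment raw statistics and
  envelope RMS voltage, plus baseline-relative patency assessment.
- **`budget`** — the device's closed-form budgets: 915 MHz link margin,
  SAR-limited observation time, battery runtime, ADC resolution.
- **`calibration`** — the bench calibration protocol on synthetic phantoms:
  flow grid, error curves with pump-tolerance bands, filter-selection
  sweep, linear fit.
- **`io` / `cli`** — WAV/CSV signal interchange with annotation sidecars, a
  flat validated config schema, and the `dopplerflow` command
  (`simulate`, `estimate`, `features`, `calibrate`, `budget`).

## Worked example

Simulate a 10 s noiseless phantom record at 20 mL/min and estimate its flow:

```python
from dopplerflow import CWDopplerFlowModel, NoiseModel, generate_segment

rec = generate_segment(20.0, 10.0, noise=NoiseModel.none(), seed=7)
res = CWDopplerFlowModel(rec).fit()
print(res.summary())
```

```
CW Doppler flow estimate
------------------------
Peak velocity v_max            3.712 cm/s
Spatial average velocity       1.856 cm/s
Volumetric flow Q              20.04 mL/min
Lumen area A                   0.180 cm^2
Envelope filter            moving_max (window 9)
Frames / spread            633 frames, 0.0 Hz std
STFT                       frame 2048, hop 256, hann, pad x2
```

The generator placed the Doppler band edge at the shift corresponding to
v_max = 3.704 cm/s (20 mL/min through 0.18 cm²); the pipeline recovers
20.04 mL/min, a +0.2 % relative error. The two-pass rule selected the
moving-maximum smoother because the first-pass (moving-minimum) flow
exceeded 3.00 mL/min.

The same from the shell, through WAV interchange:

```bash
dopplerflow simulate --flow 20 --duration 10 --seed 7 --noiseless -o rec.wav
dopplerflow estimate rec.wav
```

And the device budget chain:

```bash
$ dopplerflow budget
Implant device budget
---------------------
Free-space path loss          31.68 dB
Link margin                   64.32 dB
Radio duty cycle               64.9 %
Average delivered power        6.49 mW
SAR-limited power              3.42 mW
Max observation time         3 min  9.7 s
Battery runtime              3 h 20.0 min
ADC resolution (LSB)          2.441 mV
```

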