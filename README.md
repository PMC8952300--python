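# gaitharmonics

Harmonic modeling, prediction and classification of human gait during level
walking, from a single thigh-mounted IMU.

The thigh flexion–extension angle during steady walking is periodic at the
stride frequency, which makes a truncated Fourier series a natural and very
compact model of one gait cycle:

```
y(t) = b + Σₙ₌₁..N aₙ · cos(2π·n·f₀·t + φₙ)
```

where `f₀` is the fundamental (stride) frequency, `aₙ` and `φₙ` the amplitude
and initial phase of the n-th harmonic, and `b` the DC offset. Five harmonics
capture the thigh angle to better than 0.999 correlation per stride; the
sagittal gyro signal, being richer in high-frequency content, needs nine.

The package is aimed at researchers and engineers working on wearable-sensor
gait analysis, pedestrian dead reckoning and rehabilitation monitoring. It
covers the full pipeline:

- **`orientation`** — single-axis thigh-angle estimation from raw 6-axis IMU
  data (gyro integration with accelerometer drift correction at quasi-static
  instants);
- **`strides`** — minimum-to-minimum stride segmentation, toe-off detection
  (positive-gradient gyro zero crossing), 2000-point time/amplitude
  normalization, RMSE template grouping and mean-waveform templates;
- **`spectral`** — amplitude-calibrated FFT spectra, fundamental detection
  (highest non-DC peak), harmonic extraction and the 1 %-median significance
  rule;
- **`harmonic`** — the Fourier-series model itself, plus a bundled library of
  twelve published templates: six common thigh-angle stride patterns and the
  six matching gyro patterns, amplitude-normalized to the fundamental;
- **`classify`** — regeneration of a whole trial from a first-stride model,
  and per-stride classification against the template library by Pearson
  correlation and RMSE;
- **`synthetic`** — a fully labeled synthetic gait generator (stride-time
  jitter, residual harmonics, sensor noise, raw IMU synthesis), so every
  stage is testable without access to recorded data.

## Worked example

```python
import numpy as np
from gaitharmonics import (
    GaitSimConfig, classify_strides, fit_stride_model, load_model_library,
    predict_trial, segment_strides, simulate_trial,
)

# a 12-stride synthetic walk of stride pattern 3 with realistic noise
cfg = GaitSimConfig(n_strides=12, pattern_sequence=(3,), seed=42)
trial = simulate_trial(cfg)

strides = segment_strides(trial.angle, gyro=trial.gyro_dps)
print(f"segmented {len(strides)} strides, "
      f"mean stride time {np.mean([s.stride_time_s for s in strides]):.3f} s")

model = fit_stride_model(strides[0], n_harmonics=5)
print(f"first-stride model: f0 = {model.fundamental_hz:.3f} Hz, "
      f"a = {np.round(model.amplitudes, 4).tolist()}")

result = predict_trial(strides, model)
print(f"trial regenerated from first stride: "
      f"r = {result.correlation:.4f}, RMSE = {result.rmse_deg:.2f} deg")

matrix = classify_strides(strides, load_model_library())
print(f"best-matching pattern per stride: {matrix.best_model.tolist()}")
```

Output:

```
segmented 10 strides, mean stride time 0.993 s
first-stride model: f0 = 1.020 Hz, a = [18.9932, 3.8538, 1.4424, 0.5078, 0.4122]
trial regenerated from first stride: r = 0.9980, RMSE = 0.90 deg
best-matching pattern per stride: [3, 3, 3, 3, 3, 3, 3, 3, 3, 3]
```

The 12 generated strides give 10 after the walk's first and last strides are
discarded. The fitted amplitudes fall off quickly — the fundamental carries
~19° while the fifth harmonic is below half a degree — which is why five
harmonics regenerate the trial to a 0.998 correlation even though every
stride is reconstructed from the *first* stride's model. Classification
recovers the generating pattern for all ten strides.

The same pipeline is available from the shell:

```sh
gaitharmonics simulate --n-strides 12 --pattern 3 --seed 42 --output walk/
gaitharmonics angle    --input walk/imu.csv --output walk/angle_est.csv
gaitharmonics classify --input walk/angle.csv --output walk/matrix
```

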