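# Methods

## The harmonic gait model

The thigh flexion–extension angle θ(t) during level walking is treated as a
periodic signal at the stride frequency f₀ and modeled as a truncated Fourier
series

    y(t) = b + Σₙ₌₁ᴺ aₙ cos(2π n f₀ t + φₙ),

with N = 5 for the thigh angle and N = 9 for the sagittal gyro signal
(angular velocity dθ/dt). The model's assumptions are steady-state level
walking (no gait initiation/termination, no stairs or ramps), approximate
periodicity stride-to-stride, and a single dominant sagittal-plane rotation.
Within one stride the model is exact up to the truncation order; across
strides, amplitude and timing vary, which the pipeline absorbs by refitting
f₀ per stride (from the stride time) and affinely rescaling amplitudes.

## Spectral conventions

`compute_spectrum` uses a transform length equal to the input length — never
padded to a power of two — so that a stride cascaded c times puts its
fundamental exactly on bin c. Amplitudes are one-sided, `2|X_k|/L` for bins
k ≥ 1 (`|X_k|/L` at Nyquist for even L) and `X₀/L` for DC, with phases taken
as complex angles: a cosine `A·cos(2πft+φ)` over integer periods reads back
as amplitude A and phase φ at its bin, so spectral coefficients are directly
the Fourier-series coefficients. This calibration is verified by a Parseval
power balance (1e−9 relative) in the tests.

The fundamental is identified as the highest-amplitude non-DC bin (the
stride frequency dominates every gait spectrum; ties break to the lower
frequency). Harmonic n is read at the largest-amplitude bin within ±1 bin of
the nearest bin to n·f₀; no sub-bin interpolation is performed by default.
Extracted phases are wrapped to [0, 2π) to match the stored template
convention.

The significance rule takes per-stride amplitude rows normalized to the
fundamental and returns the largest N such that the across-stride median of
aₙ/a₁ stays ≥ 1 % for every n ≤ N (the fundamental always counts, so N ≥ 1).
On the six bundled thigh-angle template rows this yields N = 5. The six gyro
rows alone yield N = 8 under the same rule (the median ninth-harmonic
amplitude of just these six templates is ≈ 0.3 %); the nine-harmonic default
for the gyro channel reflects the population-level behavior the templates
were derived from, and is kept as the package default.

## Template library and its conventions

Twelve templates ship with the package: six thigh-angle and six gyro stride
patterns, ordered from "no oscillation after the swing maximum" (pattern 1)
to "secondary loading-response peak comparable to the primary" (pattern 6).
Amplitudes are normalized to the fundamental (a₁ = 1) and phases stored in
radians exactly as published; no DC term is published, so the package adopts
its own conventions:

- **Thigh-angle templates**: b is set so the one-period minimum is 0,
  consistent with the [0, 1] amplitude normalization used for measured
  strides.
- **Gyro templates**: b = 0, because angular velocity integrates to zero
  over a cycle and a zero-mean template keeps the toe-off zero crossing
  meaningful.

Because every comparison goes through affine amplitude rescaling, any DC
choice is equivalent for classification; these choices only affect plotting
and the zero-crossing semantics.

For generation and classification the templates are additionally
time-shifted so t = 0 sits exactly on the stride boundary: the waveform
minimum for thigh angle (strides are cropped minimum-to-minimum), the first
positive-gradient zero crossing for gyro (the toe-off signature). The
published phases already encode this alignment to within ≈ 0.04 rad; the
exact shift lets classification skip any lag search. Raw printed
coefficients are preserved untouched in the library and in the coefficient
round-trip checks.

## Stride segmentation and normalization

Stride boundaries are thigh-angle minima, found with a prominence-thresholded
peak search (default prominence 20 % of the trial's amplitude range, minimum
separation 0.4 s) so that the secondary loading-response dip of patterns 4–6
cannot split a stride. Endpoints of the series count as boundaries when the
signal leaves them upward from the lower part of the range — a trial that
starts on toe-off starts on a minimum an interior-only search would miss.
The first and last stride of the walk are discarded. Toe-off within a gyro
segment is the first zero crossing with positive gradient, linearly
interpolated between samples (central-difference gradient at touching
zeros).

Each stride is resampled to 2000 points by linear interpolation on the
half-open normalized time interval [0, 1) and amplitude-mapped to [0, 1].
Template grouping assigns a normalized stride to its lowest-RMSE template if
that RMSE is below 2.5 % of the normalized range, else leaves it unassigned;
mean templates are sample-wise means re-normalized to unit range (each
stride is normalized before averaging and the average re-normalized after).

Per-stride harmonic fitting cascades the stride four times end-to-end before
the FFT, which quadruples frequency resolution without changing harmonic
amplitudes; f₀ is taken from the stride time (its reciprocal), which for an
exactly periodic stride lands on bin 4 of the cascaded transform.

## Orientation filter

The thigh angle is estimated from raw IMU data by trapezoidal integration of
the sagittal gyro channel, blended toward the accelerometer inclination
angle `atan2(a_forward, a_longitudinal)` by a factor α (default 0.02 per
sample at 100 Hz, a ≈ 0.5 s correction time constant) whenever the
accelerometer magnitude is within 0.05 g of 1 g (quasi-static). With α = 0
the filter is exactly the cumulative trapezoidal integral. This is a
deliberately minimal one-axis complementary filter, not a full orientation
filter: no magnetometer, no 3-D attitude, no adaptive gain scheduling. It is
validated by parameter recovery on synthetic data only — with a constant
0.5 °/s gyro bias over 20 s of simulated walking, the recovered angle stays
within 1° RMSE of the generating trajectory, and the steady-state bias error
is bounded near `bias/(α·rate)` rather than growing linearly.

## Synthetic data: what it emulates and what it does not

The generator's default conditions are a normal self-selected walk: stride
time 1.0 s mean (two steps per second) with 3 % lognormal coefficient of
variation, a 40° flexion–extension excursion (−15° to +25°), residual
harmonics 6–10 at 0.5 % of the fundamental with uniform random phases
(matching the sub-1 % overtone tail of real stride spectra), 0.3° white
measurement noise on the angle, 1 °/s on the gyro, and 0.01 g on the
accelerometer. Strides are drawn from the aligned templates, each exactly
periodic over its own sample count, and joined at their boundary minima; a
pattern change introduces a small boundary-value mismatch that is absorbed
by a linear in-stride ramp (continuity is preferred over physical realism at
the junction). The gyro channel is the analytic derivative of the noiseless
angle; the IMU synthesizer rotates gravity by the angle in the sagittal
plane and adds gyro bias and white noise.

What this does **not** emulate: linear (non-gravitational) body
acceleration, soft-tissue artifact, sensor misalignment and cross-axis
sensitivity, asymmetric or pathological gait, surface changes mid-trial, and
within-stride shape variability beyond the six discrete patterns. Passing
tests therefore demonstrate correctness of the algorithms under the model's
own assumptions — exact recoverability in the noiseless limit, graceful
degradation under the stated noise — not performance on recorded clinical
data.

## Numerical choices and degenerate inputs

- Constant signals raise explicit degenerate-range/constant-input errors in
  normalization, rescaling and correlation rather than returning NaN.
- Correlation is Pearson product-moment; classification picks the
  highest-correlation model (ties to the lower label) and flags strides
  where the RMSE minimum disagrees.
- Trial prediction rescales each reconstruction to the stride's measured
  peak-to-peak range by default; an alternative rule that equates the
  fundamental amplitude to the stride's maximum angle is available as
  `rescale_rule="max_as_fundamental"`.
- Harmonics at or above Nyquist raise range errors; spectra require ≥ 8
  samples; segmentation requires ≥ 3 detected minima.
- Problem sizes in the tests and the acceptance script (200-stride
  regeneration runs, 600-stride classification runs, 20 s orientation
  trials) were chosen as the smallest sizes at which medians and recovery
  rates are stable across seeds.

## Known limitations

- The orientation filter is a stand-in validated only on synthetic data; on
  real IMU streams with sustained dynamic acceleration its quasi-static gate
  will fire rarely and drift correction will be correspondingly slower.
- Endpoint-minimum detection is heuristic under heavy noise; a missed
  endpoint costs at most the first/last stride, which the pipeline discards
  anyway.
- Template classification assumes strides cropped at toe-off; grossly wrong
  segmentation shifts the phase relationship and lowers all correlations
  (a circular-shift search is not performed).
- Stairs, ramps and non-level activities are out of scope: no templates
  exist for them in the bundled library.
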