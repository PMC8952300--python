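"""Labeled synthetic gait data for every stage of the pipeline.

The original study recordings are not publicly available, so this module
generates walking data from the published stride-pattern templates instead:
each stride is a harmonic-model reconstruction rescaled to a physiological
thigh-angle range, with per-stride lognormal stride-time jitter, residual
high-harmonic content (harmonics 6-10 at a small fraction of the fundamental,
mimicking the sub-1 % overtone tail seen in real spectra), and additive white
noise.  The sagittal gyro channel is the analytic time derivative of the
noiseless angle plus its own noise, and a raw 6-axis IMU stream can be
synthesized from any angle trajectory.  Ground-truth labels, boundaries and
stride frequencies always accompany the output, so downstream accuracy is
measurable without real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .harmonic import (
    TWO_PI,
    HarmonicModel,
    ModelLibrary,
    TimeGrid,
    load_model_library,
    reconstruct,
    reconstruct_derivative,
)
from .orientation import ImuRecord, ThighAngleSeries
from .strides import Stride

__all__ = ["GaitSimConfig", "SimulatedTrial", "simulate_trial", "simulate_strides", "simulate_imu"]


@dataclass(frozen=True)
class GaitSimConfig:
    """Study conditions for the synthetic gait generator.

    Defaults describe a normal self-selected level walk: ~1 s stride time
    (two steps per second), a 40-degree flexion-extension excursion, residual
    harmonics 6-10 at 0.5 % of the fundamental, and sub-degree measurement
    noise.  All randomness flows from ``seed``.
    """

    n_strides: int = 20
    pattern_sequence: tuple[int, ...] = (1, 2, 3, 4, 5, 6)  # cycled over strides
    stride_time_mean_s: float = 1.0
    stride_time_cv: float = 0.03
    angle_range_deg: tuple[float, float] = (-15.0, 25.0)
    noise_deg_sd: float = 0.3
    extra_harmonic_frac: float = 0.005
    gyro_noise_dps_sd: float = 1.0
    accel_noise_g_sd: float = 0.01
    gyro_bias_dps: float = 0.0
    rate_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise InputError("n_strides must be >= 1")
        if self.stride_time_mean_s <= 0:
            raise InputError("stride_time_mean_s must be positive")
        for name in ("stride_time_cv", "noise_deg_sd", "extra_harmonic_frac",
                     "gyro_noise_dps_sd", "accel_noise_g_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not all(1 <= p <= 6 for p in self.pattern_sequence):
            raise InputError("pattern labels must be in 1..6")
        if self.angle_range_deg[1] <= self.angle_range_deg[0]:
            raise InputError("angle_range_deg must have max > min")


@dataclass(frozen=True)
class SimulatedTrial:
    """A synthetic walking trial with full ground truth."""

    angle: ThighAngleSeries
    gyro_dps: np.ndarray
    labels: tuple[int, ...]
    boundaries_s: np.ndarray  # n_strides + 1 stride-boundary times
    boundary_idx: np.ndarray  # matching sample indices
    f0_hz: tuple[float, ...]
    config: GaitSimConfig = field(repr=False, default=GaitSimConfig())

    def true_strides(self) -> list[Stride]:
        """Strides cut at the generator's own boundaries (no detector involved)."""
        out = []
        for i in range(len(self.labels)):
            i0, i1 = int(self.boundary_idx[i]), int(self.boundary_idx[i + 1])
            out.append(
                Stride(
                    angle_deg=self.angle.angle_deg[i0:i1],
                    gyro_dps=self.gyro_dps[i0:i1],
                    start_s=float(self.boundaries_s[i]),
                    end_s=float(self.boundaries_s[i + 1]),
                    index_in_trial=i,
                    rate_hz=self.config.rate_hz,
                    label=self.labels[i],
                )
            )
        return out


def _stride_times(config: GaitSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-stride durations: lognormal with the configured mean and CV."""
    if config.stride_time_cv == 0:
        return np.full(config.n_strides, config.stride_time_mean_s)
    sigma2 = np.log1p(config.stride_time_cv**2)
    mu = np.log(config.stride_time_mean_s) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=config.n_strides)


def _build_stride_waveforms(
    model: HarmonicModel,
    stride_time_s: float,
    config: GaitSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Noiseless angle and gyro waveforms of one stride.

    The template (already aligned so its minimum sits at t = 0) is
    reconstructed over L = round(T * rate) samples with f0 = rate / L — the
    stride is exactly periodic over its own samples — then affinely mapped to
    the configured angle range.  Residual harmonics 6-10 with random phases
    are superimposed at ``extra_harmonic_frac`` of the fundamental amplitude.
    Returns (angle_deg, gyro_dps, effective stride time).
    """
    L = max(2, int(round(stride_time_s * config.rate_hz)))
    t_eff = L / config.rate_hz
    f0 = 1.0 / t_eff
    grid = TimeGrid(0.0, t_eff, config.rate_hz)
    m = model.at_fundamental(f0)
    base = reconstruct(m, grid)
    lo, hi = config.angle_range_deg
    ptp = float(np.ptp(base))
    amp_scale = (hi - lo) / ptp  # degrees per normalized template unit
    angle = lo + (base - base.min()) * amp_scale
    gyro = amp_scale * reconstruct_derivative(m, grid)
    if config.extra_harmonic_frac > 0:
        t = grid.times()
        a_extra = config.extra_harmonic_frac * amp_scale * m.amplitudes[0]
        for n in range(6, 11):
            phase = rng.uniform(0.0, TWO_PI)
            arg = TWO_PI * n * f0 * t + phase
            angle = angle + a_extra * np.cos(arg)
            gyro = gyro - a_extra * TWO_PI * n * f0 * np.sin(arg)
    return angle, gyro, t_eff


def _aligned_templates(library: ModelLibrary) -> dict[int, HarmonicModel]:
    return {m.label: m.aligned_to_start("min").with_min_zero_dc() for m in library.thigh_models}


def simulate_strides(
    config: GaitSimConfig,
    library: ModelLibrary | None = None,
) -> list[Stride]:
    """Generate labeled stand-alone strides (noise included), one per pattern draw.

    Pattern labels cycle through ``config.pattern_sequence``.  Each stride
    carries its ground-truth label, exact timing and a matching noisy gyro
    segment; boundaries are exact by construction, so these strides probe
    modeling and classification in isolation from the segmentation step.
    """
    library = library or load_model_library()
    rng = np.random.default_rng(config.seed)
    templates = _aligned_templates(library)
    durations = _stride_times(config, rng)
    strides: list[Stride] = []
    t0 = 0.0
    for i in range(config.n_strides):
        label = config.pattern_sequence[i % len(config.pattern_sequence)]
        angle, gyro, t_eff = _build_stride_waveforms(templates[label], durations[i], config, rng)
        if config.noise_deg_sd > 0:
            angle = angle + rng.normal(0.0, config.noise_deg_sd, angle.size)
        if config.gyro_noise_dps_sd > 0:
            gyro = gyro + rng.normal(0.0, config.gyro_noise_dps_sd, gyro.size)
        strides.append(
            Stride(
                angle_deg=angle,
                gyro_dps=gyro,
                start_s=t0,
                end_s=t0 + t_eff,
                index_in_trial=i,
                rate_hz=config.rate_hz,
                label=label,
            )
        )
        t0 += t_eff
    return strides


def simulate_trial(
    config: GaitSimConfig,
    library: ModelLibrary | None = None,
) -> SimulatedTrial:
    """Generate a continuous walking trial with ground-truth stride metadata.

    Strides are drawn as in :func:`simulate_strides` and joined end-to-end at
    their boundary minima.  Because each stride waveform is periodic over its
    own duration, successive strides of the same pattern join seamlessly;
    across patterns, the small boundary-value mismatch is absorbed by a
    linear in-stride ramp so the series stays continuous.  White measurement
    noise is added to the assembled angle series, and the gyro channel is the
    analytic derivative of the noiseless angle plus gyro noise.
    """
    library = library or load_model_library()
    rng = np.random.default_rng(config.seed)
    templates = _aligned_templates(library)
    durations = _stride_times(config, rng)

    labels: list[int] = []
    f0s: list[float] = []
    angle_parts: list[np.ndarray] = []
    gyro_parts: list[np.ndarray] = []
    boundary_idx = [0]
    boundaries_s = [0.0]
    prev_start_value: float | None = None
    for i in range(config.n_strides):
        label = config.pattern_sequence[i % len(config.pattern_sequence)]
        angle, gyro, t_eff = _build_stride_waveforms(templates[label], durations[i], config, rng)
        start_value = float(angle[0])
        if prev_start_value is not None and start_value != prev_start_value:
            # periodic end of the previous stride equals its own first sample;
            # ramp this stride so the junction is continuous
            delta = prev_start_value - start_value
            frac = 1.0 - np.arange(angle.size) / angle.size
            angle = angle + delta * frac
            gyro = gyro - delta / t_eff
        prev_start_value = start_value
        labels.append(label)
        f0s.append(1.0 / t_eff)
        angle_parts.append(angle)
        gyro_parts.append(gyro)
        boundary_idx.append(boundary_idx[-1] + angle.size)
        boundaries_s.append(boundaries_s[-1] + t_eff)

    angle_all = np.concatenate(angle_parts)
    gyro_all = np.concatenate(gyro_parts)
    if config.noise_deg_sd > 0:
        angle_all = angle_all + rng.normal(0.0, config.noise_deg_sd, angle_all.size)
    if config.gyro_noise_dps_sd > 0:
        gyro_all = gyro_all + rng.normal(0.0, config.gyro_noise_dps_sd, gyro_all.size)
    times = np.arange(angle_all.size) / config.rate_hz
    series = ThighAngleSeries(times_s=times, angle_deg=angle_all, source="direct", rate_hz=config.rate_hz)
    return SimulatedTrial(
        angle=series,
        gyro_dps=gyro_all,
        labels=tuple(labels),
        boundaries_s=np.asarray(boundaries_s),
        boundary_idx=np.asarray(boundary_idx),
        f0_hz=tuple(f0s),
        config=config,
    )


def simulate_imu(angle: ThighAngleSeries, config: GaitSimConfig) -> ImuRecord:
    """Synthesize a raw 6-axis IMU stream consistent with an angle trajectory.

    The sagittal gyro channel is the numerically differentiated angle plus a
    constant bias and white noise; the accelerometer is the gravity vector
    rotated by the thigh angle in the sagittal plane (so quasi-static
    instants carry the correct inclination) plus white noise.  Linear body
    acceleration is not modeled.
    """
    rng = np.random.default_rng(config.seed + 1)  # decoupled from the trial stream
    t = angle.times_s
    theta = np.radians(angle.angle_deg)
    gyro_y = np.gradient(angle.angle_deg, t) + config.gyro_bias_dps
    if config.gyro_noise_dps_sd > 0:
        gyro_y = gyro_y + rng.normal(0.0, config.gyro_noise_dps_sd, t.size)
    gyro = np.vstack([np.zeros_like(gyro_y), gyro_y, np.zeros_like(gyro_y)])
    accel = np.vstack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    if config.accel_noise_g_sd > 0:
        accel = accel + rng.normal(0.0, config.accel_noise_g_sd, accel.shape)
    return ImuRecord(times_s=t, accel_g=accel, gyro_dps=gyro, rate_hz=angle.rate_hz)
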