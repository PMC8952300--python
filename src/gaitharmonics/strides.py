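"""Stride segmentation, gait-event detection and stride normalization.

A stride (one full gait cycle) is cropped from one thigh-angle minimum to the
next: the minimum of the flexion-extension waveform marks toe-off, which on
the sagittal gyro channel appears as a zero crossing with positive gradient.
Strides are resampled to a fixed number of points and normalized in time
(stride time -> 1 s) and amplitude (range -> [0, 1]) before template
comparison, grouping and averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DegenerateRangeError,
    InputError,
    InsufficientStridesError,
    ToeOffNotFoundError,
)
from .harmonic import HarmonicModel
from .orientation import ThighAngleSeries
from .spectral import compute_spectrum, extract_harmonics, find_fundamental

__all__ = [
    "Stride",
    "NormalizedStride",
    "TemplateGrouping",
    "segment_strides",
    "detect_toe_off",
    "stride_frequency_from_time",
    "cascade_for_fft",
    "normalize_stride",
    "group_by_template",
    "mean_template",
    "fit_stride_model",
]

#: resampling length of a normalized stride
RESAMPLE_POINTS = 2000

#: default number of end-to-end copies before the per-stride FFT
CASCADE_COPIES = 4


@dataclass(frozen=True)
class Stride:
    """One minimum-to-minimum thigh-angle segment, optionally with its gyro."""

    angle_deg: np.ndarray
    start_s: float
    end_s: float
    index_in_trial: int
    gyro_dps: np.ndarray | None = None
    rate_hz: float = 100.0
    label: int | None = None  # ground-truth pattern label when synthetic

    def __post_init__(self) -> None:
        object.__setattr__(self, "angle_deg", np.asarray(self.angle_deg, dtype=float))
        if self.gyro_dps is not None:
            g = np.asarray(self.gyro_dps, dtype=float)
            if g.size != self.angle_deg.size:
                raise InputError("gyro segment must match angle segment length")
            object.__setattr__(self, "gyro_dps", g)
        if self.end_s <= self.start_s:
            raise InputError("stride must have positive duration")

    @property
    def stride_time_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_samples(self) -> int:
        return self.angle_deg.size

    def rel_times(self) -> np.ndarray:
        """Sample times measured from stride start (half-open [0, T))."""
        return np.arange(self.n_samples) * (self.stride_time_s / self.n_samples)


@dataclass(frozen=True)
class NormalizedStride:
    """Stride resampled to a fixed length, time -> [0, 1), amplitude -> [0, 1].

    :func:`normalize_stride` and :func:`mean_template` always produce samples
    spanning exactly [0, 1]; the container itself only requires finite values
    so that intermediate waveform arithmetic (offsets, averages) stays
    representable.
    """

    samples: np.ndarray
    originally_deg_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.size < 2 or not np.all(np.isfinite(s)):
            raise DegenerateRangeError("normalized stride must hold >= 2 finite samples")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class TemplateGrouping:
    """Assignment of normalized strides to template groups by RMSE."""

    groups: dict[int, list[int]]  # template index -> stride indices
    unassigned: list[int]
    rmse: np.ndarray  # strides x templates


def _find_minima(angle: np.ndarray, rate_hz: float, prominence_frac: float, min_separation_s: float) -> np.ndarray:
    """Indices of stride-boundary minima, endpoints included when they qualify.

    Interior minima come from a prominence-thresholded peak search on the
    negated signal; the prominence floor (a fraction of the trial's amplitude
    range) and the minimum separation suppress the secondary loading-response
    dip of the strongly oscillating stride patterns.  An endpoint counts as a
    boundary when the signal leaves it upward and its value sits in the lower
    part of the trial range (a walk recorded from toe-off starts on a
    minimum that an interior-only search would miss).
    """
    amp_range = float(np.max(angle) - np.min(angle))
    if amp_range <= 0:
        return np.empty(0, dtype=int)
    prominence = prominence_frac * amp_range
    distance = max(1, int(round(min_separation_s * rate_hz)))
    idx, _ = find_peaks(-angle, prominence=prominence, distance=distance)
    minima = list(idx)
    low_level = np.min(angle) + prominence
    if angle[0] <= low_level and angle[0] < angle[1]:
        minima.insert(0, 0)
    if angle[-1] <= low_level and angle[-1] < angle[-2]:
        minima.append(angle.size - 1)
    return np.asarray(sorted(set(minima)), dtype=int)


def segment_strides(
    angle: ThighAngleSeries,
    gyro: Sequence[float] | None = None,
    prominence_frac: float = 0.2,
    min_separation_s: float = 0.4,
) -> list[Stride]:
    """Cut a trial into minimum-to-minimum strides, dropping the walk's first and last.

    Each stride spans the half-open interval between consecutive thigh-angle
    minima; the first and the last stride of the walk (gait initiation and
    termination, which do not show steady-state shape) are excluded.  When a
    paired gyro sequence is given, the matching segment travels with each
    stride.
    """
    a = np.asarray(angle.angle_deg, dtype=float)
    minima = _find_minima(a, angle.rate_hz, prominence_frac, min_separation_s)
    if minima.size < 3:
        raise InsufficientStridesError(
            f"found {minima.size} thigh-angle minima; need at least 3 to segment strides"
        )
    g = None if gyro is None else np.asarray(gyro, dtype=float)
    if g is not None and g.size != a.size:
        raise InputError("gyro sequence must match the angle series length")
    strides: list[Stride] = []
    # pairs (minima[j], minima[j+1]) are candidate strides; drop first & last
    for out_idx, j in enumerate(range(1, minima.size - 2)):
        i0, i1 = int(minima[j]), int(minima[j + 1])
        strides.append(
            Stride(
                angle_deg=a[i0:i1],
                gyro_dps=None if g is None else g[i0:i1],
                start_s=float(angle.times_s[i0]),
                end_s=float(angle.times_s[i1]),
                index_in_trial=out_idx,
                rate_hz=angle.rate_hz,
            )
        )
    return strides


def detect_toe_off(gyro_segment: Sequence[float], times: Sequence[float]) -> float:
    """Time of the first gyro zero crossing with positive gradient.

    The crossing instant is linearly interpolated between the bracketing
    samples; the local gradient at a touching zero sample is checked by
    central difference.  Raises when the segment never crosses zero upward.
    """
    g = np.asarray(gyro_segment, dtype=float)
    t = np.asarray(times, dtype=float)
    if g.size != t.size or g.size < 3:
        raise InputError("gyro segment and times must have equal length >= 3")
    for k in range(g.size - 1):
        if g[k] < 0.0 <= g[k + 1]:
            return float(t[k] - g[k] * (t[k + 1] - t[k]) / (g[k + 1] - g[k]))
        if g[k] == 0.0:
            lo, hi = max(0, k - 1), min(g.size - 1, k + 1)
            if (g[hi] - g[lo]) / (t[hi] - t[lo]) > 0:
                return float(t[k])
    raise ToeOffNotFoundError("no positive-gradient zero crossing in gyro segment")


def stride_frequency_from_time(stride_time_s: float) -> float:
    """Fundamental (stride) frequency as the reciprocal of the stride time."""
    if stride_time_s <= 0:
        raise InputError("stride time must be positive")
    return 1.0 / stride_time_s


def cascade_for_fft(stride_samples: Sequence[float], copies: int = CASCADE_COPIES) -> np.ndarray:
    """Repeat a stride end-to-end before the FFT to refine bin resolution.

    Cascading an exact period ``c`` times multiplies the transform length by
    ``c``, placing the fundamental on bin ``c`` and sharpening all harmonic
    bins without altering their amplitudes.
    """
    x = np.asarray(stride_samples, dtype=float)
    if copies < 1:
        raise InputError("copies must be >= 1")
    if x.size == 0:
        raise InputError("empty stride")
    return np.tile(x, copies)


def normalize_stride(stride: Stride, n_points: int = RESAMPLE_POINTS) -> NormalizedStride:
    """Resample a stride to ``n_points`` and normalize time and amplitude.

    Time is mapped to the half-open unit interval (stride time -> 1 s) with
    linear interpolation; amplitude is mapped affinely to [0, 1].
    """
    a = stride.angle_deg
    if a.size < 2:
        raise DegenerateRangeError("stride too short to resample")
    lo, hi = float(np.min(a)), float(np.max(a))
    if not hi > lo:
        raise DegenerateRangeError("stride has no amplitude range")
    u_src = np.arange(a.size) / a.size  # half-open [0, 1)
    u_dst = np.arange(n_points) / n_points
    resampled = np.interp(u_dst, u_src, a)
    return NormalizedStride(samples=(resampled - lo) / (hi - lo), originally_deg_range=(lo, hi))


def _rmse(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x - y) ** 2)))


def group_by_template(
    strides: Sequence[NormalizedStride],
    templates: Sequence[NormalizedStride],
    rmse_cutoff: float = 0.025,
) -> TemplateGrouping:
    """Assign normalized strides to the nearest template within an RMSE cutoff.

    RMSE is computed on the [0, 1] normalized amplitude scale.  A stride
    joins the template with the smallest RMSE provided that RMSE is below the
    cutoff (2.5 % of the normalized range by default); otherwise it is left
    unassigned.
    """
    if any(len(s) != len(templates[0]) for s in strides) or any(
        len(tp) != len(templates[0]) for tp in templates
    ):
        raise InputError("all strides and templates must have equal sample counts")
    rmse = np.empty((len(strides), len(templates)))
    for i, s in enumerate(strides):
        for j, tp in enumerate(templates):
            rmse[i, j] = _rmse(s.samples, tp.samples)
    groups: dict[int, list[int]] = {j: [] for j in range(len(templates))}
    unassigned: list[int] = []
    for i in range(len(strides)):
        j = int(np.argmin(rmse[i]))
        if rmse[i, j] < rmse_cutoff:
            groups[j].append(i)
        else:
            unassigned.append(i)
    return TemplateGrouping(groups=groups, unassigned=unassigned, rmse=rmse)


def mean_template(group: Sequence[NormalizedStride]) -> NormalizedStride:
    """Sample-wise mean of a stride group, re-normalized to unit range."""
    if len(group) == 0:
        raise InputError("cannot average an empty stride group")
    stack = np.stack([s.samples for s in group])
    mean = stack.mean(axis=0)
    lo, hi = float(mean.min()), float(mean.max())
    if not hi > lo:
        raise DegenerateRangeError("mean waveform is constant")
    return NormalizedStride(samples=(mean - lo) / (hi - lo))


def fit_stride_model(
    stride: Stride,
    n_harmonics: int = 5,
    channel: str = "angle",
    cascade_copies: int = CASCADE_COPIES,
    f0_from_stride_time: bool = True,
    signal_kind: str | None = None,
) -> HarmonicModel:
    """Extract a harmonic model from a single stride.

    The stride is cascaded end-to-end ``cascade_copies`` times, the FFT
    spectrum computed, and amplitudes/phases read at integer multiples of the
    fundamental.  The fundamental is the reciprocal of the stride time by
    default (accurate to a small fraction of a percent of the FFT estimate);
    set ``f0_from_stride_time=False`` to use the highest spectral peak
    instead.
    """
    if channel == "angle":
        samples = stride.angle_deg
        kind = signal_kind or "thigh_angle_deg"
    elif channel == "gyro":
        if stride.gyro_dps is None:
            raise InputError("stride carries no gyro segment")
        samples = stride.gyro_dps
        kind = signal_kind or "gyro_dps"
    else:
        raise ValueError(f"unknown channel {channel!r}")
    cascaded = cascade_for_fft(samples, cascade_copies)
    # effective rate keeps the cascaded copies exactly one stride time long each
    rate = samples.size / stride.stride_time_s
    spec = compute_spectrum(cascaded, rate)
    if f0_from_stride_time:
        f0 = stride_frequency_from_time(stride.stride_time_s)
    else:
        f0, _ = find_fundamental(spec)
    hs = extract_harmonics(spec, f0, n_harmonics)
    return hs.to_model(signal_kind=kind)
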