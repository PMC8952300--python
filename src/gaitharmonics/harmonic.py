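"""Harmonic (Fourier-series) model of periodic gait signals.

A stride cycle of the thigh flexion-extension angle (or of the sagittal gyro
signal) during level walking is modeled as a truncated Fourier series

    y(t) = b + sum_{n=1}^{N} a_n * cos(2*pi*n*f0*t + phi_n)

where ``f0`` is the fundamental (stride) frequency, ``a_n`` and ``phi_n`` the
amplitude and initial phase of the n-th harmonic, and ``b`` the DC offset.
Five harmonics suffice for the thigh angle and nine for the gyro signal.

The module also bundles a library of twelve published template models — six
thigh-angle and six gyro stride patterns, amplitude-normalized to the
fundamental (``a_1 = 1``) — and the amplitude-normalization helpers used when
comparing measured strides with model reconstructions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import DegenerateRangeError, FormatError, InvalidModelError

__all__ = [
    "HarmonicModel",
    "TimeGrid",
    "ModelLibrary",
    "reconstruct",
    "normalize_to_unit_range",
    "rescale_to_reference",
    "load_model_library",
]

TWO_PI = 2.0 * np.pi

#: Signal kinds a model may describe.
SIGNAL_KINDS = ("thigh_angle_deg", "gyro_dps", "normalized")

#: Grid resolution used when materializing a template over one period.
TEMPLATE_POINTS = 2000


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid: ``times[k] = start_s + k / rate_hz``.

    The sample count is ``round(duration_s * rate_hz)`` and must be >= 2;
    the grid covers the half-open interval ``[start_s, start_s + duration_s)``.
    """

    start_s: float = 0.0
    duration_s: float = 1.0
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise InvalidModelError("duration_s and rate_hz must be positive")
        if self.n_samples < 2:
            raise InvalidModelError("grid must contain at least 2 samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.rate_hz


@dataclass(frozen=True)
class HarmonicModel:
    """Truncated Fourier-series model of one periodic gait signal.

    Parameters
    ----------
    dc_offset
        DC component ``b``, in the units of the signal.
    fundamental_hz
        Fundamental (stride) frequency ``f0`` in Hz; must be positive.
    amplitudes
        Harmonic amplitudes ``a_1 .. a_N`` (non-negative).
    phases
        Initial phases ``phi_1 .. phi_N`` in radians, cosine convention.
    signal_kind
        One of ``thigh_angle_deg``, ``gyro_dps`` or ``normalized``.  Library
        templates are ``normalized`` with ``a_1 = 1``.
    label
        Optional integer pattern label (1-6 for library models).
    """

    dc_offset: float
    fundamental_hz: float
    amplitudes: tuple[float, ...]
    phases: tuple[float, ...]
    signal_kind: str = "normalized"
    label: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "phases", tuple(float(p) for p in self.phases))
        if self.fundamental_hz <= 0:
            raise InvalidModelError(f"fundamental_hz must be > 0, got {self.fundamental_hz}")
        if len(self.amplitudes) == 0:
            raise InvalidModelError("model must have at least one harmonic")
        if len(self.amplitudes) != len(self.phases):
            raise InvalidModelError("amplitudes and phases must have equal length")
        if any(a < 0 for a in self.amplitudes):
            raise InvalidModelError("amplitudes must be non-negative")
        if self.signal_kind not in SIGNAL_KINDS:
            raise InvalidModelError(f"unknown signal_kind {self.signal_kind!r}")

    @property
    def n_harmonics(self) -> int:
        return len(self.amplitudes)

    @property
    def period_s(self) -> float:
        return 1.0 / self.fundamental_hz

    def at_fundamental(self, f0_hz: float) -> "HarmonicModel":
        """Return a copy with the fundamental frequency replaced by ``f0_hz``."""
        return replace(self, fundamental_hz=float(f0_hz))

    def with_min_zero_dc(self, n_points: int = TEMPLATE_POINTS) -> "HarmonicModel":
        """Return a copy whose DC offset makes the one-period minimum equal 0.

        The tables publish no DC term for the templates; because all
        comparisons go through affine amplitude rescaling, any DC choice is
        equivalent and the minimum-at-zero convention matches the [0, 1]
        normalization used for measured strides.
        """
        grid = TimeGrid(0.0, self.period_s, n_points / self.period_s)
        y = reconstruct(replace(self, dc_offset=0.0), grid)
        return replace(self, dc_offset=-float(np.min(y)))

    def aligned_to_start(self, mode: str = "min", n_points: int = 20 * TEMPLATE_POINTS) -> "HarmonicModel":
        """Return a copy time-shifted so that t = 0 is the stride boundary.

        ``mode='min'`` places the waveform minimum (toe-off of the thigh-angle
        cycle) at t = 0; ``mode='zero_up'`` places the first positive-gradient
        zero crossing there (the toe-off marker of the gyro signal).  Shifting
        by ``tau`` maps ``phi_n -> phi_n + 2*pi*n*f0*tau`` (mod 2*pi).
        """
        grid = TimeGrid(0.0, self.period_s, n_points / self.period_s)
        y = reconstruct(self, grid)
        t = grid.times()
        if mode == "min":
            tau = float(t[int(np.argmin(y))])
        elif mode == "zero_up":
            yc = y - np.mean(y)
            up = np.nonzero((yc[:-1] <= 0) & (yc[1:] > 0))[0]
            if up.size == 0:
                raise InvalidModelError("waveform has no positive-gradient zero crossing")
            k = int(up[0])
            # linear interpolation of the crossing instant
            tau = float(t[k] - yc[k] * (t[k + 1] - t[k]) / (yc[k + 1] - yc[k]))
        else:
            raise ValueError(f"unknown alignment mode {mode!r}")
        n = np.arange(1, self.n_harmonics + 1)
        new_phases = np.mod(np.asarray(self.phases) + TWO_PI * n * self.fundamental_hz * tau, TWO_PI)
        return replace(self, phases=tuple(new_phases))


@dataclass(frozen=True)
class ModelLibrary:
    """The bundled six thigh-angle and six gyro template models."""

    thigh_models: tuple[HarmonicModel, ...]
    gyro_models: tuple[HarmonicModel, ...]
    labels: tuple[int, ...] = field(default=(1, 2, 3, 4, 5, 6))

    def models(self, channel: str) -> tuple[HarmonicModel, ...]:
        if channel == "angle":
            return self.thigh_models
        if channel == "gyro":
            return self.gyro_models
        raise ValueError(f"unknown channel {channel!r}")


def reconstruct(model: HarmonicModel, grid: TimeGrid) -> np.ndarray:
    """Evaluate the Fourier series on a sampling grid.

    Returns ``y[k] = b + sum_n a_n * cos(2*pi*n*f0*t_k + phi_n)`` for every
    grid time ``t_k``.
    """
    t = grid.times()
    n = np.arange(1, model.n_harmonics + 1)
    phase_matrix = TWO_PI * model.fundamental_hz * np.outer(n, t) + np.asarray(model.phases)[:, None]
    return model.dc_offset + np.asarray(model.amplitudes) @ np.cos(phase_matrix)


def reconstruct_derivative(model: HarmonicModel, grid: TimeGrid) -> np.ndarray:
    """Analytic time derivative of :func:`reconstruct` on the same grid.

    For a thigh-angle model in degrees this yields the ideal sagittal gyro
    signal in degrees per second.
    """
    t = grid.times()
    n = np.arange(1, model.n_harmonics + 1)
    omega = TWO_PI * n * model.fundamental_hz
    phase_matrix = omega[:, None] * t + np.asarray(model.phases)[:, None]
    return -(np.asarray(model.amplitudes) * omega) @ np.sin(phase_matrix)


def normalize_to_unit_range(signal: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Map a signal affinely onto [0, 1].

    Returns ``(normalized, offset, scale)`` with
    ``normalized = (signal - offset) / scale`` where ``offset = min(signal)``
    and ``scale = max(signal) - min(signal)``; the original signal is exactly
    ``offset + scale * normalized``.

    Raises
    ------
    DegenerateRangeError
        If the signal is constant (max <= min) or shorter than 2 samples.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise DegenerateRangeError("need at least 2 samples to normalize")
    lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        raise DegenerateRangeError("constant signal has no amplitude range")
    return (x - lo) / (hi - lo), lo, hi - lo


def rescale_to_reference(normalized: Sequence[float], reference: Sequence[float]) -> np.ndarray:
    """Affinely rescale a waveform so its extrema match a reference signal.

    The output has the reference's minimum and maximum (peak-to-peak match)
    while preserving the waveform's shape — the operation used to put a
    normalized model reconstruction back into measured degrees.
    """
    x = np.asarray(normalized, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape != ref.shape:
        raise DegenerateRangeError("normalized and reference must have equal length")
    ref_lo, ref_hi = float(np.min(ref)), float(np.max(ref))
    if not ref_hi > ref_lo:
        raise DegenerateRangeError("reference signal has no amplitude range")
    unit, _, _ = normalize_to_unit_range(x)
    return ref_lo + unit * (ref_hi - ref_lo)


def _model_from_dict(entry: dict, signal_kind: str) -> HarmonicModel:
    try:
        harmonics = sorted(entry["harmonics"], key=lambda h: h["n"])
        ns = [h["n"] for h in harmonics]
        if ns != list(range(1, len(ns) + 1)):
            raise FormatError(f"harmonic indices must be 1..N, got {ns}")
        return HarmonicModel(
            dc_offset=float(entry["dc_offset"]),
            fundamental_hz=float(entry["fundamental_hz"]),
            amplitudes=tuple(h["amplitude"] for h in harmonics),
            phases=tuple(h["phase_rad"] for h in harmonics),
            signal_kind=signal_kind,
            label=entry.get("label"),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed model entry: {exc}") from exc


def _load_packaged(name: str) -> list[HarmonicModel]:
    text = resources.files("gaitharmonics.data").joinpath(name).read_text()
    doc = json.loads(text)
    kind = doc.get("signal_kind", "normalized")
    models = [_model_from_dict(e, kind) for e in doc["models"]]
    for m in models:
        if m.amplitudes[0] != 1.0:
            raise FormatError(f"library model {m.label}: a_1 must be exactly 1, got {m.amplitudes[0]}")
    return models


def load_model_library(min_zero_dc: bool = True) -> ModelLibrary:
    """Load the packaged six thigh-angle and six gyro template models.

    Amplitudes are normalized to the fundamental (``a_1 = 1``) and phases are
    stored in radians exactly as published.  The tables publish no DC term;
    with ``min_zero_dc=True`` (the default) each thigh-angle model's DC
    offset is set so the reconstructed one-period minimum is 0, matching the
    [0, 1] stride normalization convention.  Gyro models keep DC = 0: angular
    velocity integrates to zero over a cycle, and a zero-mean template keeps
    the toe-off zero crossing physically meaningful.  Either choice is
    equivalent under the affine rescaling used for classification.
    """
    thigh = _load_packaged("thigh_models.json")
    gyro = _load_packaged("gyro_models.json")
    if min_zero_dc:
        thigh = [m.with_min_zero_dc() for m in thigh]
    return ModelLibrary(thigh_models=tuple(thigh), gyro_models=tuple(gyro))
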