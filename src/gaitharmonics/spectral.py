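"""FFT spectrum computation and harmonic peak extraction.

The spectrum is one-sided and amplitude-calibrated so that a pure cosine
``A*cos(2*pi*f*t + phi)`` sampled over an integer number of periods shows
amplitude ``A`` and phase ``phi`` at the bin of ``f`` — i.e. the spectral
coefficients are directly the Fourier-series coefficients of the model.  The
transform length equals the input length (no zero-padding to a power of two),
so a signal cascaded to ``c`` copies of an exact period puts its fundamental
exactly on bin ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import HarmonicRangeError, NoFundamentalError, SpectrumError
from .harmonic import TWO_PI, HarmonicModel

__all__ = [
    "Spectrum",
    "HarmonicSet",
    "compute_spectrum",
    "find_fundamental",
    "extract_harmonics",
    "significant_harmonic_count",
]

_MIN_SAMPLES = 8


@dataclass(frozen=True)
class Spectrum:
    """One-sided amplitude/phase spectrum.

    ``freqs_hz``/``amplitudes``/``phases_rad`` cover bins 1..floor(L/2); the
    DC term is kept separately in ``dc`` (signed, equal to the signal mean).
    ``n_input`` is the transform length L.
    """

    freqs_hz: np.ndarray
    amplitudes: np.ndarray
    phases_rad: np.ndarray
    dc: float
    n_input: int
    rate_hz: float

    @property
    def bin_width_hz(self) -> float:
        return self.rate_hz / self.n_input

    @property
    def nyquist_hz(self) -> float:
        return self.rate_hz / 2.0


@dataclass(frozen=True)
class HarmonicSet:
    """Amplitudes and phases read off the spectrum at multiples of f0."""

    fundamental_hz: float
    amplitudes: tuple[float, ...]
    phases_rad: tuple[float, ...]
    dc: float

    @property
    def n_harmonics(self) -> int:
        return len(self.amplitudes)

    def normalized_amplitudes(self) -> np.ndarray:
        """Amplitudes divided by the fundamental amplitude (a_n / a_1)."""
        a = np.asarray(self.amplitudes)
        if a[0] == 0:
            raise NoFundamentalError("fundamental amplitude is zero")
        return a / a[0]

    def to_model(self, signal_kind: str = "thigh_angle_deg", label: int | None = None) -> HarmonicModel:
        return HarmonicModel(
            dc_offset=self.dc,
            fundamental_hz=self.fundamental_hz,
            amplitudes=self.amplitudes,
            phases=self.phases_rad,
            signal_kind=signal_kind,
            label=label,
        )


def compute_spectrum(signal: Sequence[float], rate_hz: float) -> Spectrum:
    """One-sided, amplitude-calibrated FFT spectrum of a real signal.

    The transform length equals the signal length.  Amplitudes are
    ``2|X_k|/L`` for bins ``1 <= k < L/2`` (``|X_{L/2}|/L`` at Nyquist when L
    is even), the DC term is ``X_0/L`` (the mean), and phases are the complex
    angles at each bin (cosine reference).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise SpectrumError("signal must be one-dimensional")
    L = x.size
    if L < _MIN_SAMPLES:
        raise SpectrumError(f"need at least {_MIN_SAMPLES} samples, got {L}")
    X = np.fft.rfft(x)
    amps = 2.0 * np.abs(X[1:]) / L
    if L % 2 == 0:  # Nyquist bin has no mirror; do not double it
        amps[-1] = np.abs(X[-1]) / L
    return Spectrum(
        freqs_hz=np.fft.rfftfreq(L, 1.0 / rate_hz)[1:],
        amplitudes=amps,
        phases_rad=np.angle(X[1:]),
        dc=float(X[0].real / L),
        n_input=L,
        rate_hz=float(rate_hz),
    )


def find_fundamental(spec: Spectrum, rel_tol: float = 1e-12) -> tuple[float, int]:
    """Locate the fundamental as the highest-amplitude non-DC bin.

    Returns ``(f0_hz, bin_index)`` where the bin index counts from 1 in the
    full transform.  Ties break toward the lower frequency.  The stride
    frequency dominates the gait spectrum, which is what makes this rule work.
    """
    if spec.amplitudes.size < 2:
        raise NoFundamentalError("spectrum has fewer than 2 non-DC bins")
    k = int(np.argmax(spec.amplitudes))  # argmax returns the first (lowest-f) maximum
    peak = spec.amplitudes[k]
    if peak <= rel_tol * max(1.0, abs(spec.dc)):
        raise NoFundamentalError("spectrum has no non-zero peak")
    return float(spec.freqs_hz[k]), k + 1


def extract_harmonics(spec: Spectrum, f0_hz: float, n_harmonics: int) -> HarmonicSet:
    """Read amplitudes and initial phases at integer multiples of ``f0_hz``.

    For each harmonic n the amplitude/phase is taken at the largest-amplitude
    bin within +/-1 bin of the nearest bin to ``n*f0`` — a local peak search
    that tolerates a fundamental slightly off the FFT grid.  Phases are
    wrapped to [0, 2*pi) in the cosine convention of the harmonic model; the
    DC component is carried over from the spectrum.
    """
    if n_harmonics < 1:
        raise HarmonicRangeError("n_harmonics must be >= 1")
    if f0_hz <= 0:
        raise NoFundamentalError("f0 must be positive")
    df = spec.bin_width_hz
    n_bins = spec.amplitudes.size
    amps: list[float] = []
    phases: list[float] = []
    for n in range(1, n_harmonics + 1):
        target = n * f0_hz
        if target >= spec.nyquist_hz:
            raise HarmonicRangeError(
                f"harmonic {n} at {target:g} Hz is at/above Nyquist ({spec.nyquist_hz:g} Hz)"
            )
        k0 = int(round(target / df))  # bin index in the full transform
        lo = max(1, k0 - 1)
        hi = min(n_bins, k0 + 1)
        window = np.arange(lo, hi + 1)
        k = int(window[np.argmax(spec.amplitudes[window - 1])])
        amps.append(float(spec.amplitudes[k - 1]))
        phases.append(float(np.mod(spec.phases_rad[k - 1], TWO_PI)))
    return HarmonicSet(
        fundamental_hz=float(f0_hz),
        amplitudes=tuple(amps),
        phases_rad=tuple(phases),
        dc=spec.dc,
    )


def significant_harmonic_count(
    normalized_amplitude_rows: Sequence[Sequence[float]] | np.ndarray,
    cutoff_fraction: float = 0.01,
) -> int:
    """Number of significant harmonics under the 1 %-of-fundamental rule.

    Each row holds one stride's amplitudes normalized to its fundamental
    (``a_n / a_1``, so column 0 is all ones).  The count is the largest N such
    that the across-stride median of ``a_n / a_1`` stays at or above
    ``cutoff_fraction`` for every ``n <= N``.  The fundamental is always
    significant, so the result is at least 1.
    """
    rows = np.atleast_2d(np.asarray(normalized_amplitude_rows, dtype=float))
    if rows.size == 0:
        raise SpectrumError("empty amplitude table")
    medians = np.median(rows, axis=0)
    count = 1
    for n in range(2, medians.size + 1):
        if medians[n - 1] >= cutoff_fraction:
            count = n
        else:
            break
    return count
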