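"""Exception hierarchy for gaitharmonics.

All package-specific failures derive from :class:`GaitError` so callers can
catch a single base class at pipeline boundaries (e.g. the CLI).
"""


class GaitError(Exception):
    """Base class for all gaitharmonics errors."""


class InvalidModelError(GaitError):
    """A harmonic model violates its invariants (f0 <= 0, empty harmonics, ...)."""


class DegenerateRangeError(GaitError):
    """A signal has no amplitude range (max <= min) where one is required."""


class SpectrumError(GaitError):
    """Spectrum computation received an unusable input (e.g. too short)."""


class NoFundamentalError(GaitError):
    """No non-zero spectral peak exists to serve as the fundamental."""


class HarmonicRangeError(GaitError):
    """A requested harmonic lies at or above the Nyquist frequency."""


class InsufficientStridesError(GaitError):
    """Too few thigh-angle minima to segment any stride."""


class ToeOffNotFoundError(GaitError):
    """No positive-gradient zero crossing exists in a gyro segment."""


class ConstantInputError(GaitError):
    """A correlation was requested on a constant (zero-variance) sequence."""


class FormatError(GaitError):
    """A file did not conform to the expected CSV/JSON dialect."""


class InputError(GaitError):
    """Structurally invalid in-memory input (non-monotone time, bad axis, ...)."""
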