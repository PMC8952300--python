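"""Trial prediction and template classification of strides.

A whole walking trial can be regenerated from the harmonic model of its first
stride: each stride is reconstructed with the fundamental set to the
reciprocal of that stride's time and rescaled to the stride's measured
amplitude range.  Conversely, every stride can be scored against the six
library stride patterns by reconstructing each template at the stride's
fundamental, rescaling, and computing the Pearson correlation and RMSE — the
best pattern is the one with the highest correlation (and, almost always, the
smallest RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConstantInputError, InputError
from .harmonic import (
    HarmonicModel,
    ModelLibrary,
    TimeGrid,
    reconstruct,
    rescale_to_reference,
)
from .strides import Stride, fit_stride_model

__all__ = [
    "ClassificationMatrix",
    "PredictionResult",
    "pearson_correlation",
    "rmse",
    "classify_strides",
    "predict_trial",
    "align_library",
    "regeneration_metrics",
]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length sequences."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 2:
        raise InputError("sequences must have equal length >= 2")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(np.corrcoef(xa, ya)[0, 1])


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length sequences."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 1:
        raise InputError("sequences must have equal length >= 1")
    return float(np.sqrt(np.mean((xa - ya) ** 2)))


@dataclass(frozen=True)
class ClassificationMatrix:
    """Per-stride correlation and RMSE against every library model.

    ``correlations`` and ``rmses`` are strides x models; ``best_model`` holds
    the 1-based label of the highest-correlation model per stride (ties break
    toward the lower label).  When the RMSE minimum points to a different
    model than the correlation maximum, the stride is flagged in
    ``disagreement``.
    """

    correlations: np.ndarray
    rmses: np.ndarray
    best_model: np.ndarray
    disagreement: np.ndarray
    stride_labels: tuple[int, ...]
    model_labels: tuple[int, ...]

    @property
    def rmse_best_model(self) -> np.ndarray:
        return np.asarray(self.model_labels)[np.argmin(self.rmses, axis=1)]


@dataclass(frozen=True)
class PredictionResult:
    """Reconstruction of a full trial from a single harmonic model."""

    times_s: np.ndarray
    predicted_deg: np.ndarray
    measured_deg: np.ndarray
    correlation: float
    rmse_deg: float
    per_stride_correlation: np.ndarray
    per_stride_rmse_deg: np.ndarray
    skipped: tuple[int, ...]


def align_library(library: ModelLibrary) -> ModelLibrary:
    """Time-shift every template so t = 0 sits on the stride boundary.

    Thigh-angle templates are shifted so their one-period minimum (toe-off)
    is at t = 0, matching the minimum-to-minimum stride cropping; gyro
    templates are shifted to their positive-gradient zero crossing, the gyro
    signature of toe-off.  The published coefficients already encode this
    alignment closely, so the shifts are small; applying them exactly removes
    any residual lag between measured strides and reconstructed templates.
    """
    return ModelLibrary(
        thigh_models=tuple(m.aligned_to_start("min") for m in library.thigh_models),
        gyro_models=tuple(m.aligned_to_start("zero_up") for m in library.gyro_models),
        labels=library.labels,
    )


def _stride_grid(stride: Stride) -> TimeGrid:
    # grid matching the stride's own samples: L points over [0, T)
    return TimeGrid(0.0, stride.stride_time_s, stride.n_samples / stride.stride_time_s)


def classify_strides(
    strides: Sequence[Stride],
    library: ModelLibrary,
    channel: str = "angle",
    align: bool = True,
) -> ClassificationMatrix:
    """Score every stride against the six library models.

    For each stride and model, the template is reconstructed at the stride's
    fundamental (1 / stride time) on the stride's own sampling grid, rescaled
    to the stride's amplitude range, and compared by Pearson correlation and
    RMSE (in the stride's units).  No lag search is performed: both the
    stride and the aligned template start at toe-off.
    """
    if len(strides) == 0:
        raise InputError("no strides to classify")
    lib = align_library(library) if align else library
    models = lib.models(channel)
    corr = np.empty((len(strides), len(models)))
    err = np.empty((len(strides), len(models)))
    for i, stride in enumerate(strides):
        if channel == "angle":
            measured = stride.angle_deg
        else:
            if stride.gyro_dps is None:
                raise InputError(f"stride {i} carries no gyro segment")
            measured = stride.gyro_dps
        grid = _stride_grid(stride)
        f0 = 1.0 / stride.stride_time_s
        for j, model in enumerate(models):
            recon = reconstruct(model.at_fundamental(f0), grid)
            rescaled = rescale_to_reference(recon, measured)
            corr[i, j] = pearson_correlation(rescaled, measured)
            err[i, j] = rmse(rescaled, measured)
    model_labels = tuple(lib.labels)
    best = np.asarray(model_labels)[np.argmax(corr, axis=1)]
    disagreement = best != np.asarray(model_labels)[np.argmin(err, axis=1)]
    return ClassificationMatrix(
        correlations=corr,
        rmses=err,
        best_model=best,
        disagreement=disagreement,
        stride_labels=tuple(s.index_in_trial for s in strides),
        model_labels=model_labels,
    )


def regeneration_metrics(
    strides: Sequence[Stride],
    n_harmonics: int = 5,
    channel: str = "angle",
    cascade_copies: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stride regeneration accuracy of the harmonic model.

    For each stride, a harmonic model with ``n_harmonics`` components is
    extracted from the stride's own cascaded spectrum and the stride is
    reconstructed from it; the returned arrays hold the Pearson correlation
    and the RMSE (in the stride's units) between each stride and its
    reconstruction — the quantity summarized as "regeneration accuracy".
    """
    if len(strides) == 0:
        raise InputError("no strides to evaluate")
    corrs = np.empty(len(strides))
    errs = np.empty(len(strides))
    for i, stride in enumerate(strides):
        model = fit_stride_model(
            stride, n_harmonics=n_harmonics, channel=channel, cascade_copies=cascade_copies
        )
        recon = reconstruct(model, _stride_grid(stride))
        measured = stride.angle_deg if channel == "angle" else stride.gyro_dps
        corrs[i] = pearson_correlation(recon, measured)
        errs[i] = rmse(recon, measured)
    return corrs, errs


def predict_trial(
    trial_strides: Sequence[Stride],
    model: HarmonicModel,
    rescale_rule: str = "peak_to_peak",
) -> PredictionResult:
    """Regenerate a trial from one harmonic model, stride by stride.

    Each stride is reconstructed with the fundamental set to the reciprocal
    of its stride time.  With the default ``peak_to_peak`` rule the
    reconstruction is affinely rescaled to the stride's measured min/max;
    with ``max_as_fundamental`` the harmonic amplitudes are scaled so the
    fundamental amplitude equals the stride's maximum angle and the DC term
    matches the stride mean.  Strides with a degenerate amplitude range are
    skipped and reported.
    """
    if len(trial_strides) == 0:
        raise InputError("no strides to predict")
    if rescale_rule not in ("peak_to_peak", "max_as_fundamental"):
        raise ValueError(f"unknown rescale rule {rescale_rule!r}")
    pieces_t: list[np.ndarray] = []
    pieces_pred: list[np.ndarray] = []
    pieces_meas: list[np.ndarray] = []
    per_corr: list[float] = []
    per_rmse: list[float] = []
    skipped: list[int] = []
    for stride in trial_strides:
        measured = stride.angle_deg
        if np.ptp(measured) == 0:
            skipped.append(stride.index_in_trial)
            continue
        grid = _stride_grid(stride)
        f0 = 1.0 / stride.stride_time_s
        recon = reconstruct(model.at_fundamental(f0), grid)
        if rescale_rule == "peak_to_peak":
            pred = rescale_to_reference(recon, measured)
        else:
            scale = float(np.max(measured)) / model.amplitudes[0]
            harmonic_part = (recon - model.dc_offset) * scale
            pred = harmonic_part + (float(np.mean(measured)) - float(np.mean(harmonic_part)))
        pieces_t.append(stride.start_s + grid.times())
        pieces_pred.append(pred)
        pieces_meas.append(measured)
        per_corr.append(pearson_correlation(pred, measured))
        per_rmse.append(rmse(pred, measured))
    if not pieces_pred:
        raise InputError("all strides were degenerate; nothing predicted")
    predicted = np.concatenate(pieces_pred)
    measured_all = np.concatenate(pieces_meas)
    return PredictionResult(
        times_s=np.concatenate(pieces_t),
        predicted_deg=predicted,
        measured_deg=measured_all,
        correlation=pearson_correlation(predicted, measured_all),
        rmse_deg=rmse(predicted, measured_all),
        per_stride_correlation=np.asarray(per_corr),
        per_stride_rmse_deg=np.asarray(per_rmse),
        skipped=tuple(skipped),
    )
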