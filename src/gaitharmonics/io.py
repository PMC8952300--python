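"""File I/O: IMU and angle CSV dialects, model JSON, matrix export.

CSV dialects (strict headers, time in seconds, angles in degrees, angular
rates in degrees per second):

* IMU:   ``time_s,ax_g,ay_g,az_g,gx_dps,gy_dps,gz_dps``
* angle: ``time_s,angle_deg``

Model JSON follows the packaged library schema:
``{"signal_kind", "fundamental_hz", "dc_offset", "harmonics": [{"n",
"amplitude", "phase_rad"}, ...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassificationMatrix
from .errors import FormatError
from .harmonic import HarmonicModel, _model_from_dict
from .orientation import ImuRecord, ThighAngleSeries
from .strides import NormalizedStride

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "read_angle_csv",
    "write_angle_csv",
    "read_model_json",
    "write_model_json",
    "write_matrix_csv",
    "write_matrix_json",
    "write_normalized_stride_csv",
]

IMU_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]
ANGLE_COLUMNS = ["time_s", "angle_deg"]


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if list(df.columns) != columns:
        raise FormatError(f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: missing/NaN value at line {row}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        row = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 3
        raise FormatError(f"{path}: time_s not strictly increasing at line {row}")
    return df


def _infer_rate(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 100.0


def read_imu_csv(path: str | Path) -> ImuRecord:
    """Parse a raw 6-axis IMU CSV into an :class:`ImuRecord`."""
    df = _read_csv(path, IMU_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    return ImuRecord(
        times_s=t,
        accel_g=df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float).T,
        gyro_dps=df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(dtype=float).T,
        rate_hz=_infer_rate(t),
    )


def write_imu_csv(imu: ImuRecord, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": imu.times_s,
            "ax_g": imu.accel_g[0],
            "ay_g": imu.accel_g[1],
            "az_g": imu.accel_g[2],
            "gx_dps": imu.gyro_dps[0],
            "gy_dps": imu.gyro_dps[1],
            "gz_dps": imu.gyro_dps[2],
        }
    ).to_csv(path, index=False)


def read_angle_csv(path: str | Path) -> ThighAngleSeries:
    """Parse a thigh-angle CSV into a :class:`ThighAngleSeries`."""
    df = _read_csv(path, ANGLE_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    return ThighAngleSeries(
        times_s=t,
        angle_deg=df["angle_deg"].to_numpy(dtype=float),
        source="direct",
        rate_hz=_infer_rate(t),
    )


def write_angle_csv(series: ThighAngleSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.times_s, "angle_deg": series.angle_deg}).to_csv(path, index=False)


def model_to_dict(model: HarmonicModel) -> dict:
    return {
        "signal_kind": model.signal_kind,
        "fundamental_hz": model.fundamental_hz,
        "dc_offset": model.dc_offset,
        "label": model.label,
        "harmonics": [
            {"n": n, "amplitude": a, "phase_rad": p}
            for n, (a, p) in enumerate(zip(model.amplitudes, model.phases), start=1)
        ],
    }


def write_model_json(model: HarmonicModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def read_model_json(path: str | Path) -> HarmonicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "harmonics" not in doc:
        raise FormatError(f"{path}: not a harmonic-model document")
    return _model_from_dict(doc, doc.get("signal_kind", "normalized"))


def write_matrix_csv(matrix: ClassificationMatrix, path: str | Path, kind: str = "correlation") -> None:
    """Export a classification matrix with models as rows, strides as columns."""
    values = matrix.correlations if kind == "correlation" else matrix.rmses
    df = pd.DataFrame(
        values.T,
        index=[f"model_{m}" for m in matrix.model_labels],
        columns=[f"stride_{s}" for s in matrix.stride_labels],
    )
    df.to_csv(path, index_label=kind)


def write_matrix_json(matrix: ClassificationMatrix, path: str | Path) -> None:
    doc = {
        "model_labels": list(matrix.model_labels),
        "stride_labels": list(matrix.stride_labels),
        "correlations": matrix.correlations.tolist(),
        "rmses": matrix.rmses.tolist(),
        "best_model": matrix.best_model.tolist(),
        "disagreement": matrix.disagreement.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def write_normalized_stride_csv(stride: NormalizedStride, path: str | Path) -> None:
    """One normalized amplitude per row, with a JSON sidecar for metadata."""
    path = Path(path)
    pd.DataFrame({"amplitude": stride.samples}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "n_points": int(len(stride)),
                "originally_deg_range": list(stride.originally_deg_range),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
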