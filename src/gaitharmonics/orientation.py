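"""Single-axis thigh-angle estimation from raw 6-axis IMU data.

The thigh flexion-extension angle is obtained primarily by integrating the
sagittal-plane gyro channel; because rate-gyro bias makes a pure integral
drift, the estimate is blended toward the accelerometer inclination angle
whenever the accelerometer magnitude is close to 1 g (a quasi-static instant,
when the measured specific force is essentially gravity and therefore encodes
orientation).  This is a deliberately minimal one-axis complementary filter:
it trades the full orientation-filter machinery for the single drift-stable
sagittal angle the gait pipeline needs.

Axis convention (thigh-mounted sensor): x anterior in the sagittal plane,
y mediolateral (the rotation axis of flexion-extension), z along the thigh,
pointing up when the wearer stands.  At zero thigh angle the accelerometer
reads (0, 0, 1) g; at angle theta it reads (sin theta, 0, cos theta) g, so
the inclination is ``atan2(ax, az)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = ["ImuRecord", "ThighAngleSeries", "GiofConfig", "estimate_thigh_angle"]

#: standard gravity, m/s^2 (accelerometer channels are consumed in g units)
STANDARD_GRAVITY = 9.80665


@dataclass(frozen=True)
class ImuRecord:
    """Raw 6-axis IMU stream: 3-axis accelerometer (g) + 3-axis gyro (deg/s)."""

    times_s: np.ndarray
    accel_g: np.ndarray  # shape (3, L)
    gyro_dps: np.ndarray  # shape (3, L)
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.accel_g, dtype=float)
        g = np.asarray(self.gyro_dps, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "accel_g", a)
        object.__setattr__(self, "gyro_dps", g)
        if a.shape != (3, t.size) or g.shape != (3, t.size):
            raise InputError("accel_g and gyro_dps must both be 3 x len(times_s)")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise InputError("times_s must be strictly increasing with >= 2 samples")
        med_dt = float(np.median(np.diff(t)))
        if abs(med_dt * self.rate_hz - 1.0) > 0.05:
            raise InputError(
                f"median sample interval {med_dt:g} s deviates > 5% from 1/{self.rate_hz:g} Hz"
            )

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class ThighAngleSeries:
    """Thigh flexion-extension angle over time, degrees, flexion positive."""

    times_s: np.ndarray
    angle_deg: np.ndarray
    source: str = "giof"  # 'giof' (estimated from IMU) or 'direct'
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.angle_deg, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "angle_deg", a)
        if t.size != a.size:
            raise InputError("times_s and angle_deg must have equal length")
        if not np.all(np.isfinite(a)):
            raise InputError("angle_deg contains non-finite values")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class GiofConfig:
    """Configuration of the gyro-integration orientation filter.

    alpha
        Blend weight toward the accelerometer inclination at each
        quasi-static sample (0 disables correction; 0.02 at 100 Hz gives a
        correction time constant of roughly half a second).
    quasi_static_tol_g
        A sample is quasi-static when ``| ||accel|| - 1 g |`` is within this
        tolerance.
    sagittal_gyro_axis
        Index of the gyro channel measuring flexion-extension rate (y = 1).
    forward_accel_axis / longitudinal_accel_axis
        Accelerometer channels spanning the sagittal plane; the inclination
        is ``atan2(accel[forward], accel[longitudinal])``.
    """

    alpha: float = 0.02
    quasi_static_tol_g: float = 0.05
    sagittal_gyro_axis: int = 1
    forward_accel_axis: int = 0
    longitudinal_accel_axis: int = 2
    initial_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise InputError("alpha must be in [0, 1]")
        if self.quasi_static_tol_g < 0:
            raise InputError("quasi_static_tol_g must be >= 0")
        for ax in (self.sagittal_gyro_axis, self.forward_accel_axis, self.longitudinal_accel_axis):
            if ax not in (0, 1, 2):
                raise InputError("axis indices must be 0, 1 or 2")


def estimate_thigh_angle(imu: ImuRecord, config: GiofConfig = GiofConfig()) -> ThighAngleSeries:
    """Estimate the sagittal thigh angle by drift-corrected gyro integration.

    The angle is advanced by trapezoidal integration of the sagittal gyro
    channel; at each quasi-static sample it is pulled a fraction ``alpha``
    toward the accelerometer inclination angle:

        theta[k] = theta[k-1] + (w[k-1] + w[k])/2 * dt
        theta[k] <- (1 - alpha) * theta[k] + alpha * theta_acc[k]   (quasi-static)

    With ``alpha = 0`` the output is exactly the cumulative trapezoidal
    integral of the gyro channel.  The initial angle comes from the
    accelerometer if the first sample is quasi-static, otherwise 0 degrees
    (or ``config.initial_angle_deg`` when given).
    """
    t = imu.times_s
    omega = imu.gyro_dps[config.sagittal_gyro_axis]
    acc_norm = np.linalg.norm(imu.accel_g, axis=0)
    quasi_static = np.abs(acc_norm - 1.0) <= config.quasi_static_tol_g
    theta_acc = np.degrees(
        np.arctan2(
            imu.accel_g[config.forward_accel_axis],
            imu.accel_g[config.longitudinal_accel_axis],
        )
    )

    theta = np.empty(len(imu))
    if config.initial_angle_deg is not None:
        theta[0] = config.initial_angle_deg
    elif quasi_static[0] and config.alpha > 0:
        theta[0] = theta_acc[0]
    else:
        theta[0] = 0.0

    dt = np.diff(t)
    alpha = config.alpha
    for k in range(1, len(imu)):
        th = theta[k - 1] + 0.5 * (omega[k - 1] + omega[k]) * dt[k - 1]
        if alpha > 0 and quasi_static[k]:
            th = (1.0 - alpha) * th + alpha * theta_acc[k]
        theta[k] = th

    return ThighAngleSeries(times_s=t, angle_deg=theta, source="giof", rate_hz=imu.rate_hz)
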