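"""Angular-velocity pulses for rapid non-impact head rotation.

A rotation experiment is driven by a single sagittal- (or axial-) plane
pulse: the head accelerates to a peak angular velocity of roughly 50 rad/s,
optionally dwells there, and decelerates to rest, sweeping a fixed total
angle (65 degrees in the physical rig).  The pulse is represented on a
uniform time grid sampled at the angular-rate-sensor rate (10 kHz nominal).

Velocity traces destined for the simulator are low-pass filtered with a
phaseless channel-frequency-class (CFC) filter so that high-frequency sensor
artifacts do not excite the explicit solver while the pulse shape and peak
velocity are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RotationPulse",
    "InfeasiblePulseError",
    "generate_pulse",
    "cfc_filter",
    "filtered",
    "read_pulse_csv",
    "write_pulse_csv",
]

DEFAULT_SAMPLE_RATE = 10_000.0  # Hz, angular rate sensor recording rate


class InfeasiblePulseError(ValueError):
    """Requested rotation angle cannot be met by the given peak kinematics."""


@dataclass(frozen=True)
class RotationPulse:
    """Angular velocity/acceleration time series on a uniform grid.

    Attributes
    ----------
    time : ndarray
        Seconds, strictly increasing, uniform step.
    angular_velocity : ndarray
        rad/s; zero at the first and last sample.
    angular_acceleration : ndarray
        rad/s^2, central finite difference of the velocity.
    total_angle : float
        rad, trapezoidal integral of the velocity.
    """

    time: np.ndarray
    angular_velocity: np.ndarray
    angular_acceleration: np.ndarray = field(default=None)  # type: ignore[assignment]
    total_angle: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        w = np.asarray(self.angular_velocity, dtype=float)
        if t.ndim != 1 or t.shape != w.shape or t.size < 3:
            raise ValueError("time and angular_velocity must be equal-length 1-D arrays")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("time grid must be uniform")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "angular_velocity", w)
        if self.angular_acceleration is None:
            object.__setattr__(self, "angular_acceleration", np.gradient(w, t))
        if self.total_angle is None:
            object.__setattr__(self, "total_angle", float(np.trapezoid(w, t)))

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def peak_velocity(self) -> float:
        return float(np.max(np.abs(self.angular_velocity)))

    @property
    def peak_acceleration(self) -> float:
        """Largest positive angular acceleration, rad/s^2."""
        return float(np.max(self.angular_acceleration))

    @property
    def peak_deceleration(self) -> float:
        """Magnitude of the largest negative angular acceleration, rad/s^2."""
        return float(-np.min(self.angular_acceleration))

    def angle(self) -> np.ndarray:
        """Cumulative rotation angle theta(t) in rad (trapezoidal)."""
        dth = 0.5 * (self.angular_velocity[1:] + self.angular_velocity[:-1]) * np.diff(self.time)
        return np.concatenate([[0.0], np.cumsum(dth)])

    def motion_start_time(self, threshold_fraction: float = 0.01) -> float:
        """First time |omega| exceeds ``threshold_fraction`` of the peak."""
        thr = threshold_fraction * self.peak_velocity
        idx = np.flatnonzero(np.abs(self.angular_velocity) > thr)
        if idx.size == 0:
            return float(self.time[0])
        return float(self.time[idx[0]])


def generate_pulse(
    peak_velocity: float,
    peak_accel: float,
    peak_decel: float,
    total_angle: float,
    dt: float = 1.0 / DEFAULT_SAMPLE_RATE,
    pad_before: float = 0.02,
    pad_after: float = 0.01,
) -> RotationPulse:
    """Build a smooth (C1) velocity pulse sweeping ``total_angle``.

    The profile is a half-cosine ramp up whose slope peaks at ``peak_accel``,
    an optional constant-velocity plateau, and a half-cosine ramp down whose
    slope magnitude peaks at ``peak_decel``.  Quiet padding before and after
    the pulse supplies the pre-motion frames the measurement pipeline uses
    for its baseline, and lets the velocity start and end at exactly zero.

    Parameters
    ----------
    peak_velocity : float
        rad/s, maximum of the velocity profile (> 0).
    peak_accel, peak_decel : float
        rad/s^2, magnitudes of the acceleration/deceleration extrema (> 0).
    total_angle : float
        rad, required integral of the velocity.
    dt : float
        Sample step in seconds (default 1e-4, i.e. 10 kHz).

    Raises
    ------
    InfeasiblePulseError
        If the angle is smaller than the area swept by the two ramps alone;
        the message names the minimum achievable angle.
    """
    if peak_velocity <= 0 or peak_accel <= 0 or peak_decel <= 0:
        raise InfeasiblePulseError(
            "peak_velocity, peak_accel and peak_decel must all be positive "
            f"(got {peak_velocity}, {peak_accel}, {peak_decel})"
        )
    if total_angle <= 0:
        raise InfeasiblePulseError("total_angle must be positive")

    # Half-cosine ramp w(t) = w_p/2 (1 - cos(pi t / T)): slope extremum is
    # w_p * pi / (2 T), so the ramp duration follows from the peak slope.
    t_up = np.pi * peak_velocity / (2.0 * peak_accel)
    t_down = np.pi * peak_velocity / (2.0 * peak_decel)
    ramp_angle = 0.5 * peak_velocity * (t_up + t_down)
    if total_angle < ramp_angle - 1e-12:
        raise InfeasiblePulseError(
            f"total_angle={total_angle:.4f} rad infeasible: ramps alone sweep "
            f"{ramp_angle:.4f} rad (minimum achievable angle) at the requested peaks"
        )
    t_plateau = max((total_angle - ramp_angle) / peak_velocity, 0.0)

    duration = t_up + t_plateau + t_down
    n = int(np.ceil((pad_before + duration + pad_after) / dt)) + 1
    time = np.arange(n) * dt
    tau = time - pad_before
    w = np.zeros(n)

    m_up = (tau >= 0) & (tau < t_up)
    w[m_up] = 0.5 * peak_velocity * (1.0 - np.cos(np.pi * tau[m_up] / t_up))
    m_pl = (tau >= t_up) & (tau < t_up + t_plateau)
    w[m_pl] = peak_velocity
    m_dn = (tau >= t_up + t_plateau) & (tau <= duration)
    w[m_dn] = 0.5 * peak_velocity * (
        1.0 + np.cos(np.pi * (tau[m_dn] - t_up - t_plateau) / t_down)
    )

    # Grid quantisation nudges the integral by O(dt); rescale to hit the
    # requested angle exactly (well inside the 0.5% invariant).
    area = np.trapezoid(w, time)
    if area > 0:
        w *= total_angle / area
    return RotationPulse(time=time, angular_velocity=w)


def cfc_filter(
    values: np.ndarray,
    sample_rate: float,
    cfc_class: float = 200.0,
) -> np.ndarray:
    """Phaseless channel-frequency-class low-pass filter for impact signals.

    A second-order Butterworth filter is applied forward and backward
    (zero phase); the design cutoff is 2.0775 x CFC so the combined
    response is 3 dB down at 1.65 x CFC (330 Hz for CFC 200), following
    the automotive channel-class convention.

    Raises
    ------
    ValueError
        If the sample rate is below four times the design cutoff.
    """
    values = np.asarray(values, dtype=float)
    cutoff = 2.0775 * cfc_class
    if sample_rate < 4.0 * cutoff:
        raise ValueError(
            f"sample rate {sample_rate} Hz too low for CFC {cfc_class} "
            f"(need >= {4.0 * cutoff:.0f} Hz)"
        )
    sos = signal.butter(2, cutoff, btype="low", fs=sample_rate, output="sos")
    padlen = min(3 * 10, values.size - 1)
    return signal.sosfiltfilt(sos, values, padlen=padlen)


def filtered(pulse: RotationPulse, cfc_class: float = 200.0) -> RotationPulse:
    """Return a copy of ``pulse`` with CFC-filtered angular velocity."""
    w = cfc_filter(pulse.angular_velocity, 1.0 / pulse.dt, cfc_class)
    peak_ratio = np.max(np.abs(w)) / max(pulse.peak_velocity, 1e-300)
    if abs(peak_ratio - 1.0) > 0.02:
        warnings.warn(
            f"CFC {cfc_class} filtering changed the velocity peak by "
            f"{100 * abs(peak_ratio - 1.0):.1f}%", stacklevel=2,
        )
    return RotationPulse(time=pulse.time.copy(), angular_velocity=w)


def read_pulse_csv(path) -> RotationPulse:
    """Read a pulse from CSV with columns ``time_s, omega_rad_s``."""
    df = pd.read_csv(path)
    return RotationPulse(
        time=df["time_s"].to_numpy(float),
        angular_velocity=df["omega_rad_s"].to_numpy(float),
    )


def write_pulse_csv(pulse: RotationPulse, path) -> None:
    pd.DataFrame(
        {"time_s": pulse.time, "omega_rad_s": pulse.angular_velocity}
    ).to_csv(path, index=False)
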