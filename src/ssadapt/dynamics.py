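"""Rigid-body loads of the rotated hammer-like object.

The simulated object is a point mass ``m`` at the end of a rigid, massless
rod of length ``r`` (0.08 m by default).  Rotating the rod through an angle
profile theta(t) produces a torque proportional to the angular acceleration,
a tangential force (perpendicular to the rod) proportional to the angular
acceleration, and a centripetal force (along the rod, toward the rotation
centre) proportional to the squared angular velocity:

    tau = m r^2 theta_dd
    F_t = m r theta_dd
    F_c = m r theta_d^2

The planar force vector at the handle is the rod-frame force rotated into
the manipulandum frame by a clockwise rotation matrix through the rod angle
(0 deg = +y axis, positive angles counter-clockwise).

The peak of |F| over a trial is the force the object would have exerted on
a perfectly stiff grasp; it normalizes the forces subjects produce on
error-clamp trials into a dimensionless adaptation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_ROD_LENGTH_M = 0.08
DEFAULT_AMPLITUDE_DEG = 40.0
DEFAULT_DURATION_S = 0.4


@dataclass(frozen=True)
class ObjectSpec:
    """Point mass on a rigid rod."""

    mass_kg: float
    rod_length_m: float = DEFAULT_ROD_LENGTH_M

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass_kg must be positive")
        if self.rod_length_m <= 0:
            raise ValueError("rod_length_m must be positive")


@dataclass(frozen=True)
class RotationProfile:
    """Uniformly sampled rod-angle kinematics (degrees, deg/s, deg/s^2)."""

    time: np.ndarray
    angle: np.ndarray
    angular_velocity: np.ndarray
    angular_acceleration: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.angle) == len(self.angular_velocity) == len(self.angular_acceleration) == n):
            raise ValueError("profile arrays must share one length")


@dataclass(frozen=True)
class LoadTrace:
    """Torque and force traces produced by the object (SI units)."""

    time: np.ndarray
    torque: np.ndarray
    tangential_force: np.ndarray
    centripetal_force: np.ndarray
    force_xy: np.ndarray  # shape (n, 2), manipulandum frame

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time,
                "torque": self.torque,
                "Ft": self.tangential_force,
                "Fc": self.centripetal_force,
                "Fx": self.force_xy[:, 0],
                "Fy": self.force_xy[:, 1],
            }
        )


def minimum_jerk_profile(
    amplitude_deg: float = DEFAULT_AMPLITUDE_DEG,
    duration_s: float = DEFAULT_DURATION_S,
    n_samples: int = 401,
    start_angle_deg: float = -DEFAULT_AMPLITUDE_DEG / 2,
) -> RotationProfile:
    """Rest-to-rest fifth-order (minimum-jerk) rotation profile.

    The within-trial kinematics of subjects were not recorded trial by
    trial; any smooth rest-to-rest profile covering 40 deg in the required
    0.4 s movement time serves as a repeatable normalizer, and minimum
    jerk is the conventional choice.  Peak angular speed is
    (15/8) * amplitude / duration.
    """
    if amplitude_deg == 0:
        raise ValueError("amplitude must be nonzero")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    t = np.linspace(0.0, duration_s, n_samples)
    s = t / duration_s
    pos = 10 * s**3 - 15 * s**4 + 6 * s**5
    vel = (30 * s**2 - 60 * s**3 + 30 * s**4) / duration_s
    acc = (60 * s - 180 * s**2 + 120 * s**3) / duration_s**2
    return RotationProfile(
        time=t,
        angle=start_angle_deg + amplitude_deg * pos,
        angular_velocity=amplitude_deg * vel,
        angular_acceleration=amplitude_deg * acc,
    )


def object_loads(profile: RotationProfile, obj: ObjectSpec) -> LoadTrace:
    """Torque and handle force traces for a rotation profile.

    Angles are converted to radians internally; the rod-frame force
    (tangential, centripetal) is rotated into the manipulandum frame by a
    clockwise rotation through the rod angle.
    """
    m, r = obj.mass_kg, obj.rod_length_m
    th = np.deg2rad(profile.angle)
    thd = np.deg2rad(profile.angular_velocity)
    thdd = np.deg2rad(profile.angular_acceleration)

    torque = m * r**2 * thdd
    f_t = m * r * thdd
    f_c = m * r * thd**2

    # Rod at angle th from +y (CCW positive): rod direction u = (-sin th, cos th),
    # tangential direction (CCW) is perpendicular: (-cos th, -sin th).
    # Force components: tangential along the tangential direction, centripetal
    # toward the centre (i.e. -u).  Equivalent to rotating (f_t, -f_c) expressed
    # in the rod frame by the clockwise matrix through th.
    fx = -f_t * np.cos(th) + f_c * np.sin(th)
    fy = -f_t * np.sin(th) - f_c * np.cos(th)
    return LoadTrace(
        time=profile.time,
        torque=torque,
        tangential_force=f_t,
        centripetal_force=f_c,
        force_xy=np.column_stack([fx, fy]),
    )


def peak_object_force(obj: ObjectSpec, profile: RotationProfile | None = None) -> float:
    """Peak |F| the object would exert over the profile (newtons).

    Used as the denominator of the adaptation ratio for error-clamp
    trials.  Defaults to the canonical 40 deg / 0.4 s minimum-jerk
    rotation.
    """
    if profile is None:
        profile = minimum_jerk_profile()
    loads = object_loads(profile, obj)
    return float(np.max(np.hypot(loads.force_xy[:, 0], loads.force_xy[:, 1])))
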