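"""Task dynamics: viscous curl force-fields and reference reach kinematics.

The environment is a planar robotic-manipulandum task: 10-cm point-to-point
reaches whose trajectories can be perturbed by a velocity-dependent curl
field F = B [[0, 1], [-1, 0]] v, where B is the field viscosity in
N/(m/s). The force is orthogonal to the hand velocity at every instant, so
the field does no work. A positive B deflects motion clockwise (toward
smaller movement angles); a negative B deflects it counterclockwise.

Reference kinematics are fifth-order minimum-jerk profiles along a straight
line. The default duration is set so that a 10-cm reach has the task's mean
peak speed of 0.302 m/s (minimum-jerk peak speed is 1.875 * distance /
duration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ForceFieldSpec",
    "Trajectory",
    "curl_force",
    "min_jerk_trajectory",
    "ideal_compensation_force",
    "lateral_ideal_force",
    "REACH_DISTANCE_M",
    "MEAN_PEAK_SPEED_MPS",
    "DEFAULT_DT_S",
    "DEFAULT_DURATION_S",
]

#: Point-to-point reach amplitude (m).
REACH_DISTANCE_M = 0.10
#: Mean peak hand speed across the task (m/s).
MEAN_PEAK_SPEED_MPS = 0.302
#: Kinematic sampling interval (s): 200 Hz.
DEFAULT_DT_S = 0.005
#: Reach duration (s) such that the minimum-jerk peak speed over 10 cm
#: equals the mean peak speed: T = 1.875 * d / v_peak.
DEFAULT_DURATION_S = 1.875 * REACH_DISTANCE_M / MEAN_PEAK_SPEED_MPS

_FIELD_MODES = ("curl", "null", "error_clamp")


@dataclass(frozen=True)
class ForceFieldSpec:
    """A per-trial force environment.

    Parameters
    ----------
    viscosity : float
        Signed curl viscosity B in N/(m/s). Positive values are clockwise
        (CW) fields, negative counterclockwise (CCW). Ignored when
        ``mode="null"``. For ``mode="error_clamp"`` the viscosity names the
        signed reference field against which clamp-trial compensation is
        expressed.
    mode : {"curl", "null", "error_clamp"}
        ``error_clamp`` idealizes a force channel: lateral displacement is
        held at exactly zero while the subject's compensatory force is
        recorded.
    """

    viscosity: float = 0.0
    mode: str = "null"

    def __post_init__(self):
        if self.mode not in _FIELD_MODES:
            raise ValueError(f"mode must be one of {_FIELD_MODES}, got {self.mode!r}")
        if not np.isfinite(self.viscosity):
            raise ValueError("viscosity must be finite")

    @property
    def field_sign(self) -> int:
        """+1 for a CW curl field, -1 for CCW, 0 for null/error-clamp."""
        if self.mode != "curl" or self.viscosity == 0:
            return 0
        return 1 if self.viscosity > 0 else -1

    @classmethod
    def cw(cls, viscosity: float = 9.0) -> "ForceFieldSpec":
        return cls(viscosity=abs(viscosity), mode="curl")

    @classmethod
    def ccw(cls, viscosity: float = 9.0) -> "ForceFieldSpec":
        return cls(viscosity=-abs(viscosity), mode="curl")

    @classmethod
    def null(cls) -> "ForceFieldSpec":
        return cls(viscosity=0.0, mode="null")

    @classmethod
    def error_clamp(cls, reference_viscosity: float) -> "ForceFieldSpec":
        return cls(viscosity=reference_viscosity, mode="error_clamp")


@dataclass
class Trajectory:
    """Uniformly sampled 2-D hand path for one reach.

    positions are meters, velocities m/s; ``movement_direction`` is the
    nominal heading in degrees CCW from +x.
    """

    dt: float
    positions: np.ndarray
    velocities: np.ndarray
    movement_direction: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2:
            raise ValueError("positions and velocities must be matching (N, 2) arrays")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocities, axis=1)

    @property
    def peak_speed(self) -> float:
        return float(self.speed.max())

    @property
    def reach_distance(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "vx": self.velocities[:, 0],
                "vy": self.velocities[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, movement_direction: float = 0.0) -> "Trajectory":
        df = pd.read_csv(path)
        dt = float(np.diff(df["t"].to_numpy()).mean())
        return cls(
            dt=dt,
            positions=df[["x", "y"]].to_numpy(),
            velocities=df[["vx", "vy"]].to_numpy(),
            movement_direction=movement_direction,
        )


def curl_force(velocity, viscosity: float):
    """Curl-field force F = B [[0, 1], [-1, 0]] v.

    Parameters
    ----------
    velocity : array_like, shape (2,) or (N, 2)
        Hand velocity in m/s.
    viscosity : float
        Signed field viscosity B in N/(m/s).

    Returns
    -------
    ndarray with the shape of ``velocity``: (B * vy, -B * vx) in newtons,
    always orthogonal to the velocity.
    """
    v = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(v)) or not np.isfinite(viscosity):
        raise ValueError("curl_force requires finite velocity and viscosity")
    return viscosity * np.stack([v[..., 1], -v[..., 0]], axis=-1)


def _min_jerk_profiles(distance: float, duration: float, dt: float):
    # Fifth-order polynomial with zero velocity/acceleration at both ends.
    n = int(round(duration / dt)) + 1
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    sdot = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration
    return distance * s, distance * sdot


def min_jerk_trajectory(
    direction: float,
    distance: float = REACH_DISTANCE_M,
    duration: float = DEFAULT_DURATION_S,
    dt: float = DEFAULT_DT_S,
    origin=(0.0, 0.0),
) -> Trajectory:
    """Straight minimum-jerk reach along ``direction`` (degrees CCW from +x).

    Peak speed is 1.875 * distance / duration, reached at mid-movement;
    velocity is zero at both endpoints.
    """
    if duration <= 0 or distance <= 0:
        raise ValueError("duration and distance must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    path, speed = _min_jerk_profiles(distance, duration, dt)
    theta = np.deg2rad(direction)
    u = np.array([np.cos(theta), np.sin(theta)])
    positions = np.asarray(origin, dtype=float) + np.outer(path, u)
    velocities = np.outer(speed, u)
    return Trajectory(
        dt=dt,
        positions=positions,
        velocities=velocities,
        movement_direction=float(direction),
    )


def ideal_compensation_force(traj: Trajectory, viscosity: float) -> np.ndarray:
    """Force time series that exactly cancels the curl field along ``traj``.

    Pointwise negative of :func:`curl_force` evaluated on the trajectory's
    velocities; for a straight minimum-jerk reach this is a bell-shaped,
    purely lateral profile. Linear in ``viscosity``.
    """
    return -curl_force(traj.velocities, viscosity)


def lateral_ideal_force(traj: Trajectory, viscosity: float) -> np.ndarray:
    """Lateral (leftward-positive) component of the ideal compensating force.

    For a straight reach of heading theta the curl field acts entirely along
    the leftward normal (-sin theta, cos theta), so the ideal compensation
    reduces to ``viscosity * speed(t)`` on that axis.
    """
    theta = np.deg2rad(traj.movement_direction)
    normal = np.array([-np.sin(theta), np.cos(theta)])
    return ideal_compensation_force(traj, viscosity) @ normal
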