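"""Trial-by-trial state-space learning rules over movement direction.

Adaptation is a scalar function x(theta) of movement direction theta,
expressed in compensated-viscosity units (N/(m/s)): x(theta) = B means that
movements planned along theta are fully compensated for a curl field of
viscosity B. On every trial the state decays by a retention coefficient A
and acquires a Gaussian bump of learning driven by that trial's directional
error e (degrees, actual - planned, CCW-positive):

    x_{n+1}(theta) = A x_n(theta) - gain * e_n * g(theta - theta_ref)

with g a Gaussian primitive of width sigma. Because CW fields (positive B)
push errors negative, the minus sign makes each increment oppose the
perturbing field (the state climbs toward +B in a CW field and toward -B in
a CCW field). The two credit-assignment hypotheses differ only in where the
bump is centered:

* plan-referenced learning (PRL): theta_ref = planned direction
* motion-referenced learning (MRL): theta_ref = actual direction

Error-clamp and null-field trials carry no learnable error and apply pure
retention decay.

The primitive width is given in velocity space (sigma = 0.12 m/s); at the
task's mean peak speed of 0.302 m/s this subtends
(0.12 / 0.302) * (180 / pi) ~= 22.8 degrees, the default direction-space
width.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._angles import angular_difference, wrap_degrees
from .dynamics import MEAN_PEAK_SPEED_MPS

__all__ = [
    "LearningParams",
    "AdaptationState",
    "TrialError",
    "primitive_activation",
    "update_state",
    "closed_form_state",
    "predicted_generalization",
    "SIGMA_VELOCITY_MPS",
    "DEFAULT_SIGMA_DEG",
    "DEFAULT_RETENTION",
    "DEFAULT_GAIN",
]

#: Gaussian primitive width in velocity space (m/s).
SIGMA_VELOCITY_MPS = 0.12
#: The same width converted to direction space at the mean peak speed.
DEFAULT_SIGMA_DEG = float(np.rad2deg(SIGMA_VELOCITY_MPS / MEAN_PEAK_SPEED_MPS))
#: Per-trial retention of the adaptation state.
DEFAULT_RETENTION = 0.98
#: Learning gain in N/(m/s) per degree of error: a naive trial in the
#: B = 9 N/(m/s) field (error ~= -12.6 deg under the default closed loop)
#: produces ~5% of full compensation at the primitive center.
DEFAULT_GAIN = 0.05 * 9.0 / 12.6

_HYPOTHESES = ("PRL", "MRL")


@dataclass(frozen=True)
class LearningParams:
    """Parameters of the state-space learning rule.

    retention in (0, 1]; gain >= 0 in N/(m/s) per degree; primitive_sigma
    > 0 degrees; hypothesis selects the credit-assignment reference;
    cw_gain_scale optionally scales the gain on CW-field trials to emulate
    a clockwise learning bias (1 = bias off).
    """

    retention: float = DEFAULT_RETENTION
    gain: float = DEFAULT_GAIN
    primitive_sigma: float = DEFAULT_SIGMA_DEG
    hypothesis: str = "MRL"
    cw_gain_scale: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.retention <= 1.0):
            raise ValueError("retention must be in (0, 1]")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.primitive_sigma <= 0:
            raise ValueError("primitive_sigma must be positive")
        if self.hypothesis not in _HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {_HYPOTHESES}")
        if self.cw_gain_scale < 0:
            raise ValueError("cw_gain_scale must be non-negative")

    def replace(self, **kwargs) -> "LearningParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialError:
    """One trial's planned/actual directions and signed directional error."""

    planned_direction: float
    actual_direction: float

    @property
    def error(self) -> float:
        """actual - planned, wrapped to (-180, 180] degrees."""
        return angular_difference(self.actual_direction, self.planned_direction)


@dataclass
class AdaptationState:
    """Compensation level as a function of movement direction.

    values are in compensated-viscosity units N/(m/s) on a dense uniform
    grid of directions covering [-180, 180). A naive subject is identically
    zero.
    """

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape or self.grid.ndim != 1:
            raise ValueError("grid and values must be matching 1-D arrays")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("state values must be finite")

    @classmethod
    def zeros(cls, grid_step: float = 1.0) -> "AdaptationState":
        grid = np.arange(-180.0, 180.0, grid_step)
        return cls(grid=grid, values=np.zeros_like(grid))

    def value_at(self, direction):
        """Wrap-aware linear interpolation of the state at ``direction``."""
        out = np.interp(
            wrap_degrees(direction), self.grid, self.values, period=360.0
        )
        if np.ndim(direction) == 0:
            return float(out)
        return out

    def copy(self) -> "AdaptationState":
        return AdaptationState(grid=self.grid.copy(), values=self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"direction_deg": self.grid, "compensation_Nspermeter": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AdaptationState":
        df = pd.read_csv(path)
        return cls(
            grid=df["direction_deg"].to_numpy(),
            values=df["compensation_Nspermeter"].to_numpy(),
        )


def primitive_activation(delta, sigma: float):
    """Gaussian primitive activation exp(-wrap(delta)^2 / (2 sigma^2)).

    Symmetric in ``delta`` and maximal (1) at delta = 0. ``delta`` and
    ``sigma`` are degrees.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = wrap_degrees(delta)
    return np.exp(-np.square(d) / (2.0 * sigma**2))


def _reference_direction(trial: TrialError, hypothesis: str) -> float:
    if hypothesis == "PRL":
        return trial.planned_direction
    return trial.actual_direction


def update_state(
    state: AdaptationState,
    trial: TrialError,
    field_sign: int,
    params: LearningParams,
) -> AdaptationState:
    """One step of the state-space learning rule.

    ``field_sign`` is +1 on CW-field trials, -1 on CCW, and 0 on null or
    error-clamp trials; with sign 0 the error is treated as zero and the
    state undergoes pure retention decay.
    """
    new = state.copy()
    new.values *= params.retention
    if field_sign == 0:
        return new
    gain = params.gain * (params.cw_gain_scale if field_sign > 0 else 1.0)
    theta_ref = _reference_direction(trial, params.hypothesis)
    bump = primitive_activation(state.grid - theta_ref, params.primitive_sigma)
    new.values -= gain * trial.error * bump
    return new


def closed_form_state(
    history: Sequence[tuple[TrialError, int]],
    params: LearningParams,
    grid_step: float = 1.0,
) -> AdaptationState:
    """Analytic superposition solution of the linear learning recursion.

    After n trials the state is the geometric-decay superposition
    ``x_n(theta) = sum_k A^(n-1-k) * increment_k(theta)`` where the
    increment of trial k is the (possibly zero) Gaussian bump deposited on
    that trial. Serves as the independent oracle for :func:`update_state`.
    """
    state = AdaptationState.zeros(grid_step)
    n = len(history)
    for k, (trial, field_sign) in enumerate(history):
        if field_sign == 0:
            continue
        gain = params.gain * (params.cw_gain_scale if field_sign > 0 else 1.0)
        theta_ref = _reference_direction(trial, params.hypothesis)
        bump = primitive_activation(state.grid - theta_ref, params.primitive_sigma)
        state.values -= (
            params.retention ** (n - 1 - k) * gain * trial.error * bump
        )
    return state


def predicted_generalization(
    state: AdaptationState,
    probe_directions,
    reference_viscosity: float,
):
    """Adaptation fraction at each probe direction.

    The state is divided by the magnitude of the reference field viscosity
    and signed so that positive values denote compensation appropriate for
    the CCW field (the convention used for interference generalization
    plots, where probes above the training direction show positive
    adaptation under motion-referenced learning).
    """
    if reference_viscosity == 0:
        raise ValueError("reference_viscosity must be nonzero")
    return -state.value_at(probe_directions) / abs(reference_viscosity)
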