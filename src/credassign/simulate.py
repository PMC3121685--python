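"""Closed-loop coupling of the learning rule to movement outcomes.

Each trial is summarized by its initial movement direction (reaches are
approximately straight early in the movement, so one direction per trial
captures the state relevant to velocity-dependent learning). On a curl
trial the directional error is a static-gain map of the uncompensated
viscosity plus Gaussian motor noise:

    error = -error_gain * (B_field - x(planned)) + noise

so a CW field (B > 0) drives a naive subject's error negative (toward
smaller angles) and the error vanishes in expectation once the state fully
compensates the field. The resulting (planned, actual) pair feeds the
state-space update, closing the loop.

Error-clamp trials hold lateral displacement at exactly zero: the movement
goes straight to the target, the state decays, and the subject's
compensatory lateral force profile is recorded for the adaptation-
coefficient regression downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import ForceFieldSpec, Trajectory, min_jerk_trajectory
from .primitives import AdaptationState, LearningParams, TrialError, update_state

__all__ = [
    "SimConfig",
    "TrialRecord",
    "simulate_trial",
    "simulate_experiment",
    "measured_clamp_force",
    "trial_table",
    "DEFAULT_ERROR_GAIN",
    "DEFAULT_MOTOR_NOISE_SD",
]

#: Degrees of initial-direction error per N/(m/s) of uncompensated
#: viscosity. 1.4 puts the mean CW/CCW error separation in the B = +/-9
#: interference task at ~25 degrees.
DEFAULT_ERROR_GAIN = 1.4
#: Trial-to-trial directional motor noise (degrees, SD).
DEFAULT_MOTOR_NOISE_SD = 3.0


@dataclass(frozen=True)
class SimConfig:
    """Closed-loop simulation configuration."""

    error_gain: float = DEFAULT_ERROR_GAIN
    motor_noise_sd: float = DEFAULT_MOTOR_NOISE_SD
    seed: int = 0
    grid_step: float = 1.0

    def __post_init__(self):
        if self.error_gain < 0:
            raise ValueError("error_gain must be non-negative")
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be non-negative")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")


@dataclass
class TrialRecord:
    """One simulated trial: schedule entry plus outcome.

    ``adaptation_at_probe`` and ``measured_lateral_force`` are populated on
    error-clamp trials only; ``error`` is defined only on non-clamp trials.
    The clamp coefficient is the state at the probe divided by the clamp's
    signed reference viscosity (1 = full compensation of that field).
    """

    index: int
    phase: str
    target_direction: float
    field: ForceFieldSpec
    planned_direction: float
    actual_direction: float
    error: float = np.nan
    adaptation_at_probe: float = np.nan
    measured_lateral_force: Optional[np.ndarray] = None


def measured_clamp_force(
    state: AdaptationState, probe_direction: float, traj: Trajectory
) -> np.ndarray:
    """Lateral force a clamped movement produces, leftward-positive (N).

    The adapted state acts as a feedforward viscous compensator, so the
    lateral force is state(probe) times the speed profile - bell-shaped for
    a minimum-jerk reach and oriented to oppose the field the state
    compensates.
    """
    return state.value_at(probe_direction) * traj.speed


def simulate_trial(
    state: AdaptationState,
    target: float,
    fieldspec: ForceFieldSpec,
    params: LearningParams,
    cfg: SimConfig,
    rng: np.random.Generator,
    phase: str = "training",
    index: int = 0,
    clamp_traj: Optional[Trajectory] = None,
) -> tuple[TrialRecord, AdaptationState]:
    """Simulate one trial and return the record plus the updated state.

    Plans are straight toward the target, so ``planned_direction`` equals
    the target direction.
    """
    planned = float(target)
    if fieldspec.mode == "error_clamp":
        traj = clamp_traj or min_jerk_trajectory(planned)
        record = TrialRecord(
            index=index,
            phase=phase,
            target_direction=planned,
            field=fieldspec,
            planned_direction=planned,
            actual_direction=planned,
            adaptation_at_probe=state.value_at(planned) / fieldspec.viscosity,
            measured_lateral_force=measured_clamp_force(state, planned, traj),
        )
        new_state = update_state(
            state, TrialError(planned, planned), 0, params
        )
        return record, new_state

    noise = rng.normal(0.0, cfg.motor_noise_sd) if cfg.motor_noise_sd else 0.0
    if fieldspec.mode == "curl":
        uncompensated = fieldspec.viscosity - state.value_at(planned)
        error = -cfg.error_gain * uncompensated + noise
    else:  # null field
        error = noise
    actual = planned + error
    trial = TrialError(planned, actual)
    record = TrialRecord(
        index=index,
        phase=phase,
        target_direction=planned,
        field=fieldspec,
        planned_direction=planned,
        actual_direction=actual,
        error=trial.error,
    )
    new_state = update_state(state, trial, fieldspec.field_sign, params)
    return record, new_state


def simulate_experiment(
    schedule,
    params: LearningParams,
    cfg: SimConfig,
    initial_state: Optional[AdaptationState] = None,
) -> list[TrialRecord]:
    """Run a full schedule with a single seeded generator.

    ``schedule`` is a :class:`~credassign.paradigms.Schedule` or any
    iterable of objects with ``phase``, ``target_direction`` and ``field``
    attributes. Deterministic given (schedule, params, cfg.seed).
    """
    entries = getattr(schedule, "entries", schedule)
    if len(entries) == 0:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    state = (
        initial_state.copy()
        if initial_state is not None
        else AdaptationState.zeros(cfg.grid_step)
    )
    # One reference clamp trajectory per probe direction (kinematics do not
    # depend on the state, so they can be shared).
    clamp_cache: dict[float, Trajectory] = {}
    records: list[TrialRecord] = []
    for i, entry in enumerate(entries):
        traj = None
        if entry.field.mode == "error_clamp":
            key = float(entry.target_direction)
            if key not in clamp_cache:
                clamp_cache[key] = min_jerk_trajectory(key)
            traj = clamp_cache[key]
        record, state = simulate_trial(
            state,
            entry.target_direction,
            entry.field,
            params,
            cfg,
            rng,
            phase=entry.phase,
            index=i,
            clamp_traj=traj,
        )
        records.append(record)
    return records


def trial_table(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the package's trial-table CSV dialect.

    Force time series are not included; keep the records (or the synthetic
    dataset object) when per-sample clamp forces are needed.
    """
    return pd.DataFrame(
        {
            "index": [r.index for r in records],
            "phase": [r.phase for r in records],
            "target_direction": [r.target_direction for r in records],
            "field_mode": [r.field.mode for r in records],
            "field_viscosity": [r.field.viscosity for r in records],
            "planned_direction": [r.planned_direction for r in records],
            "actual_direction": [r.actual_direction for r in records],
            "error": [r.error for r in records],
            "adaptation_at_probe": [r.adaptation_at_probe for r in records],
        }
    )
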