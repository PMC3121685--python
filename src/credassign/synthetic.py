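"""Synthetic subject datasets: schedules rendered into 200-Hz raw data.

Each simulated trial is rendered as a minimum-jerk reach along its actual
movement direction with smooth positional jitter, a per-trial duration
drawn so that peak speeds scatter realistically around 0.302 m/s, and a
log-normal reaction time - so the kinematic inclusion filter has real work
to do. Error-clamp trials additionally carry the measured lateral force
profile (the adapted state acting on the trial's noisy speed profile plus
force-sensor noise) and the matching ideal compensation profile, which the
analysis stage regresses to obtain adaptation coefficients.

The ``impaired`` profile emulates adaptation after chronic stroke: a lower
learning gain and higher residual (motor) noise than the ``healthy``
profile. The values are synthetic presets chosen to reproduce the
qualitative pattern of slowed learning with elevated residual errors, not
fits to patient data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .analysis import adaptation_coefficient
from .dynamics import (
    DEFAULT_DURATION_S,
    REACH_DISTANCE_M,
    Trajectory,
    min_jerk_trajectory,
)
from .primitives import LearningParams
from .simulate import (
    DEFAULT_ERROR_GAIN,
    DEFAULT_MOTOR_NOISE_SD,
    SimConfig,
    simulate_experiment,
    trial_table,
)

__all__ = [
    "SubjectProfile",
    "NoiseConfig",
    "SubjectDataset",
    "generate_subject",
    "generate_cohort",
    "score_clamp_trials",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Learning parameters plus closed-loop noise for one subject type."""

    params: LearningParams = field(default_factory=LearningParams)
    error_gain: float = DEFAULT_ERROR_GAIN
    motor_noise_sd: float = DEFAULT_MOTOR_NOISE_SD
    label: str = "healthy"

    @classmethod
    def healthy(cls, hypothesis: str = "MRL", **overrides) -> "SubjectProfile":
        return cls(params=LearningParams(hypothesis=hypothesis), **overrides)

    @classmethod
    def impaired(cls, hypothesis: str = "MRL") -> "SubjectProfile":
        """Stroke-like preset: reduced learning gain, noisier movements."""
        healthy = cls.healthy(hypothesis)
        return cls(
            params=healthy.params.replace(gain=0.4 * healthy.params.gain),
            error_gain=healthy.error_gain,
            motor_noise_sd=2.0 * healthy.motor_noise_sd,
            label="impaired",
        )

    def with_params(self, **kwargs) -> "SubjectProfile":
        return replace(self, params=self.params.replace(**kwargs))


@dataclass(frozen=True)
class NoiseConfig:
    """Kinematic rendering noise.

    Positional jitter is low-pass filtered white noise (SD in meters),
    durations scatter around the reference reach duration, reaction times
    are log-normal, and a configurable fraction of trials is planted
    outside the inclusion bounds to exercise the trial filter.
    """

    position_noise_sd: float = 0.001
    # Gaussian smoothing of the jitter, in samples (75 ms at 200 Hz): slow
    # enough that the derived velocity noise leaves peak-speed scatter in
    # the observed ~0.02 m/s range.
    position_noise_smooth_samples: float = 15.0
    duration_sd: float = 0.035
    rt_median: float = 0.3
    rt_log_sd: float = 0.35
    force_noise_sd: float = 0.1
    speed_outlier_fraction: float = 0.0
    rt_outlier_fraction: float = 0.0


@dataclass
class SubjectDataset:
    """One subject's trial table plus per-trial clamp force traces."""

    table: pd.DataFrame
    clamp_traces: dict
    metadata: dict

    def save(self, directory) -> None:
        """One directory per subject: trial table, traces, JSON metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "trial_table.csv", index=False)
        traces_dir = directory / "clamp_traces"
        traces_dir.mkdir(exist_ok=True)
        for idx, trace in self.clamp_traces.items():
            pd.DataFrame(trace).to_csv(
                traces_dir / f"trial_{idx:04d}.csv", index=False
            )
        with open(directory / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=float)

    @classmethod
    def load(cls, directory) -> "SubjectDataset":
        directory = Path(directory)
        table = pd.read_csv(directory / "trial_table.csv", keep_default_na=False, na_values=[""])
        traces = {}
        for path in sorted((directory / "clamp_traces").glob("trial_*.csv")):
            idx = int(path.stem.split("_")[1])
            df = pd.read_csv(path)
            traces[idx] = {c: df[c].to_numpy() for c in df.columns}
        with open(directory / "metadata.json") as fh:
            metadata = json.load(fh)
        return cls(table=table, clamp_traces=traces, metadata=metadata)


def _render_reach(
    direction: float,
    duration: float,
    rng: np.random.Generator,
    noise: NoiseConfig,
) -> Trajectory:
    clean = min_jerk_trajectory(direction, duration=duration)
    jitter = rng.normal(0.0, 1.0, size=clean.positions.shape)
    jitter = gaussian_filter1d(jitter, noise.position_noise_smooth_samples, axis=0)
    scale = jitter.std(axis=0)
    scale[scale == 0] = 1.0
    jitter = noise.position_noise_sd * jitter / scale
    positions = clean.positions + jitter
    velocities = np.gradient(positions, clean.dt, axis=0)
    return Trajectory(
        dt=clean.dt,
        positions=positions,
        velocities=velocities,
        movement_direction=direction,
    )


def generate_subject(
    profile: SubjectProfile,
    schedule,
    seed: int,
    noise: NoiseConfig = NoiseConfig(),
    initial_state=None,
) -> SubjectDataset:
    """Simulate one subject and render the raw dataset.

    Deterministic given (profile, schedule, seed, noise): the closed-loop
    simulation and the kinematic rendering draw from independent streams
    spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    sim_ss, kin_ss = ss.spawn(2)
    cfg = SimConfig(
        error_gain=profile.error_gain,
        motor_noise_sd=profile.motor_noise_sd,
        seed=int(sim_ss.generate_state(1)[0] % (2**31)),
    )
    records = simulate_experiment(
        schedule, profile.params, cfg, initial_state=initial_state
    )
    rng = np.random.default_rng(kin_ss)
    n = len(records)

    durations = rng.normal(DEFAULT_DURATION_S, noise.duration_sd, size=n)
    durations = np.clip(durations, 0.35, 0.95)
    reaction_times = rng.lognormal(np.log(noise.rt_median), noise.rt_log_sd, size=n)
    # Planted violations for exercising the inclusion filter.
    if noise.speed_outlier_fraction > 0:
        bad = rng.random(n) < noise.speed_outlier_fraction
        slow_or_fast = np.where(rng.random(n) < 0.5, 0.15, 0.65)
        durations[bad] = 1.875 * REACH_DISTANCE_M / slow_or_fast[bad]
    if noise.rt_outlier_fraction > 0:
        bad = rng.random(n) < noise.rt_outlier_fraction
        reaction_times[bad] = np.where(rng.random(n) < 0.5, 0.05, 3.0)[bad]

    peak_speeds = np.empty(n)
    clamp_traces: dict[int, dict] = {}
    for i, record in enumerate(records):
        traj = _render_reach(record.actual_direction, durations[i], rng, noise)
        peak_speeds[i] = traj.peak_speed
        if record.field.mode == "error_clamp":
            state_value = record.adaptation_at_probe * record.field.viscosity
            speed = traj.speed
            measured = state_value * speed + rng.normal(
                0.0, noise.force_noise_sd, size=speed.shape
            )
            ideal = record.field.viscosity * speed
            clamp_traces[i] = {
                "t": traj.t,
                "speed": speed,
                "measured_lateral_force": measured,
                "ideal_lateral_force": ideal,
            }

    table = trial_table(records)
    table["duration"] = durations
    table["peak_speed"] = peak_speeds
    table["reaction_time"] = reaction_times
    metadata = {
        "label": profile.label,
        "hypothesis": profile.params.hypothesis,
        "params": asdict(profile.params),
        "error_gain": profile.error_gain,
        "motor_noise_sd": profile.motor_noise_sd,
        "seed": int(seed),
        "sim_seed": cfg.seed,
        "schedule": getattr(schedule, "metadata", {}),
    }
    return SubjectDataset(table=table, clamp_traces=clamp_traces, metadata=metadata)


def score_clamp_trials(dataset: SubjectDataset) -> pd.DataFrame:
    """Regress each clamp trial's measured force onto its ideal force.

    Returns a copy of the trial table with an ``adaptation_coefficient``
    column (NaN on non-clamp trials). The regression is restricted to the
    movement window (speed above 5% of peak).
    """
    table = dataset.table.copy()
    coef = np.full(len(table), np.nan)
    for idx, trace in dataset.clamp_traces.items():
        coef[idx] = adaptation_coefficient(
            trace["measured_lateral_force"],
            trace["ideal_lateral_force"],
            speed=trace["speed"],
        )
    table["adaptation_coefficient"] = coef
    return table


def generate_cohort(
    n_subjects: int,
    profile: SubjectProfile,
    schedule: Union[object, Callable[[int], object]],
    master_seed: int = 0,
    gain_jitter_sd: float = 0.05,
    retention_jitter_sd: float = 0.005,
    noise: NoiseConfig = NoiseConfig(),
) -> list:
    """Generate a cohort with deterministic per-subject seeds.

    ``schedule`` may be a fixed Schedule shared by every subject or a
    callable ``schedule(subject_seed)`` producing one per subject. Mild
    inter-subject parameter jitter (log-normal on the gain, additive on the
    retention, both configurable) emulates individual differences.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects)
    datasets = []
    for child in children:
        rng = np.random.default_rng(child)
        subject_seed = int(child.generate_state(1)[0] % (2**31))
        params = profile.params
        if gain_jitter_sd > 0:
            params = params.replace(
                gain=params.gain * rng.lognormal(0.0, gain_jitter_sd)
            )
        if retention_jitter_sd > 0:
            params = params.replace(
                retention=float(
                    np.clip(
                        params.retention + rng.normal(0.0, retention_jitter_sd),
                        0.5,
                        1.0,
                    )
                )
            )
        subject_profile = replace(profile, params=params)
        subject_schedule = schedule(subject_seed) if callable(schedule) else schedule
        datasets.append(
            generate_subject(subject_profile, subject_schedule, subject_seed, noise)
        )
    return datasets
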