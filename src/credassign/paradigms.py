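"""Trial schedules for the interference and shifted-target experiments.

Experiment 1 (interference): 254 baseline reaches over nine directions,
then 672 force-field trials at a single training direction in alternating
CW/CCW blocks of 7 +/- 2 trials; after every 168 training trials, a testing
block of 40 consecutive error-clamp trials spread over the nine baseline
directions. The field presented last before each testing block is balanced
across the four blocks. Unbalanced CW:CCW ratios (6:8, 5:9) shorten the CW
blocks and lengthen the CCW blocks.

Experiment 2 (training paradigms): 75 baseline + 125 training trials toward
a desired learning direction (90 deg) in a CW field of 22.5 N/(m/s), with
error-clamp probes at the desired direction randomly interspersed at
probability 0.2. Single-target training (STT) presents the target at the
desired direction on every trial. Left-shifted training (LST) subtracts a
smoothed fit of the mean directional-error history from pilot STT subjects
from the target, so that planned direction + expected error lands on the
desired direction; right-shifted training (RST) mirrors LST about the
desired direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dynamics import ForceFieldSpec

__all__ = [
    "ScheduleEntry",
    "Schedule",
    "interference_schedule",
    "smooth_error_history",
    "shifted_schedules",
    "EXP1_DIRECTIONS_270",
    "EXP1_DIRECTIONS_60",
    "EXP1_TRAIN_VISCOSITY",
    "EXP2_TRAIN_VISCOSITY",
]

#: Baseline/testing directions for the group trained at 270 degrees.
EXP1_DIRECTIONS_270 = (180.0, 210.0, 240.0, 245.0, 270.0, 285.0, 300.0, 330.0, 360.0)
#: Baseline/testing directions for the group trained at 60 degrees.
EXP1_DIRECTIONS_60 = (-30.0, 0.0, 30.0, 45.0, 60.0, 75.0, 90.0, 120.0, 150.0)
#: Interference-task field magnitude, N/(m/s).
EXP1_TRAIN_VISCOSITY = 9.0
#: Shifted-target-task field magnitude, N/(m/s).
EXP2_TRAIN_VISCOSITY = 22.5

_CYCLE_LENGTH = 14
_BLOCK_RANGE = (5, 9)


@dataclass(frozen=True)
class ScheduleEntry:
    phase: str
    target_direction: float
    field: ForceFieldSpec


@dataclass
class Schedule:
    """Ordered trial list plus the metadata needed to regenerate it."""

    entries: list
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.entries)),
                "phase": [e.phase for e in self.entries],
                "target_direction": [e.target_direction for e in self.entries],
                "field_mode": [e.field.mode for e in self.entries],
                "field_viscosity": [e.field.viscosity for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: Optional[dict] = None) -> "Schedule":
        entries = [
            ScheduleEntry(
                phase=row.phase,
                target_direction=float(row.target_direction),
                field=ForceFieldSpec(
                    viscosity=float(row.field_viscosity), mode=row.field_mode
                ),
            )
            for row in df.itertuples()
        ]
        return cls(entries=entries, metadata=metadata or {})

    @classmethod
    def from_csv(cls, path) -> "Schedule":
        # keep_default_na: the literal field mode "null" must survive parsing
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        metadata: dict = {}
        try:
            with open(str(path) + ".json") as fh:
                metadata = json.load(fh)
        except FileNotFoundError:
            pass
        return cls.from_frame(df, metadata)


def _spread_over_directions(n_trials: int, directions, rng) -> np.ndarray:
    """Distribute n_trials as evenly as possible over directions, shuffled."""
    directions = np.asarray(directions, dtype=float)
    base, extra = divmod(n_trials, len(directions))
    counts = np.full(len(directions), base)
    counts[rng.permutation(len(directions))[:extra]] += 1
    out = np.repeat(directions, counts)
    rng.shuffle(out)
    return out


def _cycle_block_lengths(ratio_cw_ccw, n_cycles: int, rng) -> list:
    """Alternating CW/CCW block lengths with antithetic jitter.

    Each cycle holds one CW and one CCW block totaling 14 trials. Jitter j
    is drawn from the symmetric feasible set (both block lengths stay in
    5..9) for even cycles and negated on the following cycle, so counts
    match the requested ratio exactly over every cycle pair and over the
    full run, while block lengths vary by +/-2 when the ratio permits.
    """
    c, w = ratio_cw_ccw
    lo, hi = _BLOCK_RANGE
    feasible = [
        j
        for j in range(-(hi - lo), hi - lo + 1)
        if lo <= c + j <= hi and lo <= w - j <= hi
    ]
    symmetric = [j for j in feasible if -j in feasible]
    lengths = []
    j = 0
    for k in range(n_cycles):
        if k % 2 == 0:
            j = int(rng.choice(symmetric))
            lengths.append((c + j, w - j))
        else:
            lengths.append((c - j, w + j))
    return lengths


def interference_schedule(
    train_dir: float = 270.0,
    baseline_dirs: Sequence[float] = EXP1_DIRECTIONS_270,
    ratio_cw_ccw: tuple[int, int] = (7, 7),
    seed: int = 0,
    viscosity: float = EXP1_TRAIN_VISCOSITY,
    clamp_reference: Optional[float] = None,
    n_baseline: int = 254,
    n_cycles: int = 48,
    cycles_per_segment: int = 12,
    testing_block_length: int = 40,
) -> Schedule:
    """Build the force-field interference schedule.

    The default configuration is 254 null-field baseline trials over the
    nine directions, 48 alternating-block cycles (672 field trials) at the
    training direction, and a 40-trial error-clamp testing block after each
    group of 12 cycles. ``clamp_reference`` is the signed viscosity against
    which testing-block compensation is expressed; it defaults to the CCW
    field, the convention that plots CCW-appropriate adaptation positive.
    """
    if sum(ratio_cw_ccw) != _CYCLE_LENGTH:
        raise ValueError(
            f"ratio_cw_ccw must sum to {_CYCLE_LENGTH}, got {ratio_cw_ccw}"
        )
    if len(baseline_dirs) == 0:
        raise ValueError("baseline_dirs must be non-empty")
    if clamp_reference is None:
        clamp_reference = -abs(viscosity)
    rng = np.random.default_rng(seed)
    entries: list[ScheduleEntry] = []

    for d in _spread_over_directions(n_baseline, baseline_dirs, rng):
        entries.append(ScheduleEntry("baseline", float(d), ForceFieldSpec.null()))

    n_segments = n_cycles // cycles_per_segment
    # Balance the field presented last before each testing block: half the
    # segments end on CW, half on CCW.
    last_fields = np.array([1] * (n_segments // 2) + [-1] * (n_segments - n_segments // 2))
    rng.shuffle(last_fields)
    cycle_lengths = _cycle_block_lengths(ratio_cw_ccw, n_cycles, rng)

    cw = ForceFieldSpec.cw(viscosity)
    ccw = ForceFieldSpec.ccw(viscosity)
    clamp = ForceFieldSpec.error_clamp(clamp_reference)
    for seg in range(n_segments):
        ends_cw = last_fields[seg] > 0
        for k in range(cycles_per_segment):
            n_cw, n_ccw = cycle_lengths[seg * cycles_per_segment + k]
            blocks = [(ccw, n_ccw), (cw, n_cw)] if ends_cw else [(cw, n_cw), (ccw, n_ccw)]
            for spec, n in blocks:
                entries.extend(
                    ScheduleEntry("training", float(train_dir), spec) for _ in range(n)
                )
        for d in _spread_over_directions(testing_block_length, baseline_dirs, rng):
            entries.append(ScheduleEntry("testing", float(d), clamp))

    return Schedule(
        entries=entries,
        metadata={
            "paradigm": "interference",
            "training_direction": float(train_dir),
            "baseline_directions": list(map(float, baseline_dirs)),
            "ratio_cw_ccw": list(ratio_cw_ccw),
            "viscosity": float(viscosity),
            "clamp_reference": float(clamp_reference),
            "block_length_range": list(_BLOCK_RANGE),
            "seed": int(seed),
        },
    )


def probe_block(
    directions: Sequence[float],
    repeats: int,
    reference_viscosity: float,
    seed: int = 0,
    phase: str = "testing",
) -> list:
    """Shuffled block of error-clamp probes over several directions.

    Appending such a block to a single-target schedule adds the
    generalization measurements needed to identify the primitive width
    when fitting the learning rule.
    """
    rng = np.random.default_rng(seed)
    dirs = np.tile(np.asarray(directions, dtype=float), repeats)
    rng.shuffle(dirs)
    clamp = ForceFieldSpec.error_clamp(reference_viscosity)
    return [ScheduleEntry(phase, float(d), clamp) for d in dirs]


def _exponential(n, amplitude, rate):
    return amplitude * np.exp(-rate * n)


def smooth_error_history(
    mean_errors, trial_index=None, n_eval: Optional[int] = None
) -> np.ndarray:
    """Least-squares exponential-decay fit of a mean error history.

    Fits ``a * exp(-n / tau)`` (parametrized by a non-negative rate 1/tau,
    so a constant series is the rate -> 0 limit) and returns the fitted
    curve evaluated at every trial index. ``trial_index`` allows fitting on
    a subset of trials (e.g. field trials only) while evaluating the curve
    on 0..N-1.
    """
    y = np.asarray(mean_errors, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points to fit the error history")
    x = (
        np.arange(y.size, dtype=float)
        if trial_index is None
        else np.asarray(trial_index, dtype=float)
    )
    if x.size != y.size:
        raise ValueError("trial_index must match mean_errors in length")
    a0 = y[0] if abs(y[0]) > 1e-12 else (np.mean(y) or 1.0)
    try:
        popt, _ = curve_fit(
            _exponential,
            x,
            y,
            p0=(a0, 0.1),
            bounds=([-np.inf, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        popt = (np.mean(y), 0.0)
    if n_eval is None:
        n_eval = int(np.max(x)) + 1
    return _exponential(np.arange(n_eval, dtype=float), *popt)


def shifted_schedules(
    desired_dir: float = 90.0,
    smoothed_errors=None,
    p_ec: float = 0.2,
    seed: int = 0,
    viscosity: float = EXP2_TRAIN_VISCOSITY,
    n_baseline: int = 75,
    n_training: int = 125,
) -> tuple[Schedule, Schedule, Schedule]:
    """Build the STT, LST and RST schedules of the training-paradigm task.

    All three schedules share the same error-clamp probe positions (drawn
    once from ``seed`` with probability ``p_ec`` per trial), so paradigm
    comparisons are matched trial for trial. Probes are always directed at
    ``desired_dir``. On training trial n, STT presents the target at the
    desired direction, LST at ``desired_dir - smoothed_errors[n]`` (planned
    plus the expected error lands on the desired direction) and RST at
    ``desired_dir + smoothed_errors[n]`` (the mirror image).
    """
    if not (0.0 < p_ec < 1.0):
        raise ValueError("p_ec must be in (0, 1)")
    smoothed = (
        np.zeros(n_training)
        if smoothed_errors is None
        else np.asarray(smoothed_errors, dtype=float)
    )
    if smoothed.size < n_training:
        raise ValueError("smoothed_errors must cover every training trial")
    rng = np.random.default_rng(seed)
    ec_baseline = rng.random(n_baseline) < p_ec
    ec_training = rng.random(n_training) < p_ec

    cw = ForceFieldSpec.cw(viscosity)
    clamp = ForceFieldSpec.error_clamp(abs(viscosity))

    def build(label: str, shift_sign: float) -> Schedule:
        entries: list[ScheduleEntry] = []
        for i in range(n_baseline):
            spec = clamp if ec_baseline[i] else ForceFieldSpec.null()
            entries.append(ScheduleEntry("baseline", float(desired_dir), spec))
        for n in range(n_training):
            if ec_training[n]:
                entries.append(
                    ScheduleEntry("training", float(desired_dir), clamp)
                )
            else:
                target = desired_dir + shift_sign * smoothed[n]
                entries.append(ScheduleEntry("training", float(target), cw))
        return Schedule(
            entries=entries,
            metadata={
                "paradigm": label,
                "desired_direction": float(desired_dir),
                "viscosity": float(viscosity),
                "p_ec": float(p_ec),
                "seed": int(seed),
            },
        )

    return build("STT", 0.0), build("LST", -1.0), build("RST", +1.0)
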