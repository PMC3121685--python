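"""Measurement pipeline: adaptation coefficients, trial filters,
generalization patterns, peak separation and learning-curve summaries.

The adaptation coefficient is the no-intercept ordinary-least-squares slope
of the lateral force measured on an error-clamp trial onto the ideal
force that would fully compensate the reference field: 1 means full
compensation, 0 a naive subject. The regression window runs from movement
onset to offset, defined as the speed crossing 5% of its peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._angles import angular_difference, wrap_degrees

__all__ = [
    "GeneralizationPattern",
    "InclusionRule",
    "UndefinedCoefficientError",
    "NoBimodalityError",
    "adaptation_coefficient",
    "movement_window",
    "apply_inclusion",
    "generalization_pattern",
    "peak_separation",
    "pattern_correlation",
    "learning_summary",
    "group_comparison",
]


class UndefinedCoefficientError(ValueError):
    """Raised when the ideal force is identically zero."""


class NoBimodalityError(ValueError):
    """Raised when a generalization pattern has no positive peak and
    negative trough above the noise threshold."""


@dataclass(frozen=True)
class InclusionRule:
    """Bounds used to drop grossly irregular trials (strict inequalities).

    Defaults: peak speed inside (0.2, 0.55) m/s, reaction time inside
    (0.075, 2.5) s.
    """

    speed_bounds: tuple = (0.2, 0.55)
    rt_bounds: tuple = (0.075, 2.5)

    def __post_init__(self):
        for lo, hi in (self.speed_bounds, self.rt_bounds):
            if not lo < hi:
                raise ValueError("bounds must satisfy lower < upper")


@dataclass
class GeneralizationPattern:
    """Mean adaptation coefficient versus probe direction."""

    directions: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "direction": self.directions,
                "mean": self.mean,
                "se": self.se,
                "n": self.n,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def pooled_se(self) -> float:
        finite = self.se[np.isfinite(self.se)]
        return float(np.sqrt(np.mean(np.square(finite)))) if finite.size else 0.0


def movement_window(speed: np.ndarray, threshold_fraction: float = 0.05) -> np.ndarray:
    """Boolean mask from movement onset to offset.

    Onset is the first sample with speed above ``threshold_fraction`` of
    the peak; offset the last such sample.
    """
    speed = np.asarray(speed, dtype=float)
    above = speed > threshold_fraction * speed.max()
    if not above.any():
        return np.zeros_like(speed, dtype=bool)
    idx = np.nonzero(above)[0]
    mask = np.zeros_like(speed, dtype=bool)
    mask[idx[0] : idx[-1] + 1] = True
    return mask


def adaptation_coefficient(
    measured, ideal, speed=None, threshold_fraction: float = 0.05
) -> float:
    """No-intercept OLS slope of measured force onto the ideal force.

    If ``speed`` is given, the regression is restricted to the movement
    window (speed above 5% of its peak).
    """
    m = np.asarray(measured, dtype=float)
    i = np.asarray(ideal, dtype=float)
    if m.shape != i.shape:
        raise ValueError("measured and ideal must have equal length")
    if speed is not None:
        mask = movement_window(speed, threshold_fraction)
        m, i = m[mask], i[mask]
    denom = float(np.dot(i, i))
    if denom == 0.0 or not np.isfinite(denom):
        raise UndefinedCoefficientError("ideal force is identically zero")
    return float(np.dot(m, i) / denom)


def apply_inclusion(
    trials: pd.DataFrame, rule: InclusionRule = InclusionRule()
) -> tuple[pd.DataFrame, dict]:
    """Filter a trial table on kinematic summaries.

    Trials are retained iff ``peak_speed`` and ``reaction_time`` fall
    strictly inside the rule's bounds. Trials with missing kinematics are
    flagged in the report and excluded, never silently dropped.
    """
    for col in ("peak_speed", "reaction_time"):
        if col not in trials.columns:
            raise ValueError(f"trial table must have a {col!r} column")
    speed = trials["peak_speed"].to_numpy(dtype=float)
    rt = trials["reaction_time"].to_numpy(dtype=float)
    missing = ~(np.isfinite(speed) & np.isfinite(rt))
    speed_ok = (speed > rule.speed_bounds[0]) & (speed < rule.speed_bounds[1])
    rt_ok = (rt > rule.rt_bounds[0]) & (rt < rule.rt_bounds[1])
    keep = speed_ok & rt_ok & ~missing
    report = {
        "n_total": int(len(trials)),
        "n_retained": int(keep.sum()),
        "n_speed_excluded": int((~speed_ok & ~missing).sum()),
        "n_rt_excluded": int((~rt_ok & ~missing).sum()),
        "n_missing_kinematics": int(missing.sum()),
        "missing_index": trials.index[missing].tolist(),
        "fraction_retained": float(keep.mean()) if len(trials) else float("nan"),
    }
    return trials.loc[keep], report


def generalization_pattern(
    clamp_trials: pd.DataFrame,
    direction_column: str = "target_direction",
    value_column: str = "adaptation_coefficient",
) -> GeneralizationPattern:
    """Per-direction mean and standard error of adaptation coefficients.

    Directions with no finite coefficient are omitted with a warning;
    single-trial directions report SE = 0 (flagged by n = 1).
    """
    df = clamp_trials[[direction_column, value_column]].dropna()
    if df.empty:
        raise ValueError("no clamp trials with finite coefficients")
    dropped = set(clamp_trials[direction_column].unique()) - set(
        df[direction_column].unique()
    )
    if dropped:
        warnings.warn(
            f"directions with no usable clamp trials omitted: {sorted(dropped)}"
        )
    grouped = df.groupby(direction_column)[value_column]
    mean = grouped.mean()
    n = grouped.size()
    se = (grouped.std(ddof=1) / np.sqrt(n)).fillna(0.0)
    order = np.argsort(mean.index.to_numpy())
    return GeneralizationPattern(
        directions=mean.index.to_numpy(dtype=float)[order],
        mean=mean.to_numpy()[order],
        se=se.to_numpy()[order],
        n=n.to_numpy()[order],
    )


def peak_separation(
    directions,
    values,
    se=None,
    training_direction: float = None,
    grid_step: float = 0.5,
) -> float:
    """Wrap-aware distance in degrees between a pattern's extrema.

    The pattern is linearly interpolated onto a ``grid_step`` grid (period
    360). Both a positive maximum and a negative minimum exceeding the
    noise threshold (2x the pooled SE when ``se`` is given) are required,
    otherwise :class:`NoBimodalityError` is raised. Ties are broken toward
    ``training_direction`` when provided.
    """
    d = wrap_degrees(np.asarray(directions, dtype=float))
    v = np.asarray(values, dtype=float)
    order = np.argsort(d)
    d, v = d[order], v[order]
    fine = np.arange(-180.0, 180.0, grid_step)
    pattern = np.interp(fine, d, v, period=360.0)
    threshold = 0.0
    if se is not None:
        finite = np.asarray(se, dtype=float)
        finite = finite[np.isfinite(finite)]
        if finite.size:
            threshold = 2.0 * float(np.sqrt(np.mean(np.square(finite))))
    vmax, vmin = pattern.max(), pattern.min()
    if not (vmax > threshold and vmin < -threshold):
        raise NoBimodalityError(
            "pattern has no positive peak and negative trough above the "
            f"noise threshold ({threshold:.3g})"
        )

    def _pick(candidates):
        if training_direction is None or candidates.size == 1:
            return fine[candidates[0]]
        dist = np.abs(angular_difference(fine[candidates], training_direction))
        return fine[candidates[np.argmin(dist)]]

    tol = 1e-12
    argmax = _pick(np.nonzero(pattern >= vmax - tol)[0])
    argmin = _pick(np.nonzero(pattern <= vmin + tol)[0])
    return float(abs(angular_difference(argmax, argmin)))


def pattern_correlation(predicted, observed) -> float:
    """Pearson correlation between aligned generalization patterns."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise ValueError("need at least 3 aligned points")
    if np.std(p) == 0.0 or np.std(o) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(p, o).statistic)


def learning_summary(clamp_series, window: int = 3) -> dict:
    """Early/late means of an error-clamp adaptation series in trial order.

    Returns a dict with the mean over the first ``window`` probes, the mean
    over the last ``window`` probes, and the full curve.
    """
    curve = np.asarray(clamp_series, dtype=float)
    if curve.size < 2 * window:
        raise ValueError(f"need at least {2 * window} clamp trials")
    return {
        "early": float(curve[:window].mean()),
        "late": float(curve[-window:].mean()),
        "curve": curve,
    }


def group_comparison(groups: dict) -> dict:
    """Plain one-way ANOVA plus pairwise Welch t-tests across groups.

    ``groups`` maps label -> 1-D array of per-subject values. No
    multiple-comparison correction is applied.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    f, p = stats.f_oneway(*samples)
    pairwise = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            t, tp = stats.ttest_ind(samples[i], samples[j], equal_var=False)
            pairwise[f"{labels[i]} vs {labels[j]}"] = {"t": float(t), "p": float(tp)}
    return {
        "anova": {"F": float(f), "p": float(p)},
        "pairwise": pairwise,
        "means": {k: float(np.mean(groups[k])) for k in labels},
    }
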