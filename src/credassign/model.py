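"""Fitting the state-space learning rule to error-clamp data.

`MotorAdaptationModel` plays the role of a statsmodels model object: it is
built from a trial table (or a cohort of synthetic subjects), treats the
observed error-clamp adaptation coefficients as the response, and replays
each subject's recorded trial history - fields, errors and movement
directions - through the learning rule to predict those coefficients as a
deterministic function of (retention, gain, primitive sigma). `fit()`
minimizes the sum of squared residuals and returns a
`MotorAdaptationResults` carrying estimates, Gauss-Newton standard errors
and a `summary()` table.

Because the recursion is linear in the error history, the predicted state
at a clamp probe p on global trial t is the geometric superposition

    x_t(p) = -gain * sum_{k<t} A**(t-1-k) * e_k * g(p - ref_k, sigma)

over prior field trials k, with ref_k the planned (PRL) or actual (MRL)
direction. The predicted coefficient is x_t(p) divided by the clamp's
signed reference viscosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._angles import angular_difference
from .primitives import LearningParams
from .simulate import SimConfig, simulate_experiment

__all__ = ["MotorAdaptationModel", "MotorAdaptationResults"]

_PARAM_NAMES = ("retention", "gain", "primitive_sigma")
_REQUIRED_COLUMNS = (
    "field_mode",
    "field_viscosity",
    "planned_direction",
    "actual_direction",
    "error",
)


@dataclass
class _SubjectHistory:
    """Precomputed replay arrays for one subject."""

    field_trial_index: np.ndarray  # global trial index of each field trial
    errors: np.ndarray
    planned: np.ndarray
    actual: np.ndarray
    clamp_trial_index: np.ndarray  # global trial index of each observed clamp
    clamp_probe: np.ndarray
    clamp_reference: np.ndarray
    observed: np.ndarray


class MotorAdaptationModel:
    """State-space learning model bound to an observed trial table.

    Parameters
    ----------
    trials : DataFrame
        Trial table in the package's dialect (one row per trial, in trial
        order) with a ``subject`` column when several subjects are stacked.
        The response column is ``adaptation_coefficient`` if present (the
        regression-measured coefficient), otherwise ``adaptation_at_probe``.
    hypothesis : {"MRL", "PRL"}
        Credit-assignment reference used for the replay.
    """

    def __init__(self, trials: pd.DataFrame, hypothesis: str = "MRL"):
        missing = [c for c in _REQUIRED_COLUMNS if c not in trials.columns]
        if missing:
            raise ValueError(f"trial table lacks required columns: {missing}")
        if hypothesis not in ("MRL", "PRL"):
            raise ValueError("hypothesis must be 'MRL' or 'PRL'")
        self.hypothesis = hypothesis
        response = (
            "adaptation_coefficient"
            if "adaptation_coefficient" in trials.columns
            else "adaptation_at_probe"
        )
        self.response_column = response
        self._histories: list[_SubjectHistory] = []
        groups = (
            trials.groupby("subject", sort=False)
            if "subject" in trials.columns
            else [(0, trials)]
        )
        for _, df in groups:
            df = df.reset_index(drop=True)
            is_field = (df["field_mode"] == "curl").to_numpy()
            is_clamp = (df["field_mode"] == "error_clamp").to_numpy()
            observed = df[response].to_numpy(dtype=float)
            use_clamp = is_clamp & np.isfinite(observed)
            if not use_clamp.any():
                continue
            self._histories.append(
                _SubjectHistory(
                    field_trial_index=np.nonzero(is_field)[0],
                    errors=df.loc[is_field, "error"].to_numpy(dtype=float),
                    planned=df.loc[is_field, "planned_direction"].to_numpy(float),
                    actual=df.loc[is_field, "actual_direction"].to_numpy(float),
                    clamp_trial_index=np.nonzero(use_clamp)[0],
                    clamp_probe=df.loc[use_clamp, "planned_direction"].to_numpy(float),
                    clamp_reference=df.loc[use_clamp, "field_viscosity"].to_numpy(float),
                    observed=observed[use_clamp],
                )
            )
        if not self._histories:
            raise ValueError("no observed error-clamp coefficients to fit")
        self.endog = np.concatenate([h.observed for h in self._histories])
        self.nobs = self.endog.size

    @classmethod
    def from_subjects(
        cls, datasets: Sequence, hypothesis: str = "MRL"
    ) -> "MotorAdaptationModel":
        """Build from a list of synthetic `SubjectDataset`s.

        Uses the regression-scored coefficient when available, falling back
        to the simulator's probe value.
        """
        from .synthetic import score_clamp_trials

        tables = []
        for s, dataset in enumerate(datasets):
            table = (
                score_clamp_trials(dataset)
                if getattr(dataset, "clamp_traces", None)
                else dataset.table.copy()
            )
            table["subject"] = s
            tables.append(table)
        return cls(pd.concat(tables, ignore_index=True), hypothesis=hypothesis)

    # -- prediction ---------------------------------------------------

    def predict(self, params) -> np.ndarray:
        """Predicted clamp coefficients for (retention, gain, sigma)."""
        retention, gain, sigma = np.asarray(params, dtype=float)
        out = []
        for h in self._histories:
            ref = h.actual if self.hypothesis == "MRL" else h.planned
            # (n_clamp, n_field) decay exponents; field trial k contributes
            # to clamp t iff k precedes t.
            lags = h.clamp_trial_index[:, None] - 1 - h.field_trial_index[None, :]
            mask = lags >= 0
            decay = np.where(mask, retention ** np.clip(lags, 0, None), 0.0)
            tuning = np.exp(
                -np.square(angular_difference(h.clamp_probe[:, None], ref[None, :]))
                / (2.0 * sigma**2)
            )
            state = -gain * (decay * tuning) @ h.errors
            out.append(state / h.clamp_reference)
        return np.concatenate(out)

    # -- fitting ------------------------------------------------------

    def fit(
        self,
        start_params=None,
        bounds=((0.5, 1e-6, 3.0), (0.9999, 0.5, 80.0)),
        **kwargs,
    ) -> "MotorAdaptationResults":
        """Least-squares fit of (retention, gain, primitive_sigma)."""
        if start_params is None:
            start_params = (0.95, 0.02, 30.0)
        x0 = np.clip(np.asarray(start_params, float), bounds[0], bounds[1])

        def residuals(x):
            return self.predict(x) - self.endog

        sol = least_squares(
            residuals, x0, bounds=bounds, x_scale=(0.05, 0.01, 10.0), **kwargs
        )
        n, p = self.nobs, len(sol.x)
        dof = max(n - p, 1)
        s2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        return MotorAdaptationResults(model=self, solution=sol, cov_params=cov)

    # -- simulation ---------------------------------------------------

    def simulate(
        self,
        schedule,
        params: Optional[LearningParams] = None,
        error_gain: float = None,
        motor_noise_sd: float = None,
        seed: int = 0,
    ):
        """Forward closed-loop simulation under this model's hypothesis."""
        from .simulate import DEFAULT_ERROR_GAIN, DEFAULT_MOTOR_NOISE_SD

        params = params or LearningParams(hypothesis=self.hypothesis)
        cfg = SimConfig(
            error_gain=DEFAULT_ERROR_GAIN if error_gain is None else error_gain,
            motor_noise_sd=(
                DEFAULT_MOTOR_NOISE_SD if motor_noise_sd is None else motor_noise_sd
            ),
            seed=seed,
        )
        return simulate_experiment(schedule, params, cfg)


class MotorAdaptationResults:
    """Estimates, uncertainties and diagnostics of a fitted model."""

    def __init__(self, model, solution, cov_params):
        self.model = model
        self._solution = solution
        self.params = pd.Series(solution.x, index=_PARAM_NAMES)
        self.cov = pd.DataFrame(cov_params, index=_PARAM_NAMES, columns=_PARAM_NAMES)
        self.bse = pd.Series(np.sqrt(np.diag(cov_params)), index=_PARAM_NAMES)
        self.fittedvalues = model.predict(solution.x)
        self.resid = self.fittedvalues - model.endog
        self.nobs = model.nobs
        self.ssr = float(np.sum(self.resid**2))
        sst = float(np.sum((model.endog - model.endog.mean()) ** 2))
        self.rsquared = 1.0 - self.ssr / sst if sst > 0 else np.nan
        self.converged = bool(solution.success)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def learning_params(self) -> LearningParams:
        """Fitted parameters as a `LearningParams` for re-simulation."""
        return LearningParams(
            retention=float(self.params["retention"]),
            gain=float(self.params["gain"]),
            primitive_sigma=float(self.params["primitive_sigma"]),
            hypothesis=self.model.hypothesis,
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "        Motor Adaptation Model Results",
            "=" * 58,
            f"Hypothesis:          {self.model.hypothesis:>6}    "
            f"No. clamp obs: {self.nobs:>6}",
            f"R-squared:          {self.rsquared:7.4f}    "
            f"Converged:     {str(self.converged):>6}",
            "-" * 58,
            f"{'':16}{'coef':>10}{'std err':>10}{'[0.025':>10}{'0.975]':>10}",
            "-" * 58,
        ]
        for name in _PARAM_NAMES:
            lines.append(
                f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self):
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<MotorAdaptationResults: {pars}>"
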