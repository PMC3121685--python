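import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from credassign._angles import wrap_degrees
from credassign.primitives import (
    AdaptationState,
    LearningParams,
    TrialError,
    closed_form_state,
    predicted_generalization,
    primitive_activation,
    update_state,
)

angles = st.floats(min_value=-720, max_value=720, allow_nan=False)


def random_history(rng, n, target=90.0, error_scale=15.0):
    """Random (TrialError, field_sign) history around a training target."""
    history = []
    for _ in range(n):
        sign = int(rng.choice([-1, 0, 1]))
        err = float(rng.normal(0.0, error_scale))
        history.append((TrialError(target, target + err), sign))
    return history


def iterate(history, params):
    state = AdaptationState.zeros()
    for trial, sign in history:
        state = update_state(state, trial, sign, params)
    return state


class TestWrap:
    @given(a=angles)
    @settings(max_examples=100, deadline=None)
    def test_wrap_range_and_equivalence(self, a):
        w = wrap_degrees(a)
        assert -180.0 < w <= 180.0
        residue = (a - w) % 360.0
        assert min(residue, 360.0 - residue) == pytest.approx(0.0, abs=1e-6)


class TestPrimitiveActivation:
    def test_peak_and_analytic_point(self):
        assert primitive_activation(0.0, 20.0) == 1.0
        assert primitive_activation(20.0, 20.0) == pytest.approx(np.exp(-0.5))

    @given(d=angles, sigma=st.floats(1.0, 90.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_bounds(self, d, sigma):
        a_pos = primitive_activation(d, sigma)
        a_neg = primitive_activation(-d, sigma)
        assert a_pos == pytest.approx(a_neg, abs=1e-12)
        assert 0.0 <= a_pos <= 1.0

    def test_wraps_across_the_circle(self):
        assert primitive_activation(350.0, 20.0) == pytest.approx(
            primitive_activation(-10.0, 20.0)
        )

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            primitive_activation(10.0, 0.0)


class TestUpdateState:
    def test_pure_decay_without_field(self, mrl_params):
        state = AdaptationState.zeros()
        state.values += 4.0
        trial = TrialError(90.0, 80.0)  # error present but no field
        new = update_state(state, trial, 0, mrl_params)
        np.testing.assert_allclose(new.values, mrl_params.retention * state.values)

    def test_zero_error_is_pure_decay(self, mrl_params):
        state = AdaptationState.zeros()
        state.values += 2.0
        new = update_state(state, TrialError(90.0, 90.0), 1, mrl_params)
        np.testing.assert_allclose(new.values, mrl_params.retention * 2.0)

    @pytest.mark.parametrize("hypothesis,expected_center", [("PRL", 90.0), ("MRL", 70.0)])
    def test_single_bump_centered_at_reference(self, hypothesis, expected_center):
        params = LearningParams(hypothesis=hypothesis)
        state = update_state(
            AdaptationState.zeros(), TrialError(90.0, 70.0), 1, params
        )
        assert state.grid[np.argmax(np.abs(state.values))] == expected_center

    def test_learning_opposes_the_field(self, mrl_params):
        # CW field -> negative error -> positive (CW-compensating) increment.
        cw = update_state(AdaptationState.zeros(), TrialError(90.0, 77.4), 1, mrl_params)
        assert cw.value_at(77.4) > 0
        ccw = update_state(AdaptationState.zeros(), TrialError(90.0, 102.6), -1, mrl_params)
        assert ccw.value_at(102.6) < 0

    def test_cw_gain_scale_only_affects_cw_trials(self):
        base = LearningParams(hypothesis="MRL")
        biased = LearningParams(hypothesis="MRL", cw_gain_scale=2.0)
        trial = TrialError(90.0, 80.0)
        cw_base = update_state(AdaptationState.zeros(), trial, 1, base)
        cw_biased = update_state(AdaptationState.zeros(), trial, 1, biased)
        np.testing.assert_allclose(cw_biased.values, 2.0 * cw_base.values)
        ccw_base = update_state(AdaptationState.zeros(), trial, -1, base)
        ccw_biased = update_state(AdaptationState.zeros(), trial, -1, biased)
        np.testing.assert_allclose(ccw_biased.values, ccw_base.values)


class TestClosedFormOracle:
    def test_empty_history_is_zero(self, mrl_params):
        assert np.all(closed_form_state([], mrl_params).values == 0.0)

    def test_single_trial_matches_update(self, mrl_params):
        history = [(TrialError(90.0, 75.0), 1)]
        np.testing.assert_allclose(
            closed_form_state(history, mrl_params).values,
            iterate(history, mrl_params).values,
        )

    @pytest.mark.parametrize("hypothesis", ["PRL", "MRL"])
    def test_iterated_updates_match_superposition(self, hypothesis, rng):
        params = LearningParams(hypothesis=hypothesis, cw_gain_scale=1.3)
        for _ in range(20):
            history = random_history(rng, int(rng.integers(1, 40)))
            np.testing.assert_allclose(
                iterate(history, params).values,
                closed_form_state(history, params).values,
                atol=1e-12,
            )

    def test_linearity_in_the_error_history(self, rng, mrl_params):
        # The state of a concatenated history equals the decayed state of
        # the first part plus the state of the second part.
        h1 = random_history(rng, 15)
        h2 = random_history(rng, 10)
        full = iterate(h1 + h2, mrl_params).values
        part = (
            mrl_params.retention ** len(h2) * iterate(h1, mrl_params).values
            + iterate(h2, mrl_params).values
        )
        np.testing.assert_allclose(full, part, atol=1e-12)


class TestBalancedInterferenceGeometry:
    """Sign-balanced CW/CCW errors at one target, as in interference training."""

    def balanced_history(self, rng, n_pairs=200, target=90.0):
        history = []
        for _ in range(n_pairs):
            mag = float(rng.normal(12.6, 3.0))
            history.append((TrialError(target, target - mag), 1))   # CW trial
            history.append((TrialError(target, target + mag), -1))  # CCW trial
        return history

    def test_prl_pattern_cancels(self, rng):
        params = LearningParams(hypothesis="PRL", retention=1.0)
        history = self.balanced_history(rng)
        state = closed_form_state(history, params)
        # paired +/- errors at the same reference cancel trial by trial
        scale = params.gain * 12.6 * len(history) / 2
        assert np.abs(state.values).max() < 0.02 * scale

    def test_mrl_pattern_is_bimodal_with_ccw_lobe_above_target(self, rng):
        params = LearningParams(hypothesis="MRL", retention=1.0)
        state = closed_form_state(self.balanced_history(rng), params)
        pattern = predicted_generalization(state, state.grid, 9.0)
        peak_dir = state.grid[np.argmax(pattern)]
        trough_dir = state.grid[np.argmin(pattern)]
        assert peak_dir > 90.0  # CCW-appropriate adaptation above the target
        assert trough_dir < 90.0
        # one positive and one negative lobe: a single sign change among
        # directions carrying appreciable adaptation
        core = pattern[np.abs(pattern) > 0.05 * np.abs(pattern).max()]
        sign_changes = np.sum(np.diff(np.sign(core)) != 0)
        assert sign_changes == 1

    def test_outward_skew_with_error_magnitude_weighting(self, rng):
        # learning proportional to error size pushes the extrema farther
        # apart than the mean CW/CCW actual directions
        params = LearningParams(hypothesis="MRL", retention=1.0)
        history = self.balanced_history(rng)
        state = closed_form_state(history, params)
        actual_cw = np.mean([t.actual_direction for t, s in history if s == 1])
        actual_ccw = np.mean([t.actual_direction for t, s in history if s == -1])
        extrema_sep = abs(
            state.grid[np.argmax(state.values)] - state.grid[np.argmin(state.values)]
        )
        assert extrema_sep > abs(actual_ccw - actual_cw)


class TestPredictedGeneralization:
    def test_zero_state_gives_zero_pattern(self, zero_state):
        pattern = predicted_generalization(zero_state, [0.0, 90.0, 180.0], 9.0)
        assert np.all(pattern == 0.0)

    def test_full_compensation_has_unit_magnitude(self, zero_state):
        zero_state.values += 9.0
        pattern = predicted_generalization(zero_state, [45.0, 90.0], 9.0)
        # CW-compensating state is CCW-inappropriate: magnitude 1, negative
        # on the CCW-positive axis
        np.testing.assert_allclose(np.abs(pattern), 1.0)
        np.testing.assert_allclose(pattern, -1.0)

    def test_zero_reference_rejected(self, zero_state):
        with pytest.raises(ValueError):
            predicted_generalization(zero_state, [0.0], 0.0)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"retention": 0.0}, {"retention": 1.2}, {"gain": -0.1},
        {"primitive_sigma": 0.0}, {"hypothesis": "XYZ"}, {"cw_gain_scale": -1.0},
    ])
    def test_invalid_learning_params(self, kwargs):
        with pytest.raises(ValueError):
            LearningParams(**kwargs)

    def test_state_csv_roundtrip(self, tmp_path, rng):
        state = AdaptationState.zeros()
        state.values = rng.normal(size=state.values.size)
        path = tmp_path / "state.csv"
        state.to_csv(path)
        back = AdaptationState.from_csv(path)
        np.testing.assert_allclose(back.values, state.values)
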