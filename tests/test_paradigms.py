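import numpy as np
import pytest

from credassign.paradigms import (
    Schedule,
    interference_schedule,
    probe_block,
    shifted_schedules,
    smooth_error_history,
)
from credassign.primitives import LearningParams
from credassign.simulate import SimConfig, simulate_experiment


def training_signs(schedule):
    return np.array(
        [np.sign(e.field.viscosity) for e in schedule if e.phase == "training"]
    )


@pytest.fixture(scope="module")
def sched():
    return interference_schedule(seed=5)


@pytest.fixture(scope="module")
def smoothed():
    return -17.0 * np.exp(-np.arange(125) / 8.0)


class TestInterferenceSchedule:

    def test_phase_counts(self, sched):
        df = sched.to_frame()
        counts = df["phase"].value_counts()
        assert counts["baseline"] == 254
        assert counts["training"] == 672
        assert counts["testing"] == 160  # 4 blocks of 40

    def test_testing_blocks_are_consecutive_error_clamps(self, sched):
        df = sched.to_frame()
        testing = df[df["phase"] == "testing"]
        assert set(testing["field_mode"]) == {"error_clamp"}
        # 40 consecutive testing trials after each 168 training trials
        phases = df["phase"].to_numpy()
        block_starts = np.nonzero(
            (phases == "testing") & (np.roll(phases, 1) != "testing")
        )[0]
        assert len(block_starts) == 4
        for start in block_starts:
            assert set(phases[start : start + 40]) == {"testing"}

    @pytest.mark.parametrize("ratio", [(7, 7), (6, 8), (5, 9)])
    def test_cw_ccw_ratio_exact_overall(self, ratio):
        sched = interference_schedule(ratio_cw_ccw=ratio, seed=2)
        signs = training_signs(sched)
        assert (signs > 0).sum() == 48 * ratio[0]
        assert (signs < 0).sum() == 48 * ratio[1]

    def test_five_nine_ratio_has_exact_blocks(self):
        sched = interference_schedule(ratio_cw_ccw=(5, 9), seed=3)
        signs = training_signs(sched)
        # per 14-trial cycle: 5 CW and 9 CCW
        for cycle in signs.reshape(48, 14):
            assert (cycle > 0).sum() == 5
            assert (cycle < 0).sum() == 9

    def test_balanced_block_lengths_vary_within_7pm2(self):
        sched = interference_schedule(ratio_cw_ccw=(7, 7), seed=8)
        signs = training_signs(sched).reshape(4, 168)  # per segment
        lengths = []
        for segment in signs:
            change = np.nonzero(np.diff(segment))[0]
            lengths.extend(np.diff(np.concatenate([[0], change + 1, [168]])))
        lengths = np.array(lengths)
        assert lengths.min() >= 5 and lengths.max() <= 9
        assert len(np.unique(lengths)) > 1  # genuinely stochastic

    def test_last_field_before_testing_balanced(self, sched):
        signs = training_signs(sched).reshape(4, 168)
        last = [segment[-1] for segment in signs]
        assert sorted(last) == [-1, -1, 1, 1]

    def test_baseline_spread_over_directions(self, sched):
        df = sched.to_frame()
        counts = df[df["phase"] == "baseline"]["target_direction"].value_counts()
        assert counts.sum() == 254
        assert counts.min() >= 28 and counts.max() <= 29

    def test_reproducible_from_seed(self):
        a = interference_schedule(seed=9).to_frame()
        b = interference_schedule(seed=9).to_frame()
        assert a.equals(b)
        c = interference_schedule(seed=10).to_frame()
        assert not a.equals(c)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            interference_schedule(ratio_cw_ccw=(6, 9))

    def test_csv_roundtrip(self, sched, tmp_path):
        path = tmp_path / "schedule.csv"
        sched.to_csv(path)
        back = Schedule.from_csv(path)
        assert back.to_frame().equals(sched.to_frame())
        assert back.metadata["ratio_cw_ccw"] == [7, 7]


class TestSmoothErrorHistory:
    def test_exact_exponential_recovered(self):
        n = np.arange(60)
        y = -15.0 * np.exp(-n / 10.0)
        fit = smooth_error_history(y)
        np.testing.assert_allclose(fit, y, atol=1e-6)

    def test_constant_series_recovered(self):
        fit = smooth_error_history(np.full(30, -4.0))
        np.testing.assert_allclose(fit, -4.0, atol=1e-3)

    def test_noisy_exponential_parameter_recovery(self):
        rng = np.random.default_rng(0)
        n = np.arange(125)
        y = -17.0 * np.exp(-n / 8.0) + rng.normal(0, 2.0, size=n.size)
        fit = smooth_error_history(y)
        # recovered amplitude within +/-2 deg, time constant within 25%
        assert fit[0] == pytest.approx(-17.0, abs=2.0)
        tau = -1.0 / np.log(fit[1] / fit[0])
        assert tau == pytest.approx(8.0, rel=0.25)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_error_history([1.0, 2.0])


class TestShiftedSchedules:

    def test_first_targets_mirror_about_desired(self, smoothed):
        stt, lst, rst = shifted_schedules(90.0, smoothed, seed=0)
        lst_ff = [e for e in lst if e.field.mode == "curl"]
        rst_ff = [e for e in rst if e.field.mode == "curl"]
        assert lst_ff[0].target_direction == pytest.approx(107.0)
        assert rst_ff[0].target_direction == pytest.approx(73.0)

    def test_lst_rst_mirror_every_trial(self, smoothed):
        _, lst, rst = shifted_schedules(90.0, smoothed, seed=1)
        for a, b in zip(lst, rst):
            assert a.field.mode == b.field.mode
            assert a.target_direction + b.target_direction == pytest.approx(180.0)

    def test_zero_shifts_collapse_to_stt(self):
        stt, lst, rst = shifted_schedules(90.0, np.zeros(125), seed=2)
        for s in (lst, rst):
            assert s.to_frame().equals(stt.to_frame())

    def test_probe_positions_shared_and_at_desired_direction(self, smoothed):
        stt, lst, rst = shifted_schedules(90.0, smoothed, seed=3, p_ec=0.2)
        for a, b, c in zip(stt, lst, rst):
            assert (a.field.mode == "error_clamp") == (b.field.mode == "error_clamp")
            assert (a.field.mode == "error_clamp") == (c.field.mode == "error_clamp")
            if a.field.mode == "error_clamp":
                assert a.target_direction == b.target_direction == 90.0
        n_ec = sum(e.field.mode == "error_clamp" for e in stt)
        assert 0.1 < n_ec / len(stt) < 0.35

    def test_structure_counts(self, smoothed):
        stt, _, _ = shifted_schedules(90.0, smoothed, seed=4)
        df = stt.to_frame()
        assert (df["phase"] == "baseline").sum() == 75
        assert (df["phase"] == "training").sum() == 125

    def test_invalid_inputs(self, smoothed):
        with pytest.raises(ValueError):
            shifted_schedules(90.0, smoothed, p_ec=0.0)
        with pytest.raises(ValueError):
            shifted_schedules(90.0, np.zeros(10))

    def test_lst_aligns_actual_motion_with_desired_direction(self):
        # A subject whose error gain matches the calibration run reaches
        # close to the desired direction throughout LST training, while the
        # RST misalignment is about twice the STT misalignment.
        params = LearningParams(hypothesis="MRL", gain=0.165)
        cfg = SimConfig(error_gain=17 / 22.5, motor_noise_sd=0.0, seed=0)
        stt0, _, _ = shifted_schedules(90.0, np.zeros(125), seed=5)
        pilot = simulate_experiment(stt0, params, cfg)
        errors = np.array(
            [r.error if r.field.mode == "curl" else np.nan
             for r in pilot if r.phase == "training"]
        )
        ff = np.isfinite(errors)
        smoothed = smooth_error_history(
            errors[ff], trial_index=np.nonzero(ff)[0], n_eval=errors.size
        )
        stt, lst, rst = shifted_schedules(90.0, smoothed, seed=5)

        def mean_misalignment(schedule):
            records = simulate_experiment(schedule, params, cfg)
            actual = [
                r.actual_direction for r in records
                if r.phase == "training" and r.field.mode == "curl"
            ]
            return abs(np.mean(actual) - 90.0)

        assert mean_misalignment(lst) < 2.0
        assert mean_misalignment(rst) == pytest.approx(
            2.0 * mean_misalignment(stt), rel=0.35
        )


class TestProbeBlock:
    def test_block_contents_and_determinism(self):
        dirs = [60.0, 90.0, 120.0]
        a = probe_block(dirs, repeats=2, reference_viscosity=22.5, seed=1)
        b = probe_block(dirs, repeats=2, reference_viscosity=22.5, seed=1)
        assert [e.target_direction for e in a] == [e.target_direction for e in b]
        assert sorted(e.target_direction for e in a) == sorted(dirs * 2)
        assert all(e.field.mode == "error_clamp" for e in a)
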