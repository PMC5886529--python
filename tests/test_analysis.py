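"""Trajectory preprocessing: normalization, correctness rule, averaging,
RT, changes of mind, heading angle, pull-back exclusion."""

import numpy as np
import pytest

from numreach.analysis import (
    classify_correct,
    compute_rt,
    detect_changes_of_mind,
    exclude_pullbacks,
    flip_and_average,
    heading_angle,
    normalize_time,
    normalize_trial,
    summary_table,
)
from numreach.controller import minjerk_closed_form
from numreach.trials import SimTrial, TrialDataset


def make_trial(x, depth=None, dt=0.005, correct_side="right", trial_id=0,
               ratio=0.5, rt_ms=400.0, com_count=0):
    x = np.asarray(x, dtype=float)
    return SimTrial(
        trial_id=trial_id, n_left=5, n_right=10, ratio=ratio,
        correct_side=correct_side, tf_s=(len(x) - 1) * dt, dt=dt,
        x_cm=x, depth_cm=None if depth is None else np.asarray(depth, float),
        choice="right" if x[-1] >= 0 else "left",
        correct=None if correct_side is None else classify_correct(
            np.interp(np.linspace(0, len(x) - 1, 101), np.arange(len(x)), x),
            correct_side),
        rt_ms=rt_ms, com_count=com_count,
    )


class TestNormalizeTime:
    def test_identity_on_uniform_101(self):
        t = np.linspace(0, 1, 101)
        x = np.sin(t * 3)
        np.testing.assert_allclose(normalize_time(t, x), x)

    def test_constant_series(self):
        out = normalize_time([0.0, 0.5, 1.0], [2.0, 2.0, 2.0])
        assert out.shape == (101,)
        np.testing.assert_allclose(out, 2.0)

    def test_exact_on_affine_functions(self):
        t = np.linspace(0, 2, 51)
        x = 3.0 * t - 1.0
        out = normalize_time(t, x)
        np.testing.assert_allclose(out, 3.0 * np.linspace(0, 2, 101) - 1.0, atol=1e-12)

    def test_rejects_short_or_unsorted_input(self):
        with pytest.raises(ValueError):
            normalize_time([0.0], [1.0])
        with pytest.raises(ValueError):
            normalize_time([0.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassifyCorrect:
    def test_all_points_on_correct_side(self):
        assert classify_correct(np.linspace(0.1, 10, 101), "right")

    def test_endpoint_clause_dominates(self):
        x = np.concatenate([np.full(100, 5.0), [-0.5]])
        assert not classify_correct(x, "right")

    def test_majority_count_rule(self):
        # 50 points correct side, 51 wrong side including the endpoint
        x = np.concatenate([np.full(50, 2.0), np.full(51, -2.0)])
        assert not classify_correct(x, "right")
        # 51 correct incl. endpoint, 50 wrong
        x2 = np.concatenate([np.full(50, -2.0), np.full(51, 2.0)])
        assert classify_correct(x2, "right")


class TestFlipAndAverage:
    def test_mirror_pair_averages_to_either(self):
        t_right = make_trial(np.linspace(0, 10, 121), correct_side="right")
        t_left = make_trial(-np.linspace(0, 10, 121), correct_side="left", trial_id=1)
        summ = flip_and_average(TrialDataset([t_right, t_left]))
        s = summ[0.5]
        np.testing.assert_allclose(
            s.mean_trajectory, np.linspace(0, 10, 101), atol=1e-9
        )
        assert s.accuracy == 1.0
        assert s.n_trials == 2

    def test_hp_equals_mean_of_trajectory_points(self):
        traj = minjerk_closed_form(10.0, 0.6, np.linspace(0, 0.6, 121))
        trial = make_trial(traj)
        s = flip_and_average(TrialDataset([trial]), truncate_frac=None)[0.5]
        assert s.hp == pytest.approx(s.mean_trajectory.mean())
        ref = minjerk_closed_form(10.0, 0.6, np.linspace(0, 0.6, 101)).mean()
        assert s.hp == pytest.approx(ref, rel=1e-6)

    def test_global_mirror_invariance(self, small_block):
        mirrored = []
        for t in small_block:
            m = SimTrial(**{**t.__dict__,
                            "x_cm": -t.x_cm,
                            "correct_side": {"left": "right", "right": "left",
                                             None: None}[t.correct_side],
                            "choice": {"left": "right", "right": "left"}[t.choice]})
            mirrored.append(m)
        s1 = flip_and_average(small_block)
        s2 = flip_and_average(TrialDataset(mirrored, dict(small_block.meta)))
        for r in s1:
            np.testing.assert_allclose(s1[r].mean_trajectory, s2[r].mean_trajectory,
                                       atol=1e-9)
            assert s1[r].accuracy == s2[r].accuracy

    def test_empty_group_warns(self):
        t = make_trial(np.linspace(0, -10, 121), correct_side="right")  # incorrect
        with pytest.warns(RuntimeWarning):
            summ = flip_and_average(TrialDataset([t]))
        assert summ[0.5].n_trials == 0
        assert np.isnan(summ[0.5].hp)

    def test_summary_table_columns(self, small_block):
        table = summary_table(flip_and_average(small_block))
        assert list(table.columns) == ["ratio", "hp_cm", "accuracy", "mean_rt_ms",
                                       "com_rate", "n_trials"]
        assert len(table) == 3


class TestComputeRT:
    def test_immobile_trajectory_has_no_rt(self):
        assert compute_rt(np.zeros(100), np.zeros(100), 0.001) is None

    def test_additivity_of_ndt(self):
        # crosses 0.28 mm at a known tick; ndt adds on top
        x = np.concatenate([np.zeros(120), np.linspace(0, 1, 80)])
        rt = compute_rt(x, None, 0.001, ndt_ms=300.0)
        # ramp steps of 1/79 cm: cumulative displacement passes 0.28 mm on
        # the third ramp step, i.e. at tick 123
        assert rt == pytest.approx(123.0 + 300.0)
        assert compute_rt(x, None, 0.001, ndt_ms=200.0) == pytest.approx(123.0 + 200.0)

    def test_rt_decreases_with_constant_weight(self):
        # more certainty -> faster displacement -> earlier RT
        from numreach.controller import ControllerConfig, KinematicState, step

        rts = []
        for w in (0.2, 0.5, 1.0):
            cfg = ControllerConfig(weight_mode="unweighted")
            s = KinematicState.zeros(0.6, n_axes=2)
            xs, ds = [0.0], [0.0]
            for _ in range(600):
                s = step(s, [10.0, 29.0], w, cfg)
                xs.append(s.position[0]); ds.append(s.position[1])
            rts.append(compute_rt(np.array(xs), np.array(ds), 0.001, ndt_ms=300.0))
        assert rts[0] > rts[1] > rts[2]


class TestChangesOfMind:
    def test_monotone_approach_has_none(self):
        count, dirs = detect_changes_of_mind(np.linspace(0, 10, 200))
        assert count == 0 and dirs == []

    def test_single_excursion_detected_and_labelled(self):
        x = np.concatenate([np.linspace(0, -1.5, 60), np.linspace(-1.5, 10, 140)])
        count, dirs = detect_changes_of_mind(x, endpoint_is_correct=True)
        assert count == 1
        assert dirs == ["incorrect_to_correct"]

    def test_shallow_excursion_ignored(self):
        x = np.concatenate([np.linspace(0, -0.6, 60), np.linspace(-0.6, 10, 140)])
        assert detect_changes_of_mind(x)[0] == 0

    def test_double_change_of_mind(self):
        x = np.concatenate([
            np.linspace(0, -1.5, 50), np.linspace(-1.5, 2, 50),
            np.linspace(2, -1.2, 50), np.linspace(-1.2, 10, 60),
        ])
        count, dirs = detect_changes_of_mind(x, endpoint_is_correct=True)
        assert count == 2

    def test_count_invariant_to_time_normalization(self):
        x = np.concatenate([np.linspace(0, -1.5, 300), np.linspace(-1.5, 10, 700)])
        raw_count = detect_changes_of_mind(x)[0]
        normed = normalize_time(np.arange(x.size), x)
        assert detect_changes_of_mind(normed)[0] == raw_count == 1


class TestHeadingAngle:
    def test_straight_ahead_is_zero(self):
        depth = minjerk_closed_form(29.0, 0.6, np.linspace(0, 0.6, 121))
        assert heading_angle(np.zeros(121), depth, 0.005) == pytest.approx(0.0)

    def test_pure_lateral_is_ninety(self):
        x = minjerk_closed_form(10.0, 0.6, np.linspace(0, 0.6, 121))
        assert heading_angle(x, None, 0.005) == pytest.approx(90.0)

    def test_diagonal_is_forty_five(self):
        ramp = np.linspace(0, 10, 121)
        assert heading_angle(ramp, ramp.copy(), 0.005) == pytest.approx(45.0)

    def test_immobile_is_undefined(self):
        assert np.isnan(heading_angle(np.zeros(50), np.zeros(50), 0.005))


class TestExcludePullbacks:
    @staticmethod
    def _dataset(n_normal, n_pullback):
        trials = []
        t = np.linspace(0, 0.6, 121)
        for i in range(n_normal):
            depth = minjerk_closed_form(29.0, 0.6, t)
            trials.append(make_trial(np.linspace(0, 10, 121), depth, trial_id=i))
        for i in range(n_pullback):
            depth = minjerk_closed_form(29.0, 0.6, t).copy()
            depth[60:80] = depth[60] - np.linspace(0, 2.0, 20)  # retreat 2 cm
            trials.append(make_trial(np.linspace(0, 10, 121), depth,
                                     trial_id=n_normal + i))
        return TrialDataset(trials)

    def test_monotone_depth_kept_and_injected_removed(self):
        data = self._dataset(18, 2)
        kept, rate = exclude_pullbacks(data)
        assert len(kept) == 18
        assert rate == pytest.approx(0.1)
        assert all(not np.any(np.diff(t.depth_cm) < -0.01) for t in kept)


class TestNormalizeTrial:
    def test_depth_truncation_shortens_window(self):
        t = np.linspace(0, 0.6, 121)
        x = minjerk_closed_form(10.0, 0.6, t)
        depth = minjerk_closed_form(29.0, 0.6, t)
        trial = make_trial(x, depth)
        full = normalize_trial(trial, truncate_frac=None)
        cut = normalize_trial(trial, truncate_frac=0.99)
        # truncated trajectory stops short of the endpoint value
        assert cut.horizontal[-1] <= full.horizontal[-1]
        assert len(cut.horizontal) == 101
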