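"""Trial composition: threshold-free model, accumulation gate, and the
traditional collapsing-bound accumulator."""

import math

import numpy as np
import pytest
from scipy import special

from numreach.evidence import StimulusPair, predicted_error_rate
from numreach.simulator import (
    BlockDesign,
    DDMParams,
    ModelParams,
    collapsing_threshold,
    drift_for_ratio,
    simulate_block,
    simulate_ddm_block,
    simulate_ddm_trial,
    simulate_trial,
    simulate_trial_thresholded,
)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r_ms": 0.5},
            {"r_ms": 150.0},
            {"d": 1.5},
            {"w": 0.0},
            {"omega": 0.0},
            {"ndt_ms": 100.0},
            {"threshold": -1.0},
        ],
    )
    def test_bounds_enforced(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)


class TestSimulateTrial:
    def test_noisefree_easy_trial_is_deterministic_and_direct(self, rng):
        # omega -> 0: certainty rises deterministically, endpoint on target
        params = ModelParams(omega=1e-12, d=1.0, w=16.0)
        trial = simulate_trial(params, StimulusPair(1, 10), 0.6, rng=rng)
        assert trial.correct
        assert trial.com_count == 0
        assert trial.x_cm[-1] == pytest.approx(10.0, abs=0.1)
        assert np.all(np.diff(trial.certainty) >= -1e-12)

    def test_holds_still_before_first_sample(self, rng):
        params = ModelParams(r_ms=50.0, omega=0.17)
        trial = simulate_trial(params, StimulusPair(1, 10), 0.6, rng=rng)
        # samples arrive at 50 ms; no displacement before then
        assert np.all(trial.x_cm[:50] == 0.0)
        assert np.all(trial.depth_cm[:50] == 0.0)

    def test_trajectory_length_and_rt_floor(self, rng):
        params = ModelParams(omega=0.17, ndt_ms=300.0)
        trial = simulate_trial(params, StimulusPair(1, 10), 0.6, rng=rng)
        assert trial.n_steps == round(0.6 / trial.dt)
        assert trial.rt_ms >= params.ndt_ms

    def test_choice_consistent_with_endpoint(self, rng):
        params = ModelParams(omega=0.3)
        for _ in range(20):
            t = simulate_trial(params, StimulusPair(9, 10), 0.5, rng=rng)
            assert t.choice == t.endpoint_side

    def test_short_trial_flagged_no_evidence(self, rng):
        params = ModelParams(r_ms=100.0)
        trial = simulate_trial(params, StimulusPair(1, 10), 0.05, rng=rng)
        assert trial.meta.get("no_evidence")
        assert not trial.responded
        assert np.all(trial.x_cm == 0.0)

    def test_mirror_symmetry(self):
        params = ModelParams(omega=0.25, d=1.0, w=4.0)
        t1 = simulate_trial(params, StimulusPair(5, 10), 0.6,
                            rng=np.random.default_rng(7))
        t2 = simulate_trial(params, StimulusPair(10, 5), 0.6,
                            rng=np.random.default_rng(7))
        np.testing.assert_allclose(t1.x_cm, -t2.x_cm)
        np.testing.assert_allclose(t1.depth_cm, t2.depth_cm)

    def test_equal_count_trials_tilt_but_average_out(self):
        # ratio-1 trials: single reaches commit to a side, the signed mean
        # stays near the midline
        params = ModelParams(omega=0.17, d=1.0, w=4.0)
        design = BlockDesign(ratios=(1.0,), trials_per_ratio=480)
        data = simulate_block(params, design, seed=11)
        endpoints = np.array([t.x_cm[-1] for t in data])
        assert np.mean(np.abs(endpoints) > 1.0) > 0.5  # single trials tilt
        assert abs(endpoints.mean()) < np.abs(endpoints).mean() / 3

    def test_satisficing_reaches_target_on_equal_counts(self):
        # the certainty-only model stalls short of the screen on ties; the
        # satisficing release drives the finger all the way to a target
        base = ModelParams(omega=0.17, d=0.06, w=16.0)
        sat = ModelParams(omega=0.17, d=0.06, w=16.0, satisficing=True)
        design = BlockDesign(ratios=(1.0,), trials_per_ratio=240)
        plain = simulate_block(base, design, seed=13)
        satis = simulate_block(sat, design, seed=13)
        final_plain = np.mean([abs(t.x_cm[-1]) for t in plain])
        final_sat = np.mean([abs(t.x_cm[-1]) for t in satis])
        assert final_sat > final_plain
        assert final_sat > 0.9 * 10.0  # essentially full arrival


class TestAccumulationGate:
    def test_zero_gate_equals_threshold_free(self):
        p0 = ModelParams(omega=0.2, threshold=0.0)
        p1 = ModelParams(omega=0.2, threshold=1e-12)
        t0 = simulate_trial(p0, StimulusPair(5, 10), 0.6, rng=np.random.default_rng(3))
        t1 = simulate_trial(p1, StimulusPair(5, 10), 0.6, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(t0.x_cm, t1.x_cm)

    def test_tiny_threshold_passes_on_first_sample(self):
        # 5 vs 10 at omega 0.17 with a 0.27 gate: ~0.6% of first samples
        # fail, so essentially every trial starts moving on the first sample
        params = ModelParams(omega=0.17, threshold=0.27)
        rng = np.random.default_rng(5)
        starts_on_first = 0
        n = 400
        for _ in range(n):
            t = simulate_trial(params, StimulusPair(5, 10), 0.6, rng=rng)
            moved = np.flatnonzero(t.x_cm != 0.0)
            # jerk propagates to position over three Euler ticks
            if moved.size and moved[0] * t.dt * 1000.0 <= params.r_ms + 3.5:
                starts_on_first += 1
        assert starts_on_first / n >= 0.97

    def test_unreachable_gate_flags_nonresponsive(self, rng):
        params = ModelParams(omega=0.17, threshold=1e6)
        trial = simulate_trial_thresholded(params, StimulusPair(1, 10), 0.6, rng=rng)
        assert not trial.responded
        assert trial.meta.get("gate_never_opened")
        assert np.all(trial.x_cm == 0.0)

    def test_thresholded_requires_positive_gate(self, rng):
        with pytest.raises(ValueError):
            simulate_trial_thresholded(ModelParams(), StimulusPair(1, 10), 0.6, rng=rng)


class TestBlock:
    def test_counts_and_counterbalance(self):
        design = BlockDesign(ratios=(0.1, 0.9), trials_per_ratio=40)
        data = simulate_block(ModelParams(), design, seed=1)
        assert len(data) == 80
        for ratio, trials in data.by_ratio().items():
            sides = [t.correct_side for t in trials]
            assert sides.count("left") == sides.count("right") == 20

    def test_bit_identical_under_seed(self):
        design = BlockDesign(ratios=(0.5,), trials_per_ratio=12)
        a = simulate_block(ModelParams(), design, seed=9)
        b = simulate_block(ModelParams(), design, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x_cm, tb.x_cm)
            np.testing.assert_array_equal(ta.raw, tb.raw)
            assert ta.rt_ms == tb.rt_ms

    def test_accuracy_bounded_below_by_single_sample_rule(self):
        # D = 1, long flights: averaging many samples can only beat one sample
        params = ModelParams(omega=0.25, d=1.0, w=4.0)
        design = BlockDesign(ratios=(0.75,), trials_per_ratio=1500)
        data = simulate_block(params, design, seed=21)
        graded = [t.correct for t in data if t.correct is not None and t.responded]
        acc = np.mean(graded)
        pair = StimulusPair(3, 4)
        bound = 1.0 - predicted_error_rate(pair, 0.25)
        # allow 3 binomial sigmas around the bound
        sigma = math.sqrt(bound * (1 - bound) / len(graded))
        assert acc >= bound - 3 * sigma


class TestDriftAndBound:
    def test_drift_vanishes_at_equal_ratio(self):
        assert drift_for_ratio(1.0, 0.28) == 0.0

    def test_drift_vanishes_at_large_scale(self):
        assert drift_for_ratio(0.5, 1e9) == pytest.approx(0.0, abs=1e-6)

    def test_drift_matches_erfc_arithmetic(self):
        ratio, dft = 0.1, 0.28
        ref = 1.0 - special.erfc(abs(ratio - 1.0) / (math.sqrt(2) * dft * math.hypot(ratio, 1.0)))
        assert drift_for_ratio(ratio, dft) == pytest.approx(ref, rel=1e-12)

    def test_collapse_values(self):
        assert collapsing_threshold(0.62, 3.56, 0.0) == 0.62
        assert collapsing_threshold(0.62, 0.0, 5.0) == 0.62
        assert collapsing_threshold(0.62, 3.56, 1.0) == pytest.approx(0.62 / 2**3.56)


class TestDDM:
    def test_zero_drift_splits_evenly(self):
        ddm = DDMParams(thr=0.5, dft=0.28, sig2=0.14, k=0.0)
        design = BlockDesign(ratios=(1.0,), trials_per_ratio=800)
        data = simulate_ddm_block(ddm, design, seed=2)
        # the symmetric random walk crosses either bound equally often
        sides = [t.meta["crossing_side"] for t in data if t.responded]
        frac_right = np.mean([s == "right" for s in sides])
        assert frac_right == pytest.approx(0.5, abs=0.06)

    def test_published_fit_reproduces_orderings(self):
        data = simulate_ddm_block(DDMParams(), BlockDesign(trials_per_ratio=480), seed=3)
        from numreach.fitting import ddm_targets

        tg = ddm_targets(data)
        ratios = sorted(tg)
        accs = [tg[r][0] for r in ratios]
        rts = [tg[r][1][2] for r in ratios]
        assert accs[-1] < accs[0]  # harder -> less accurate
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(accs, accs[1:]))
        assert rts[-1] > rts[0]  # harder -> slower

    def test_rt_is_crossing_plus_ndt(self, rng):
        ddm = DDMParams(ndt_s=0.19)
        trial = simulate_ddm_trial(ddm, 0.1, 0.6, rng=rng)
        assert trial.rt_ms == pytest.approx(trial.meta["decision_ms"] + 190.0)

    def test_nonresponse_flagged(self, rng):
        ddm = DDMParams(thr=1e9, dft=0.28, sig2=0.01, k=0.0, max_decision_s=0.05)
        trial = simulate_ddm_trial(ddm, 0.9, 0.5, rng=rng)
        assert not trial.responded
        assert trial.rt_ms is None

    def test_second_threshold_and_deadline_straighten_reaches(self):
        # post-lift-off commitment: after the deadline the target is locked
        # and average trajectories collapse toward a common direct path
        base = DDMParams()
        ext = DDMParams(second_thr=1.02, deadline_ms=51.0)
        design = BlockDesign(ratios=(0.75, 0.9), trials_per_ratio=400)
        d_base = simulate_ddm_block(base, design, seed=4)
        d_ext = simulate_ddm_block(ext, design, seed=4)
        from numreach import analysis

        s_base = analysis.flip_and_average(d_base)
        s_ext = analysis.flip_and_average(d_ext)
        spread_base = abs(s_base[0.75].hp - s_base[0.9].hp)
        spread_ext = abs(s_ext[0.75].hp - s_ext[0.9].hp)
        assert spread_ext <= spread_base + 0.05
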