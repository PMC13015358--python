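import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

import pigeontask as pt
from pigeontask import behavior_analysis as ba
from pigeontask import synthetic_cohort as sc


class TestEstimateNdt:
    def test_monotone_trial_ties_break_to_smallest_delay(self):
        positions = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        est = pt.estimate_ndt([(positions, 5, 1)])
        assert est.ndt_steps == 0
        assert all(c == 1.0 for c in est.congruence_by_delay.values())

    def test_zero_positions_excluded_from_denominator(self):
        positions = np.array([0.0, 0.0, 0.2, 0.3])
        est = pt.estimate_ndt([(positions, 3, 1)])
        # delay 2 probes the exact-zero position; with a single trial that
        # delay has no scorable trials and is warned down to 0
        assert est.congruence_by_delay[0] == 1.0

    def test_recovers_known_motor_delay(self, block2):
        rng = np.random.default_rng(3)
        policy = pt.AgentPolicy(
            bound_schedule=pt.BoundSchedule("constant", level=0.25),
            ndt_steps=2,
            fast_guess_prob=0.15,
        )
        recs = [pt.simulate_trial(policy, block2, rng) for _ in range(200)]
        trials = [(r.walk.positions, r.rt_steps, r.choice) for r in recs]
        est = pt.estimate_ndt(trials)
        # independent oracle: exhaustive congruence scan
        def oracle(d):
            agree = tot = 0
            for pos, rt, ch in trials:
                i = rt - d
                if i < 0 or pos[i] == 0:
                    continue
                tot += 1
                agree += np.sign(pos[i]) == ch
            return agree / tot

        scan = {d: oracle(d) for d in range(5)}
        best = min([d for d in scan if scan[d] == max(scan.values())])
        assert est.ndt_steps == best == 2

    def test_recovery_rate_across_default_cohort(self, block2):
        rng = np.random.default_rng(4)
        hits = 0
        n_agents = 40
        for _ in range(n_agents):
            policy = pt.AgentPolicy(
                bound_schedule=pt.BoundSchedule(
                    "constant", level=float(rng.uniform(*sc.DEFAULT_BOUND_RANGE))
                ),
                ndt_steps=int(rng.choice(list(sc.DEFAULT_NDT_CHOICES))),
                fast_guess_prob=float(rng.uniform(*sc.DEFAULT_FAST_GUESS_RANGE)),
            )
            recs = [pt.simulate_trial(policy, block2, rng) for _ in range(200)]
            est = pt.estimate_ndt(
                (r.walk.positions, r.rt_steps, r.choice) for r in recs
            )
            hits += est.ndt_steps == policy.ndt_steps
        assert hits / n_agents >= 0.95


class TestDecisionTimeAndBound:
    @pytest.mark.parametrize("rt,ndt,expected", [(10, 2, 8), (1, 4, 1), (3, 3, 1)])
    def test_decision_time(self, rt, ndt, expected):
        assert pt.decision_time(rt, ndt) == expected

    @pytest.mark.parametrize(
        "positions,dt,expected",
        [
            ([0, 0.1, 0.25], 2, 0.175),
            ([0, 0.12], 1, 0.06),
            ([0, -0.1, -0.3], 2, 0.2),
        ],
    )
    def test_measure_raw_bound(self, positions, dt, expected):
        m = pt.measure_raw_bound(np.array(positions, dtype=float), dt)
        assert m.raw_bound == pytest.approx(expected)

    def test_measure_raw_bound_beyond_walk_is_error(self):
        with pytest.raises(ValueError):
            pt.measure_raw_bound(np.array([0.0, 0.1]), 2)

    @given(
        pos=hnp.arrays(
            np.float64,
            st.integers(2, 20),
            elements=st.floats(-0.8, 0.8, allow_nan=False),
        ),
        dt=st.integers(1, 19),
    )
    def test_mirror_invariance(self, pos, dt):
        pos[0] = 0.0
        dt = min(dt, len(pos) - 1)
        a = pt.measure_raw_bound(pos, dt).raw_bound
        b = pt.measure_raw_bound(-pos, dt).raw_bound
        assert a == pytest.approx(b)


class TestRegressions:
    def test_constant_bounds_give_zero_slope(self):
        dts = [3, 4, 5, 6, 7, 8]
        bounds = [0.4] * 6
        assert pt.bound_vs_dt_slope(dts, bounds) == pytest.approx(0.0)

    def test_short_dts_excluded(self):
        # only two distinct DTs survive the exclusion; slope uses their medians
        dts = [1, 2, 3, 3, 9]
        bounds = [0.9, 0.9, 0.2, 0.4, 0.6]
        slope = pt.bound_vs_dt_slope(dts, bounds)
        assert slope == pytest.approx((0.6 - 0.3) / 6)

    def test_insufficient_dts_returns_none(self):
        with pytest.warns(UserWarning):
            assert pt.bound_vs_dt_slope([3, 3], [0.2, 0.3]) is None

    def test_iid_bounds_regress_to_mean_with_unit_slope(self):
        rng = np.random.default_rng(5)
        b = rng.normal(0.3, 0.05, 10_000)
        assert pt.bound_change_regression(b) == pytest.approx(1.0, abs=0.05)

    def test_random_walk_bounds_have_zero_slope(self):
        rng = np.random.default_rng(6)
        b = 0.4 + np.cumsum(rng.normal(0, 0.01, 10_000))
        assert pt.bound_change_regression(b) == pytest.approx(0.0, abs=0.05)

    def test_constant_bounds_are_degenerate(self):
        assert pt.bound_change_regression([0.3, 0.3, 0.3, 0.3]) is None
        assert pt.bound_change_regression([0.3, 0.4]) is None


class TestZscore:
    def test_two_trials(self):
        z = pt.zscore_bounds([0.2, 0.4])
        np.testing.assert_allclose(z, [-0.7071, 0.7071], atol=1e-4)

    @given(
        b=hnp.arrays(
            np.float64,
            st.integers(3, 50),
            elements=st.floats(0.01, 0.79, allow_nan=False),
        )
    )
    def test_normalization_invariant(self, b):
        if np.std(b, ddof=1) < 1e-6:  # numerically degenerate spread
            return
        z = pt.zscore_bounds(b)
        assert z.mean() == pytest.approx(0.0, abs=1e-7)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-7)

    def test_zero_variance_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            z = pt.zscore_bounds([0.3, 0.3, 0.3])
        np.testing.assert_array_equal(z, 0.0)


class TestTableLevel:
    def test_participant_summary_accuracy(self, analyzed_block2_cohort):
        trials, analyzed = analyzed_block2_cohort
        summary = pt.participant_summary(analyzed)
        # independent naive recomputation from the raw trial table
        naive = trials.groupby("participant_id")["correct"].mean()
        merged = summary.set_index("participant_id")
        np.testing.assert_allclose(merged["accuracy"], naive, atol=1e-12)
        naive_rr = trials.groupby("participant_id").apply(
            lambda g: g["coins_delta"].sum() / g["steps_cost"].sum(),
            include_groups=False,
        )
        np.testing.assert_allclose(merged["reward_rate"], naive_rr, atol=1e-12)

    def test_left_right_bound_symmetry(self, analyzed_block2_cohort):
        _, analyzed = analyzed_block2_cohort
        rel = analyzed[(analyzed["dt"] > 2) & (analyzed["forced"] == 0)]
        per = rel.groupby(["participant_id", "choice"])["raw_bound"].median()
        wide = per.unstack("choice").dropna()
        p = stats.wilcoxon(wide[-1] - wide[1]).pvalue
        assert p > 0.01

    def test_zscored_time_course_flat_for_fixed_bound_agents(
        self, analyzed_block2_cohort
    ):
        _, analyzed = analyzed_block2_cohort
        rel = analyzed[(analyzed["dt"] > 2) & (analyzed["forced"] == 0)]
        per_dt = (
            rel[rel["dt"] <= 12]
            .groupby(["participant_id", "dt"])["z_bound"]
            .median()
            .groupby("dt")
            .median()
        )
        assert abs(per_dt.mean()) < 0.25
        slope = np.polyfit(per_dt.index, per_dt.to_numpy(), 1)[0]
        assert abs(slope) < 0.04

    def test_corrected_bounds_recover_truth_per_agent(
        self, analyzed_block2_cohort
    ):
        trials, analyzed = analyzed_block2_cohort
        rel = analyzed[(analyzed["dt"] > 2) & (analyzed["forced"] == 0)]
        est = rel.groupby("participant_id")["corrected_bound"].mean()
        truth = trials.groupby("participant_id")["true_bound"].first()
        rho = stats.spearmanr(truth, est).statistic
        assert rho > 0.9

    def test_accuracy_dt_correlation_positive(self, analyzed_block2_cohort):
        _, analyzed = analyzed_block2_cohort
        summary = pt.participant_summary(analyzed)
        rho, _ = ba.accuracy_dt_correlation(summary)
        assert rho > 0.3
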