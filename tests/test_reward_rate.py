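import dataclasses

import numpy as np
import pytest

import pigeontask as pt
from pigeontask import _kernels
from pigeontask.reward_rate import (
    DEFAULT_BOUND_GRID,
    RewardRateFunction,
    rr_function_changepoint,
    rr_function_fixed,
    simulate_fixed_bound_blocks,
)
from pigeontask.task_model import BlockCondition


def make_rrf(grid, medians):
    g = np.asarray(grid, dtype=float)
    m = np.asarray(medians, dtype=float)
    return RewardRateFunction(
        bound_grid=g, rr_median=m, rr_lo=m, rr_hi=m, n_reps=1
    )


class TestReductions:
    def test_monotone_decreasing_picks_first(self):
        rrf = make_rrf([0.1, 0.2, 0.3], [0.3, 0.2, 0.1])
        assert pt.optimal_bound(rrf) == pytest.approx(0.1)

    def test_flat_ties_break_low(self):
        rrf = make_rrf([0.1, 0.2, 0.3], [0.2, 0.2, 0.2])
        assert pt.optimal_bound(rrf) == pytest.approx(0.1)

    def test_matches_brute_force_scan(self, rng):
        grid = DEFAULT_BOUND_GRID
        for _ in range(20):
            vals = np.round(rng.normal(size=16), 1)  # rounding forces ties
            rrf = make_rrf(grid, vals)
            # brute-force reducer: lowest bound among exact maxima
            brute = min(g for g, v in zip(grid, vals) if v == vals.max())
            assert pt.optimal_bound(rrf) == pytest.approx(brute)

    def test_gradient_arithmetic(self):
        rrf = make_rrf([0.2, 0.4], [0.01, 0.03])
        g = pt.rr_gradient(rrf, 0.2)
        assert g.gradient == pytest.approx(0.1)
        assert g.expected_direction == "increase"
        assert g.optimal_post_bound == pytest.approx(0.4)

    def test_gradient_zero_at_optimum(self):
        rrf = make_rrf([0.2, 0.4], [0.05, 0.03])
        g = pt.rr_gradient(rrf, 0.2)
        assert g.gradient == 0.0
        assert g.expected_direction == "none"

    def test_gradient_sign_matches_direction_of_optimum(self):
        rrf = make_rrf([0.1, 0.3, 0.5], [0.0, 0.02, 0.05])
        assert pt.rr_gradient(rrf, 0.1).gradient > 0
        rrf2 = make_rrf([0.1, 0.3, 0.5], [0.05, 0.02, 0.0])
        assert pt.rr_gradient(rrf2, 0.5).gradient < 0


class TestFixedBoundSimulation:
    def test_accuracy_and_dt_monotone_in_bound(self, rng, block2):
        accs, dts = [], []
        for b in (0.1, 0.25, 0.4, 0.55, 0.7):
            batch = _kernels.simulate_trial_batch(
                20_000, mu_schedule=np.float64(0.05), sigma=0.15,
                bounds=b, rng=rng,
            )
            accs.append(batch.correct.mean())
            dts.append(batch.commit_step.mean())
        assert np.all(np.diff(accs) > -0.005)
        assert np.all(np.diff(dts) > 0)

    def test_wald_closed_form_limit_small_steps(self, rng):
        # a >> sigma regime: accuracy and mean DT approach the two-boundary
        # diffusion formulas (discrete overshoot only raises both slightly)
        a, mu, sigma = 0.4, 0.0125, 0.05
        batch = _kernels.simulate_trial_batch(
            30_000, mu_schedule=np.float64(mu), sigma=sigma, bounds=a,
            rng=rng, max_steps=200, n_steps=200,
        )
        acc = batch.correct.mean()
        mean_dt = batch.commit_step.mean()
        wald_acc = 1.0 / (1.0 + np.exp(-2 * a * mu / sigma**2))
        wald_dt = (a / mu) * np.tanh(a * mu / sigma**2)
        assert acc >= wald_acc - 0.005
        assert acc - wald_acc < 0.05
        assert abs(mean_dt - wald_dt) / wald_dt < 0.20

    def test_median_and_ci_are_coherent(self, block2, rng):
        rrf = rr_function_fixed(
            block2, bound_grid=np.array([0.2, 0.4]), n_reps=200, rng=rng
        )
        assert np.all(rrf.rr_lo <= rrf.rr_median)
        assert np.all(rrf.rr_median <= rrf.rr_hi)

    def test_frame_export(self, block2, rng):
        rrf = rr_function_fixed(
            block2, bound_grid=np.array([0.2, 0.4]), n_reps=50, rng=rng
        )
        frame = rrf.to_frame()
        assert list(frame.columns) == ["bound", "rr_median", "rr_lo", "rr_hi"]
        assert len(frame) == 2


class TestChangepoint:
    def test_degenerate_changepoint_matches_fixed(self, rng):
        # mu2 == mu1: the changepoint does nothing
        cond_fixed = pt.get_condition(3, 1)
        cond_cp = BlockCondition(
            step_mean_magnitude=0.01, step_std=0.05, snr_mode="changepoint",
            mean_magnitudes=(0.01, 0.01), changepoint_direction="low_to_high",
            changepoint_step=8, coins_correct=1, coins_error=-1,
        )
        b = 0.16
        rrf_cp = rr_function_changepoint(
            cond_cp, pre_bound=b, post_bound_grid=np.array([b]),
            n_reps=400, rng=rng,
        )
        rrf_fx = rr_function_fixed(
            cond_fixed, bound_grid=np.array([b]), n_reps=400, rng=rng
        )
        lo = min(rrf_cp.rr_lo[0], rrf_fx.rr_lo[0])
        hi = max(rrf_cp.rr_hi[0], rrf_fx.rr_hi[0])
        assert lo <= rrf_cp.rr_median[0] <= hi
        assert abs(rrf_cp.rr_median[0] - rrf_fx.rr_median[0]) < 0.02

    def test_high_to_low_with_high_pre_bound_prescribes_decrease(self, rng):
        cond = pt.get_condition(3, 5)
        rrf = rr_function_changepoint(
            cond, pre_bound=0.26, changepoint_step=12, n_reps=300, rng=rng
        )
        g = pt.rr_gradient(rrf, 0.26)
        assert g.expected_direction == "decrease"
        assert g.optimal_post_bound < 0.26

    def test_gradient_result_consistency(self, rng):
        cond = pt.get_condition(3, 5)
        rrf = rr_function_changepoint(
            cond, pre_bound=0.2, changepoint_step=10, n_reps=200, rng=rng
        )
        g = pt.rr_gradient(rrf, 0.2)
        assert np.sign(g.gradient) == np.sign(g.optimal_post_bound - g.pre_bound)


class TestTwoSnr:
    def test_trial_mixed_diagonal_matches_direct_mixed_simulation(self):
        """Dual route: the pooled surface assembly against the per-trial
        agent simulator on a genuinely mixed block with one common bound."""
        rng = np.random.default_rng(20)
        low = BlockCondition(step_mean_magnitude=0.05, step_std=0.15,
                             coins_correct=1, coins_error=-4)
        high = BlockCondition(step_mean_magnitude=0.15, step_std=0.15,
                              coins_correct=1, coins_error=-4)
        b = 0.31
        surf = pt.rr_surface_two_snr(
            low, high, "trial_mixed",
            bound_grid=np.array([b]), bound_grid2=np.array([b]),
            n_reps=400, rng=rng, pool_size=30_000,
        )
        mixed_cond = pt.get_condition(2, 2)
        policy = pt.AgentPolicy(
            bound_schedule=pt.BoundSchedule("constant", level=b)
        )
        rates = []
        for _ in range(150):
            _, ledger = pt.simulate_block(policy, mixed_cond, rng)
            rates.append(pt.block_reward_rate(ledger))
        assert surf.rr_lo[0, 0] - 0.015 < np.median(rates) < surf.rr_hi[0, 0] + 0.015

    def test_payoff_mismatch_rejected(self):
        low = BlockCondition(step_mean_magnitude=0.05, step_std=0.15,
                             coins_correct=1, coins_error=-4)
        high = BlockCondition(step_mean_magnitude=0.15, step_std=0.15,
                              coins_correct=1, coins_error=0)
        with pytest.raises(Exception):
            pt.rr_surface_two_snr(low, high, "blockwise")

    def test_surface_frame_export(self, rng):
        low = BlockCondition(step_mean_magnitude=0.05, step_std=0.15)
        high = BlockCondition(step_mean_magnitude=0.15, step_std=0.15)
        surf = pt.rr_surface_two_snr(
            low, high, "blockwise",
            bound_grid=np.array([0.2, 0.4]), bound_grid2=np.array([0.2, 0.4]),
            n_reps=50, rng=rng,
        )
        frame = surf.to_frame()
        assert len(frame) == 4
        assert {"bound_low", "bound_high", "rr_median"} <= set(frame.columns)


class TestBonus:
    def test_threshold_definition_and_median_property(self, rng):
        cond = pt.get_condition(1, 1)
        thr = pt.bonus_threshold(cond, n_reps=200, rng=rng)
        # an ideal-observer block beats 80% of its own median >= half the time
        rrf = rr_function_fixed(cond, n_reps=200, rng=rng)
        b_star = pt.optimal_bound(rrf)
        coins, _, _ = simulate_fixed_bound_blocks(cond, b_star, 200, rng)
        assert np.mean(coins >= thr) >= 0.5
        assert thr == pytest.approx(0.8 * np.median(coins), rel=0.2)

    def test_threshold_converges_with_more_repetitions(self):
        cond = pt.get_condition(1, 1)
        t1 = pt.bonus_threshold(cond, n_reps=200, rng=np.random.default_rng(1))
        t2 = pt.bonus_threshold(cond, n_reps=400, rng=np.random.default_rng(2))
        assert abs(t1 - t2) / max(t1, t2) < 0.15
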