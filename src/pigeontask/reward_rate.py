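"""Monte-Carlo reward-rate functions of decision-bound height.

Reward rate is coins earned per step consumed over a whole block (fixed
600-step budget; +1 step at each trial start, +1 per pigeon step before the
keypress, plus any error step penalty).  Functions are estimated by
simulating full blocks for a deterministic bounded-accumulation agent at
each bound on a grid, and summarizing the per-block coins/steps ratio by
its median and percentile 95% CI across repetitions.  Variants cover fixed
bounds, two-SNR designs (block-wise or trial-mixed), and a single
within-trial changepoint with a piecewise bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import _kernels
from .task_model import (
    EDGE,
    DEFAULT_MAX_STEPS,
    SNR_CHANGEPOINT,
    SNR_FIXED,
    BlockCondition,
    ConfigurationError,
    step_mean_schedule,
)

#: The 16-point bound grid: 0.01 to 0.76 in steps of 0.05.
DEFAULT_BOUND_GRID = np.round(0.01 + 0.05 * np.arange(16), 2)
#: Block repetitions per bound value.
DEFAULT_N_REPS = 500
_CI = (2.5, 97.5)


@dataclass
class RewardRateFunction:
    """Median reward rate (coins/step) with 95% CI over a bound grid.

    For two-SNR surfaces ``bound_grid`` indexes the low-SNR bound (rows) and
    ``bound_grid2`` the high-SNR bound (columns); ``rr_median`` is then 2-D.
    For changepoint functions the grid indexes the post-changepoint bound
    and ``pre_bound``/``changepoint_step`` record the conditioning.
    """

    bound_grid: np.ndarray
    rr_median: np.ndarray
    rr_lo: np.ndarray
    rr_hi: np.ndarray
    n_reps: int
    kind: str = "fixed"
    bound_grid2: np.ndarray | None = None
    pre_bound: float | None = None
    changepoint_step: int | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.rr_median.ndim == 1:
            return pd.DataFrame(
                {
                    "bound": self.bound_grid,
                    "rr_median": self.rr_median,
                    "rr_lo": self.rr_lo,
                    "rr_hi": self.rr_hi,
                }
            )
        ii, jj = np.meshgrid(
            np.arange(len(self.bound_grid)),
            np.arange(len(self.bound_grid2)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "bound_low": self.bound_grid[ii.ravel()],
                "bound_high": self.bound_grid2[jj.ravel()],
                "rr_median": self.rr_median.ravel(),
                "rr_lo": self.rr_lo.ravel(),
                "rr_hi": self.rr_hi.ravel(),
            }
        )


@dataclass
class GradientResult:
    """Reward-rate gradient from a pre bound toward the RR maximum."""

    pre_bound: float
    optimal_post_bound: float
    gradient: float
    expected_direction: str  # increase | decrease | none


# ---------------------------------------------------------------------------
# trial pools


def _trial_pool_fn(
    cond: BlockCondition,
    bounds,
    mu_schedule,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Callable[[int], tuple[np.ndarray, np.ndarray]]:
    """Pool generator of (step_costs, coins) for i.i.d. trials.

    The simulated agent is deterministic (no motor delay, no lapses):
    it commits at the first crossing of ``bounds`` and its choice is scored
    against the latent drift sign.
    """

    def pool(n: int) -> tuple[np.ndarray, np.ndarray]:
        batch = _kernels.simulate_trial_batch(
            n,
            mu_schedule=mu_schedule,
            sigma=cond.step_std,
            bounds=bounds,
            rng=rng,
            max_steps=max_steps,
        )
        coins = np.where(batch.correct, cond.coins_correct, cond.coins_error)
        costs = 1 + batch.commit_step + np.where(
            batch.correct, 0, cond.steps_error_penalty
        )
        return costs.astype(float), coins.astype(float)

    return pool


def _est_trials_per_block(cond: BlockCondition, bound: float) -> float:
    # crude expected-cost guess used only to size simulation chunks
    dt_guess = max(1.0, bound / max(min(cond.magnitudes), 1e-3))
    dt_guess = min(dt_guess, DEFAULT_MAX_STEPS)
    return cond.block_step_budget / (1.0 + dt_guess)


def simulate_fixed_bound_blocks(
    cond: BlockCondition,
    bound: float,
    n_reps: int,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block (coins, steps, n_trials) for a fixed-bound agent."""
    if cond.snr_mode != SNR_FIXED:
        raise ConfigurationError("simulate_fixed_bound_blocks needs a fixed-SNR block")
    pool = _trial_pool_fn(
        cond, float(bound), np.float64(cond.step_mean_magnitude), rng, max_steps
    )
    return _kernels.block_rates_from_pool(
        pool, cond.block_step_budget, n_reps, _est_trials_per_block(cond, bound)
    )


def _summarize(rates: np.ndarray) -> tuple[float, float, float]:
    lo, hi = np.percentile(rates, _CI)
    return float(np.median(rates)), float(lo), float(hi)


# ---------------------------------------------------------------------------
# reward-rate functions


def rr_function_fixed(
    cond: BlockCondition,
    bound_grid: np.ndarray | None = None,
    n_reps: int = DEFAULT_N_REPS,
    rng: np.random.Generator | int | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> RewardRateFunction:
    """Reward-rate function of a fixed bound under a fixed-SNR block."""
    if bound_grid is None:
        bound_grid = DEFAULT_BOUND_GRID
    rng = np.random.default_rng(rng)
    med, lo, hi = [], [], []
    for b in bound_grid:
        coins, steps, _ = simulate_fixed_bound_blocks(cond, b, n_reps, rng, max_steps)
        m, l, h = _summarize(coins / steps)
        med.append(m)
        lo.append(l)
        hi.append(h)
    return RewardRateFunction(
        bound_grid=np.asarray(bound_grid, dtype=float),
        rr_median=np.asarray(med),
        rr_lo=np.asarray(lo),
        rr_hi=np.asarray(hi),
        n_reps=n_reps,
        kind="fixed",
    )


def rr_surface_two_snr(
    cond_low: BlockCondition,
    cond_high: BlockCondition,
    mode: str,
    bound_grid: np.ndarray | None = None,
    bound_grid2: np.ndarray | None = None,
    n_reps: int = DEFAULT_N_REPS,
    rng: np.random.Generator | int | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    pool_size: int = 40_000,
) -> RewardRateFunction:
    """Reward rate over (low-SNR bound, high-SNR bound) pairs.

    ``blockwise``: the total coins of one low-SNR and one high-SNR block
    divided by their total steps.  ``trial_mixed``: single blocks whose
    trials draw the SNR 50/50 and where the agent applies the bound matching
    the trial's (cued) SNR.  Both conditions must share the payoff
    structure.
    """
    if mode not in ("blockwise", "trial_mixed"):
        raise ValueError("mode must be 'blockwise' or 'trial_mixed'")
    if (
        cond_low.coins_correct != cond_high.coins_correct
        or cond_low.coins_error != cond_high.coins_error
        or cond_low.steps_error_penalty != cond_high.steps_error_penalty
    ):
        raise ConfigurationError("two-SNR conditions must share payoffs")
    if bound_grid is None:
        bound_grid = DEFAULT_BOUND_GRID
    if bound_grid2 is None:
        bound_grid2 = bound_grid
    rng = np.random.default_rng(rng)
    nL, nH = len(bound_grid), len(bound_grid2)
    med = np.empty((nL, nH))
    lo = np.empty((nL, nH))
    hi = np.empty((nL, nH))

    if mode == "blockwise":
        low = [
            simulate_fixed_bound_blocks(cond_low, b, n_reps, rng, max_steps)
            for b in bound_grid
        ]
        high = [
            simulate_fixed_bound_blocks(cond_high, b, n_reps, rng, max_steps)
            for b in bound_grid2
        ]
        for i, (cl, sl, _) in enumerate(low):
            for j, (ch, sh, _) in enumerate(high):
                rates = (cl + ch) / (sl + sh)
                med[i, j], lo[i, j], hi[i, j] = _summarize(rates)
    else:
        budget = cond_low.block_step_budget
        pools: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]] = {}
        for label, cond, grid in (
            ("low", cond_low, bound_grid),
            ("high", cond_high, bound_grid2),
        ):
            for b in grid:
                if (label, float(b)) in pools:
                    continue
                pool = _trial_pool_fn(
                    cond,
                    float(b),
                    np.float64(cond.step_mean_magnitude),
                    rng,
                    max_steps,
                )
                pools[(label, float(b))] = pool(pool_size)
        # worst-case trials per block: every trial costs >= 2 steps
        k_max = budget // 2 + 1
        for i, bl in enumerate(bound_grid):
            cost_l, coin_l = pools[("low", float(bl))]
            for j, bh in enumerate(bound_grid2):
                cost_h, coin_h = pools[("high", float(bh))]
                take_high = rng.random((n_reps, k_max)) < 0.5
                idx_l = rng.integers(0, len(cost_l), size=(n_reps, k_max))
                idx_h = rng.integers(0, len(cost_h), size=(n_reps, k_max))
                costs = np.where(take_high, cost_h[idx_h], cost_l[idx_l])
                coins = np.where(take_high, coin_h[idx_h], coin_l[idx_l])
                cum = np.cumsum(costs, axis=1)
                end = np.argmax(cum >= budget, axis=1)
                rows = np.arange(n_reps)
                steps = cum[rows, end]
                total = np.cumsum(coins, axis=1)[rows, end]
                med[i, j], lo[i, j], hi[i, j] = _summarize(total / steps)
    return RewardRateFunction(
        bound_grid=np.asarray(bound_grid, dtype=float),
        rr_median=med,
        rr_lo=lo,
        rr_hi=hi,
        n_reps=n_reps,
        kind=f"two_snr_{mode}",
        bound_grid2=np.asarray(bound_grid2, dtype=float),
    )


def rr_function_changepoint(
    cond: BlockCondition,
    pre_bound: float,
    changepoint_step: int | None = None,
    post_bound_grid: np.ndarray | None = None,
    n_reps: int = DEFAULT_N_REPS,
    rng: np.random.Generator | int | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> RewardRateFunction:
    """Reward rate of the post-changepoint bound, given the pre bound.

    The agent uses ``pre_bound`` for steps before the changepoint and the
    grid's post bound from the changepoint step on; the step drawn from the
    new SNR distribution is the first the new bound can terminate.
    """
    if not 0.0 <= pre_bound <= EDGE:
        raise ConfigurationError("pre_bound must be in [0, 0.8]")
    if cond.snr_mode != SNR_CHANGEPOINT:
        raise ConfigurationError("rr_function_changepoint needs a changepoint block")
    if changepoint_step is None:
        changepoint_step = cond.changepoint_step
    if changepoint_step is None or changepoint_step < 1:
        raise ConfigurationError("changepoint_step must be >= 1")
    if post_bound_grid is None:
        post_bound_grid = DEFAULT_BOUND_GRID
    rng = np.random.default_rng(rng)
    import dataclasses as _dc

    cond_cp = _dc.replace(cond, changepoint_step=int(changepoint_step))
    mu_row = step_mean_schedule(cond_cp, max_steps)
    k = np.arange(1, max_steps + 1)
    med, lo, hi = [], [], []
    for b_post in post_bound_grid:
        bounds_row = np.where(k < changepoint_step, pre_bound, float(b_post))
        pool = _trial_pool_fn(cond_cp, bounds_row, mu_row, rng, max_steps)
        coins, steps, _ = _kernels.block_rates_from_pool(
            pool,
            cond.block_step_budget,
            n_reps,
            _est_trials_per_block(cond_cp, max(pre_bound, float(b_post))),
        )
        m, l, h = _summarize(coins / steps)
        med.append(m)
        lo.append(l)
        hi.append(h)
    return RewardRateFunction(
        bound_grid=np.asarray(post_bound_grid, dtype=float),
        rr_median=np.asarray(med),
        rr_lo=np.asarray(lo),
        rr_hi=np.asarray(hi),
        n_reps=n_reps,
        kind="changepoint",
        pre_bound=float(pre_bound),
        changepoint_step=int(changepoint_step),
    )


# ---------------------------------------------------------------------------
# reductions


def optimal_bound(rrf: RewardRateFunction) -> float:
    """Grid argmax of the median RR; ties break toward the lowest bound."""
    if rrf.rr_median.ndim != 1:
        raise ValueError("optimal_bound applies to 1-D RR functions")
    if len(rrf.bound_grid) == 0:
        raise ValueError("empty bound grid")
    return float(rrf.bound_grid[int(np.argmax(rrf.rr_median))])


def optimal_bound_pair(rrf: RewardRateFunction) -> tuple[float, float]:
    """Argmax (low-SNR bound, high-SNR bound) of a two-SNR surface."""
    if rrf.rr_median.ndim != 2:
        raise ValueError("optimal_bound_pair applies to 2-D RR surfaces")
    i, j = np.unravel_index(int(np.argmax(rrf.rr_median)), rrf.rr_median.shape)
    return float(rrf.bound_grid[i]), float(rrf.bound_grid2[j])


def rr_gradient(rrf: RewardRateFunction, pre_bound: float) -> GradientResult:
    """Reward-rate change per unit bound change toward the RR maximum.

    Positive gradients prescribe raising the bound, negative lowering it.
    ``pre_bound`` is snapped to the nearest grid point.
    """
    if rrf.rr_median.ndim != 1:
        raise ValueError("rr_gradient applies to 1-D RR functions")
    grid = rrf.bound_grid
    i_pre = int(np.argmin(np.abs(grid - pre_bound)))
    b_star = optimal_bound(rrf)
    i_star = int(np.argmax(rrf.rr_median))
    if i_star == i_pre:
        return GradientResult(
            pre_bound=float(grid[i_pre]),
            optimal_post_bound=b_star,
            gradient=0.0,
            expected_direction="none",
        )
    grad = (rrf.rr_median[i_star] - rrf.rr_median[i_pre]) / (
        grid[i_star] - grid[i_pre]
    )
    return GradientResult(
        pre_bound=float(grid[i_pre]),
        optimal_post_bound=b_star,
        gradient=float(grad),
        expected_direction="increase" if grad > 0 else "decrease",
    )


def bonus_threshold(
    cond: BlockCondition,
    n_reps: int = DEFAULT_N_REPS,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Coins needed for the block bonus: 80% of the ideal observer's median.

    The ideal observer plays the RR-optimal fixed bound for the block.
    """
    rng = np.random.default_rng(rng)
    rrf = rr_function_fixed(cond, n_reps=n_reps, rng=rng)
    b_star = optimal_bound(rrf)
    coins, _steps, _ = simulate_fixed_bound_blocks(cond, b_star, n_reps, rng)
    return float(0.8 * np.median(coins))
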