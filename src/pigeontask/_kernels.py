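"""Vectorized simulation kernels shared by the reward-rate and correction
machinery.

Trials are simulated as (n_trials × n_steps) matrices of clipped cumulative
Gaussian increments; first bound crossings, choices and block assembly are
computed with array operations so that the Monte-Carlo routines stay within
seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_model import EDGE, DEFAULT_MAX_STEPS, clipped_cumsum


@dataclass
class TrialBatch:
    """Outcome arrays of a batch of independent simulated trials."""

    positions: np.ndarray  # (n, n_steps) positions after steps 1..n_steps
    drift_sign: np.ndarray  # (n,)
    commit_step: np.ndarray  # (n,) 1-based first-crossing step (or cap)
    forced: np.ndarray  # (n,) True where the cap forced the choice
    choice: np.ndarray  # (n,)
    correct: np.ndarray  # (n,)

    def __len__(self) -> int:
        return len(self.commit_step)


def sign_with_random_ties(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    s = np.sign(x)
    ties = s == 0
    if ties.any():
        s[ties] = rng.choice((-1.0, 1.0), size=int(ties.sum()))
    return s.astype(np.int8)


def simulate_trial_batch(
    n: int,
    mu_schedule: np.ndarray,
    sigma: float,
    bounds: np.ndarray | float,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
    n_steps: int | None = None,
    drift_sign: np.ndarray | None = None,
) -> TrialBatch:
    """Simulate ``n`` trials committing at the first bound crossing.

    Parameters
    ----------
    mu_schedule
        Unsigned per-step drift magnitudes; broadcastable to (n, n_steps)
        (scalar, (n_steps,) row for changepoints, or (n, 1) column for
        per-trial magnitudes).
    bounds
        Bound height per step; broadcastable to (n, max_steps) (scalar for a
        fixed bound, a row for collapsing/piecewise schedules, a column for
        per-trial jittered bounds).
    max_steps
        Commit search horizon; trials that never cross choose at the cap.
    n_steps
        Total steps generated per trial (≥ max_steps; extra steps let the
        walk continue during a non-decision delay).
    """
    if n_steps is None:
        n_steps = max_steps
    if n_steps < max_steps:
        raise ValueError("n_steps must be >= max_steps")
    if drift_sign is None:
        drift_sign = rng.choice((-1, 1), size=n).astype(np.int8)
    inc = np.broadcast_to(mu_schedule, (n, n_steps)) * drift_sign[:, None] \
        + sigma * rng.standard_normal((n, n_steps))
    pos = clipped_cumsum(inc)
    hit = np.abs(pos[:, :max_steps]) >= np.broadcast_to(bounds, (n, max_steps))
    crossed = hit.any(axis=1)
    commit = np.where(crossed, hit.argmax(axis=1) + 1, max_steps)
    at_commit = pos[np.arange(n), commit - 1]
    choice = sign_with_random_ties(at_commit.copy(), rng)
    return TrialBatch(
        positions=pos,
        drift_sign=drift_sign,
        commit_step=commit.astype(np.int64),
        forced=~crossed,
        choice=choice,
        correct=choice == drift_sign,
    )


def assemble_blocks(
    step_costs: np.ndarray, coins: np.ndarray, budget: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Partition a sequential trial pool into completed blocks.

    A block ends on the first trial at which its cumulative step count
    reaches the budget; that trial is played to completion, so blocks may
    overshoot.  Returns (coins, steps, n_trials) per completed block plus the
    number of pool trials consumed; trailing trials that do not complete a
    block are discarded.
    """
    cum_steps = np.cumsum(step_costs)
    cum_coins = np.cumsum(coins)
    block_coins, block_steps, block_trials = [], [], []
    offset_steps = 0.0
    offset_coins = 0.0
    start = 0
    while True:
        j = int(np.searchsorted(cum_steps, offset_steps + budget, side="left"))
        if j >= len(cum_steps):
            break
        block_coins.append(cum_coins[j] - offset_coins)
        block_steps.append(cum_steps[j] - offset_steps)
        block_trials.append(j - start + 1)
        offset_steps = cum_steps[j]
        offset_coins = cum_coins[j]
        start = j + 1
    return (
        np.asarray(block_coins, dtype=float),
        np.asarray(block_steps, dtype=float),
        np.asarray(block_trials, dtype=int),
        start,
    )


def block_rates_from_pool(
    pool_fn,
    budget: int,
    n_blocks: int,
    est_trials_per_block: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble ``n_blocks`` sequential blocks, drawing trials from pool_fn.

    ``pool_fn(n)`` must return (step_costs, coins) arrays for n fresh
    independent trials.  Returns per-block (coins, steps, n_trials).
    """
    chunk = max(1000, int(n_blocks * est_trials_per_block * 1.15) + 50)
    costs, coin = pool_fn(chunk)
    while True:
        bc, bs, bt, _used = assemble_blocks(costs, coin, budget)
        if len(bc) >= n_blocks:
            return bc[:n_blocks], bs[:n_blocks], bt[:n_blocks]
        more_costs, more_coin = pool_fn(chunk)
        costs = np.concatenate([costs, more_costs])
        coin = np.concatenate([coin, more_coin])
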