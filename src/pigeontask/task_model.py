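"""Task conditions and generation of the explicit decision variable.

Evidence in the pigeon task is presented as the horizontal position of a
pigeon taking one Gaussian random-walk step every 200 ms toward one of two
seed piles.  Positions are expressed in screen-normalized units: 0 is the
central starting point, ±1 the screen edges, and ±0.8 the seed piles, which
are the farthest points the pigeon can reach.  Each step increment is drawn
i.i.d. from N(s·μ, σ²) with s = ±1 the latent drift (correct) side, drawn
50/50 per trial.  Evidence quality is summarized by the per-step
signal-to-noise ratio SNR = μ/σ.

A block consumes a fixed budget of pigeon steps: +1 at the start of every
trial, +1 per step taken before the keypress, plus an optional error penalty
in steps.  With a fixed step budget, the reward rate of a block is the coins
earned per step consumed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

#: Seed-pile position; the pigeon cannot move past ±EDGE.
EDGE = 0.8
#: Steps available in a block before it ends.
DEFAULT_STEP_BUDGET = 600
#: Duration of one pigeon step, seconds.
STEP_DURATION_S = 0.2
#: Per-trial cap on pigeon steps; a decision is forced at the cap.
DEFAULT_MAX_STEPS = 60

SNR_FIXED = "fixed"
SNR_TRIAL_MIXED = "trial_mixed"
SNR_CHANGEPOINT = "changepoint"
_SNR_MODES = (SNR_FIXED, SNR_TRIAL_MIXED, SNR_CHANGEPOINT)

CP_NONE = "none"
CP_LOW_TO_HIGH = "low_to_high"
CP_HIGH_TO_LOW = "high_to_low"
_CP_DIRECTIONS = (CP_NONE, CP_LOW_TO_HIGH, CP_HIGH_TO_LOW)


class ConfigurationError(ValueError):
    """An invalid or inconsistent block/agent configuration."""


@dataclass(frozen=True)
class BlockCondition:
    """Generative and payoff parameters of one task block.

    Parameters
    ----------
    step_mean_magnitude
        μ, the unsigned mean of the per-step Gaussian increment (position
        units per step).  For ``trial_mixed`` and ``changepoint`` modes this
        is ignored in favour of ``mean_magnitudes``.
    step_std
        σ, the per-step standard deviation (fixed within a block).
    snr_mode
        ``fixed`` (one μ throughout), ``trial_mixed`` (μ drawn 50/50 per
        trial from two values), or ``changepoint`` (μ switches from the
        first to the second value at ``changepoint_step`` within each trial).
    mean_magnitudes
        The two μ magnitudes for ``trial_mixed``/``changepoint`` modes, in
        (first, second) order for changepoints.
    changepoint_step
        1-based step index at which the second μ takes effect; the step
        drawn at this index is the first from the new distribution.  May be
        ``None`` in a block template whose changepoint time is assigned per
        participant later.
    coins_correct, coins_error
        Coins gained on a correct choice / lost (≤ 0) on an error.
    steps_error_penalty
        Steps added to the block's step count after an error.
    """

    step_mean_magnitude: float
    step_std: float
    snr_mode: str = SNR_FIXED
    mean_magnitudes: tuple[float, float] | None = None
    changepoint_direction: str = CP_NONE
    changepoint_step: int | None = None
    coins_correct: int = 1
    coins_error: int = 0
    steps_error_penalty: int = 0
    block_step_budget: int = DEFAULT_STEP_BUDGET
    step_duration: float = STEP_DURATION_S

    def __post_init__(self) -> None:
        if self.step_std <= 0:
            raise ConfigurationError("step_std must be > 0")
        if self.snr_mode not in _SNR_MODES:
            raise ConfigurationError(f"unknown snr_mode {self.snr_mode!r}")
        if self.changepoint_direction not in _CP_DIRECTIONS:
            raise ConfigurationError(
                f"unknown changepoint_direction {self.changepoint_direction!r}"
            )
        if self.snr_mode == SNR_FIXED:
            if self.step_mean_magnitude < 0:
                raise ConfigurationError("step mean magnitude must be >= 0")
        else:
            if self.mean_magnitudes is None or len(self.mean_magnitudes) != 2:
                raise ConfigurationError(
                    f"{self.snr_mode} mode requires exactly two mean magnitudes"
                )
            if any(m < 0 for m in self.mean_magnitudes):
                raise ConfigurationError("mean magnitudes must be >= 0")
        if self.changepoint_step is not None and self.changepoint_step < 1:
            raise ConfigurationError("changepoint_step must be >= 1")
        if self.block_step_budget < 1:
            raise ConfigurationError("block_step_budget must be >= 1")
        if self.coins_error > 0:
            raise ConfigurationError("coins_error must be <= 0")
        if self.steps_error_penalty < 0:
            raise ConfigurationError("steps_error_penalty must be >= 0")

    # -- derived quantities -------------------------------------------------

    @property
    def snr(self) -> float:
        """|μ|/σ for fixed mode; undefined (raises) otherwise."""
        if self.snr_mode != SNR_FIXED:
            raise ConfigurationError("snr is only scalar for fixed-SNR blocks")
        return self.step_mean_magnitude / self.step_std

    @property
    def magnitudes(self) -> tuple[float, ...]:
        """All μ magnitudes this block can present."""
        if self.snr_mode == SNR_FIXED:
            return (self.step_mean_magnitude,)
        return tuple(self.mean_magnitudes)  # type: ignore[arg-type]

    def snr_label(self, mu_magnitude: float) -> str:
        """'low'/'high' label of one μ within this block ('' if unambiguous)."""
        mags = sorted(set(self.magnitudes))
        if len(mags) == 1:
            return ""
        return "low" if mu_magnitude == mags[0] else "high"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["mean_magnitudes"] is not None:
            d["mean_magnitudes"] = list(d["mean_magnitudes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BlockCondition":
        d = dict(d)
        if d.get("mean_magnitudes") is not None:
            d["mean_magnitudes"] = tuple(d["mean_magnitudes"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "BlockCondition":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "BlockCondition":
        return cls.from_dict(json.loads(text))


@dataclass
class PigeonWalk:
    """One trial's latent drift side and decision-variable trajectory.

    ``positions[k]`` is the pigeon position after k steps; ``positions[0]``
    is 0 and every position lies in [−0.8, 0.8].
    """

    drift_sign: int
    trial_mu_magnitude: float
    positions: np.ndarray
    changepoint_step: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1


@dataclass
class BlockLedger:
    """Running step/coin accounting of one block."""

    steps_used: int = 0
    coins_earned: int = 0
    trials_completed: int = 0

    def add_trial(self, steps_cost: int, coins_delta: int) -> None:
        self.steps_used += int(steps_cost)
        self.coins_earned += int(coins_delta)
        self.trials_completed += 1


# ---------------------------------------------------------------------------
# walk generation


def clipped_cumsum(increments: np.ndarray, edge: float = EDGE) -> np.ndarray:
    """Cumulative position with sequential clipping at ±edge.

    Clipping is applied after each step (the pigeon stops at a pile and may
    walk back), which differs from clipping a plain cumulative sum.
    Accepts a 1-D array of increments or a 2-D (trials × steps) array.
    """
    inc = np.atleast_2d(np.asarray(increments, dtype=float))
    pos = np.empty_like(inc)
    running = np.zeros(inc.shape[0])
    for k in range(inc.shape[1]):
        running = np.clip(running + inc[:, k], -edge, edge)
        pos[:, k] = running
    return pos[0] if np.ndim(increments) == 1 else pos


def step_mean_schedule(
    cond: BlockCondition, max_steps: int, trial_mu: float | None = None
) -> np.ndarray:
    """Unsigned per-step mean magnitudes μ_k for steps k = 1..max_steps."""
    if cond.snr_mode == SNR_FIXED:
        return np.full(max_steps, cond.step_mean_magnitude)
    if cond.snr_mode == SNR_TRIAL_MIXED:
        if trial_mu is None:
            raise ConfigurationError("trial_mixed schedule needs the trial's μ")
        return np.full(max_steps, trial_mu)
    if cond.changepoint_step is None:
        raise ConfigurationError(
            "changepoint mode requires changepoint_step to be set"
        )
    mu1, mu2 = cond.mean_magnitudes  # type: ignore[misc]
    k = np.arange(1, max_steps + 1)
    return np.where(k < cond.changepoint_step, mu1, mu2)


def sample_walk(
    cond: BlockCondition, max_steps: int, rng: np.random.Generator
) -> PigeonWalk:
    """Draw one pigeon walk of exactly ``max_steps`` increments."""
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    drift_sign = -1 if rng.random() < 0.5 else 1
    if cond.snr_mode == SNR_TRIAL_MIXED:
        mags = cond.mean_magnitudes  # type: ignore[misc]
        trial_mu = float(mags[0] if rng.random() < 0.5 else mags[1])
    else:
        trial_mu = None
    mus = step_mean_schedule(cond, max_steps, trial_mu)
    increments = drift_sign * mus + cond.step_std * rng.standard_normal(max_steps)
    positions = np.concatenate(([0.0], clipped_cumsum(increments)))
    if cond.snr_mode == SNR_FIXED:
        mu_mag = cond.step_mean_magnitude
    elif cond.snr_mode == SNR_TRIAL_MIXED:
        mu_mag = trial_mu  # type: ignore[assignment]
    else:
        mu_mag = cond.mean_magnitudes[0]  # type: ignore[index]
    return PigeonWalk(
        drift_sign=drift_sign,
        trial_mu_magnitude=float(mu_mag),
        positions=positions,
        changepoint_step=cond.changepoint_step
        if cond.snr_mode == SNR_CHANGEPOINT
        else None,
    )


# ---------------------------------------------------------------------------
# step/coin accounting


def trial_step_cost(rt: int, is_error: bool, cond: BlockCondition) -> int:
    """Steps charged for one trial: 1 (start) + RT + error penalty."""
    if rt < 1:
        raise ValueError("rt must be >= 1 step")
    return 1 + int(rt) + (cond.steps_error_penalty if is_error else 0)


def block_reward_rate(ledger: BlockLedger) -> float:
    """Coins earned per step consumed over a block."""
    if ledger.trials_completed < 1 or ledger.steps_used < 1:
        raise ValueError("reward rate undefined for an empty block")
    return ledger.coins_earned / ledger.steps_used


def cp_step_from_rts(rts: Sequence[float], statistic: str = "median") -> int:
    """Changepoint step derived from RTs of a fixed-SNR block.

    The statistic (median or mean) of the RTs, in steps, rounded up to an
    integer step index (a fractional 9.5 is applied at step 10).
    """
    rts = np.asarray(list(rts), dtype=float)
    if rts.size == 0:
        raise ConfigurationError("cannot derive a changepoint step from no trials")
    if statistic == "median":
        value = float(np.median(rts))
    elif statistic == "mean":
        value = float(np.mean(rts))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return max(1, math.ceil(value))


# ---------------------------------------------------------------------------
# packaged task-parameter table


def _condition_from_row(row: dict) -> BlockCondition:
    mode = row.get("snr_mode", SNR_FIXED)
    mean = row["step_mean"]
    if mode == SNR_FIXED:
        kwargs = {"step_mean_magnitude": float(mean), "mean_magnitudes": None}
    else:
        kwargs = {
            "step_mean_magnitude": float(mean[0]),
            "mean_magnitudes": (float(mean[0]), float(mean[1])),
        }
    return BlockCondition(
        snr_mode=mode,
        step_std=float(row["step_std"]),
        changepoint_direction=row.get("changepoint_direction", CP_NONE),
        coins_correct=int(row["coins_correct"]),
        coins_error=int(row["coins_error"]),
        steps_error_penalty=int(row["steps_error_penalty"]),
        **kwargs,
    )


def load_task_table() -> dict[tuple[int, int], BlockCondition]:
    """The packaged task-parameter table, keyed by (cohort, block)."""
    text = (
        resources.files("pigeontask").joinpath("data/task_conditions.yaml")
    ).read_text()
    rows = yaml.safe_load(text)
    return {
        (int(r["cohort"]), int(r["block"])): _condition_from_row(r) for r in rows
    }


def get_condition(cohort: int, block: int, **overrides) -> BlockCondition:
    """One packaged block condition, optionally with fields overridden."""
    cond = load_task_table()[(cohort, block)]
    return dataclasses.replace(cond, **overrides) if overrides else cond
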