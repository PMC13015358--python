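"""Synthetic cohorts of bounded-accumulation agents.

Agents watch the explicit decision variable and commit when it first reaches
a bound schedule; the keypress follows the commitment after a fixed motor
(non-decision) delay during which the pigeon keeps walking, so the position
at the keypress can be incongruent with the choice.  A fraction of trials
are fast guesses committed on the very first step.  Every emitted trial
carries its ground truth (bound, non-decision time, fast-guess flag) so that
the estimation chain can be scored by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .task_model import (
    EDGE,
    DEFAULT_MAX_STEPS,
    SNR_CHANGEPOINT,
    SNR_FIXED,
    SNR_TRIAL_MIXED,
    BlockCondition,
    BlockLedger,
    ConfigurationError,
    PigeonWalk,
    cp_step_from_rts,
    sample_walk,
    trial_step_cost,
)

SCHEDULE_CONSTANT = "constant"
SCHEDULE_LINEAR = "linear"
SCHEDULE_PIECEWISE = "piecewise"

#: Default heterogeneity of generated cohorts: constant per-agent bounds,
#: short motor delays and a modest fast-guess rate, spanning the qualitative
#: range of individual differences the analysis chain must cope with.
DEFAULT_BOUND_RANGE = (0.1, 0.6)
DEFAULT_NDT_CHOICES = (1, 2)
DEFAULT_FAST_GUESS_RANGE = (0.0, 0.3)
#: Bound range for low-σ (cohort-3-style) conditions: with σ = 0.05 and
#: per-step SNR 0.2–0.4, bounds in this range give decision times of roughly
#: 3–20 steps and median changepoint times near 8–15 steps, the scale the
#: changepoint design operates at; bounds much above 0.3 would stall trials
#: for most of a block's budget.
COHORT3_BOUND_RANGE = (0.1, 0.3)

TRIAL_TABLE_COLUMNS = [
    "participant_id",
    "cohort",
    "block_index",
    "trial_index",
    "drift_sign",
    "snr_label",
    "changepoint_step",
    "rt_steps",
    "choice",
    "correct",
    "coins_delta",
    "steps_cost",
    "positions",
    "true_bound",
    "true_ndt",
    "fast_guess",
    "forced",
]


@dataclass(frozen=True)
class BoundSchedule:
    """Bound height as a function of the (1-based) step index.

    ``constant``: ``level`` throughout.  ``linear``: ``level`` at step 1,
    collapsing by ``slope`` per step.  ``piecewise``: ``level`` before the
    trial's changepoint step, ``post_level`` from that step on.
    Values are clipped to [0, 0.8].
    """

    kind: str = SCHEDULE_CONSTANT
    level: float = 0.3
    slope: float = 0.0
    post_level: float | None = None

    def values(self, n_steps: int, changepoint_step: int | None = None) -> np.ndarray:
        k = np.arange(1, n_steps + 1)
        if self.kind == SCHEDULE_CONSTANT:
            v = np.full(n_steps, self.level, dtype=float)
        elif self.kind == SCHEDULE_LINEAR:
            v = self.level + self.slope * (k - 1)
        elif self.kind == SCHEDULE_PIECEWISE:
            if changepoint_step is None:
                raise ConfigurationError(
                    "piecewise schedule requires a changepoint step"
                )
            if self.post_level is None:
                raise ConfigurationError("piecewise schedule requires post_level")
            v = np.where(k < changepoint_step, self.level, self.post_level)
        else:
            raise ConfigurationError(f"unknown schedule kind {self.kind!r}")
        return np.clip(v, 0.0, EDGE)


@dataclass(frozen=True)
class AgentPolicy:
    """A simulated decision-maker.

    ``bound_schedule`` applies to fixed-SNR, changepoint, and the low-SNR
    trials of mixed blocks; ``bound_schedule_high``, when given, applies to
    the high-SNR trials of mixed blocks (agents are assumed to know the cued
    trial SNR).  ``ndt_steps`` is the motor delay between commitment and
    keypress; the choice is fixed at commitment and never revised.
    """

    bound_schedule: BoundSchedule
    ndt_steps: int = 0
    fast_guess_prob: float = 0.0
    trial_bound_jitter_sd: float = 0.0
    bound_schedule_high: BoundSchedule | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.ndt_steps <= 4:
            raise ConfigurationError("ndt_steps must be in 0..4")
        if not 0.0 <= self.fast_guess_prob <= 1.0:
            raise ConfigurationError("fast_guess_prob must be a probability")
        if self.trial_bound_jitter_sd < 0:
            raise ConfigurationError("trial_bound_jitter_sd must be >= 0")

    def schedule_for(self, snr_label: str) -> BoundSchedule:
        if snr_label == "high" and self.bound_schedule_high is not None:
            return self.bound_schedule_high
        return self.bound_schedule


@dataclass
class TrialRecord:
    """One simulated behavioral trial with its ground truth."""

    walk: PigeonWalk
    commit_step: int
    rt_steps: int
    choice: int
    correct: bool
    coins_delta: int
    steps_cost: int
    snr_label: str
    true_bound: float
    true_ndt: int
    fast_guess: bool
    forced: bool


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort: participants × block sequence.

    Per-agent parameters are drawn once per participant from the ranges
    below.  Changepoint blocks whose ``changepoint_step`` is unset get a
    participant-specific step derived from that participant's RTs in the
    earlier fixed-SNR block with the same starting μ (``cp_statistic`` of
    the RTs, rounded up).
    """

    n_participants: int
    blocks: Sequence[BlockCondition]
    cohort_id: int = 1
    bound_range: tuple[float, float] = DEFAULT_BOUND_RANGE
    ndt_choices: Sequence[int] = DEFAULT_NDT_CHOICES
    fast_guess_range: tuple[float, float] = DEFAULT_FAST_GUESS_RANGE
    trial_bound_jitter_sd: float = 0.0
    cp_statistic: str = "median"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")


# ---------------------------------------------------------------------------


def simulate_trial(
    policy: AgentPolicy,
    cond: BlockCondition,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> TrialRecord:
    """Simulate one trial of ``policy`` under ``cond``.

    The agent commits at the first step whose position magnitude reaches the
    (per-trial jittered) bound schedule, or guesses on step 1 with
    probability ``fast_guess_prob``; if the bound is never crossed within
    ``max_steps`` the choice is forced at the cap and flagged.  The keypress
    occurs ``ndt_steps`` after commitment while the walk continues.
    """
    if (
        policy.bound_schedule.kind == SCHEDULE_PIECEWISE
        and cond.snr_mode != SNR_CHANGEPOINT
    ):
        raise ConfigurationError(
            "piecewise bound schedules apply only to changepoint blocks"
        )
    ndt = policy.ndt_steps
    walk = sample_walk(cond, max_steps + ndt, rng)
    snr_label = cond.snr_label(walk.trial_mu_magnitude)
    schedule = policy.schedule_for(snr_label)
    base_bounds = schedule.values(max_steps, cond.changepoint_step)
    if policy.trial_bound_jitter_sd > 0:
        offset = rng.normal(0.0, policy.trial_bound_jitter_sd)
        bounds = np.clip(base_bounds + offset, 0.0, EDGE)
    else:
        bounds = base_bounds

    fast_guess = rng.random() < policy.fast_guess_prob
    pos = walk.positions
    forced = False
    if fast_guess:
        commit = 1
    else:
        hits = np.nonzero(np.abs(pos[1 : max_steps + 1]) >= bounds)[0]
        if hits.size:
            commit = int(hits[0]) + 1
        else:
            commit = max_steps
            forced = True
    at_commit = pos[commit]
    if at_commit == 0:
        choice = int(rng.choice((-1, 1)))
    else:
        choice = int(np.sign(at_commit))
    rt = commit + ndt
    correct = choice == walk.drift_sign
    coins = cond.coins_correct if correct else cond.coins_error
    cost = trial_step_cost(rt, not correct, cond)
    walk.positions = pos[: rt + 1]
    return TrialRecord(
        walk=walk,
        commit_step=commit,
        rt_steps=rt,
        choice=choice,
        correct=correct,
        coins_delta=coins,
        steps_cost=cost,
        snr_label=snr_label,
        true_bound=float(base_bounds[commit - 1]),
        true_ndt=ndt,
        fast_guess=fast_guess,
        forced=forced,
    )


def simulate_block(
    policy: AgentPolicy,
    cond: BlockCondition,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[list[TrialRecord], BlockLedger]:
    """Run trials until the block's step budget is consumed.

    The final trial is played to completion, so the ledger may overshoot the
    budget.
    """
    trials: list[TrialRecord] = []
    ledger = BlockLedger()
    while ledger.steps_used < cond.block_step_budget:
        rec = simulate_trial(policy, cond, rng, max_steps)
        trials.append(rec)
        ledger.add_trial(rec.steps_cost, rec.coins_delta)
    return trials, ledger


def draw_policies(spec: CohortSpec, rng: np.random.Generator) -> list[AgentPolicy]:
    """Draw one constant-bound policy per participant from the spec's ranges."""
    lo, hi = spec.bound_range
    policies = []
    for _ in range(spec.n_participants):
        policies.append(
            AgentPolicy(
                bound_schedule=BoundSchedule(
                    SCHEDULE_CONSTANT, level=float(rng.uniform(lo, hi))
                ),
                ndt_steps=int(rng.choice(list(spec.ndt_choices))),
                fast_guess_prob=float(rng.uniform(*spec.fast_guess_range)),
                trial_bound_jitter_sd=spec.trial_bound_jitter_sd,
            )
        )
    return policies


def _records_to_rows(
    records: Sequence[TrialRecord],
    participant_id: int,
    cohort: int,
    block_index: int,
    changepoint_step: int | None,
) -> list[dict]:
    rows = []
    for t_idx, rec in enumerate(records):
        rows.append(
            {
                "participant_id": participant_id,
                "cohort": cohort,
                "block_index": block_index,
                "trial_index": t_idx,
                "drift_sign": rec.walk.drift_sign,
                "snr_label": rec.snr_label,
                "changepoint_step": changepoint_step if changepoint_step else "",
                "rt_steps": rec.rt_steps,
                "choice": rec.choice,
                "correct": int(rec.correct),
                "coins_delta": rec.coins_delta,
                "steps_cost": rec.steps_cost,
                "positions": ";".join(
                    format(p, ".6f") for p in rec.walk.positions
                ),
                "true_bound": rec.true_bound,
                "true_ndt": rec.true_ndt,
                "fast_guess": int(rec.fast_guess),
                "forced": int(rec.forced),
            }
        )
    return rows


def generate_cohort(
    spec: CohortSpec,
    policies: Sequence[AgentPolicy] | None = None,
    policy_table: Sequence[Sequence[AgentPolicy]] | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> pd.DataFrame:
    """Simulate the whole cohort and return a tidy one-row-per-trial table.

    ``policies`` (one per participant, reused across blocks) or
    ``policy_table`` (``policy_table[p][b]`` per participant × block) may
    override the spec's default policy draws.  All randomness flows from
    ``spec.seed`` through one spawned stream per participant.
    """
    master = np.random.SeedSequence(spec.seed)
    policy_rng_seq, *participant_seqs = master.spawn(spec.n_participants + 1)
    if policies is None and policy_table is None:
        policies = draw_policies(spec, np.random.default_rng(policy_rng_seq))

    all_rows: list[dict] = []
    for p_idx, p_seq in enumerate(participant_seqs):
        rng = np.random.default_rng(p_seq)
        # RTs per fixed-SNR starting magnitude, for deriving changepoint times
        rts_by_start_mu: dict[float, list[int]] = {}
        for b_idx, cond in enumerate(spec.blocks):
            if policy_table is not None:
                policy = policy_table[p_idx][b_idx]
            else:
                policy = policies[p_idx]  # type: ignore[index]
            if (
                cond.snr_mode == SNR_CHANGEPOINT
                and cond.changepoint_step is None
            ):
                start_mu = cond.mean_magnitudes[0]  # type: ignore[index]
                if start_mu not in rts_by_start_mu:
                    raise ConfigurationError(
                        "changepoint block needs an earlier fixed-SNR block "
                        f"with μ={start_mu} to derive its changepoint step"
                    )
                cp = cp_step_from_rts(
                    rts_by_start_mu[start_mu], spec.cp_statistic
                )
                cond = dataclasses.replace(cond, changepoint_step=cp)
            records, _ledger = simulate_block(policy, cond, rng, max_steps)
            if cond.snr_mode == SNR_FIXED:
                rts_by_start_mu.setdefault(cond.step_mean_magnitude, []).extend(
                    r.rt_steps for r in records
                )
            all_rows.extend(
                _records_to_rows(
                    records, p_idx, spec.cohort_id, b_idx, cond.changepoint_step
                )
            )
    return pd.DataFrame(all_rows, columns=TRIAL_TABLE_COLUMNS)


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("rt_steps", "choice", "correct", "coins_delta", "steps_cost",
                "true_ndt", "fast_guess", "forced"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df


def parse_positions(cell: str) -> np.ndarray:
    """Decode the semicolon-joined positions column of a trial table."""
    if isinstance(cell, np.ndarray):
        return cell
    return np.array(cell.split(";"), dtype=float)
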