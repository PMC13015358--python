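"""Per-participant estimation chain: non-decision time by congruence
maximization, decision times, trialwise bound measurement, z-scoring, and
the two regression diagnostics (bound vs DT, bound change vs previous
bound).

The non-decision time (NDT) of a participant is the delay d ∈ {0..4} steps
before the keypress at which the pigeon position most often agrees in sign
with the choice; subtracting it from the response time (RT) gives the
decision time (DT).  The trial's bound is the unsigned position halfway
between one step before the DT and at the DT — the expected crossing point
assuming the bound was crossed during that final decision step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bound_correction import CorrectionTable
from .synthetic_cohort import parse_positions
from .task_model import EDGE

NDT_DELAY_RANGE = range(0, 5)
#: DT at or below which bound estimates are considered unreliable and
#: excluded from regressions and participant bound averages.
SHORT_DT_MAX = 2


@dataclass
class NdtEstimate:
    """Congruence-maximizing non-decision time for one participant/context."""

    ndt_steps: int
    congruence_by_delay: dict[int, float]
    n_trials: int


@dataclass
class BoundMeasurement:
    dt_steps: int
    raw_bound: float
    corrected_bound: float | None = None

    @property
    def short_dt_flag(self) -> bool:
        return self.dt_steps <= SHORT_DT_MAX


# ---------------------------------------------------------------------------
# core estimators


def estimate_ndt(
    trials: Iterable[tuple[np.ndarray, int, int]],
    delay_range: Iterable[int] = NDT_DELAY_RANGE,
) -> NdtEstimate:
    """Estimate NDT from (positions, rt, choice) triples.

    For each candidate delay d, the congruence is the fraction of trials on
    which the sign of the position d steps before the keypress equals the
    choice; trials whose probed position is exactly zero (sign undefined) or
    whose probed index falls before the trial start are excluded from that
    delay's denominator.  Returns the smallest delay attaining the maximum.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("estimate_ndt needs at least one trial")
    congruence: dict[int, float] = {}
    for d in delay_range:
        agree = 0
        total = 0
        for positions, rt, choice in trials:
            idx = rt - d
            if idx < 0:
                continue
            p = positions[idx]
            if p == 0:
                continue
            total += 1
            agree += int(np.sign(p) == choice)
        if total == 0:
            warnings.warn(
                f"no scorable trials at delay {d}; congruence set to 0",
                stacklevel=2,
            )
            congruence[d] = 0.0
        else:
            congruence[d] = agree / total
    best = max(congruence, key=lambda d: (congruence[d], -d))
    return NdtEstimate(
        ndt_steps=int(best), congruence_by_delay=congruence, n_trials=len(trials)
    )


def decision_time(rt_steps: int, ndt_steps: int) -> int:
    """DT = RT − NDT, floored at one step."""
    if rt_steps < 1:
        raise ValueError("rt must be >= 1")
    return max(int(rt_steps) - int(ndt_steps), 1)


def measure_raw_bound(positions: np.ndarray, dt_steps: int) -> BoundMeasurement:
    """Unsigned bound estimate |(pos[dt−1] + pos[dt]) / 2| for one trial."""
    if dt_steps < 1:
        raise ValueError("dt must be >= 1")
    if dt_steps > len(positions) - 1:
        raise ValueError("dt exceeds the walk length")
    raw = abs((positions[dt_steps - 1] + positions[dt_steps]) / 2.0)
    return BoundMeasurement(dt_steps=int(dt_steps), raw_bound=float(raw))


# ---------------------------------------------------------------------------
# regression diagnostics


def bound_vs_dt_slope(
    dts: Sequence[int],
    bounds: Sequence[float],
    exclude_dt_leq: int = SHORT_DT_MAX,
    per_dt_medians: bool = True,
) -> float | None:
    """OLS slope of bound against DT (bound units per step).

    By default the regression uses one point per DT value — the median bound
    at that DT — excluding short DTs whose estimates are unreliable.
    Returns ``None`` (with a warning) when fewer than two distinct DT values
    survive the exclusion.
    """
    dts = np.asarray(dts)
    bounds = np.asarray(bounds, dtype=float)
    keep = dts > exclude_dt_leq
    dts, bounds = dts[keep], bounds[keep]
    if per_dt_medians:
        if len(dts) == 0:
            warnings.warn("no trials beyond the DT exclusion", stacklevel=2)
            return None
        s = pd.Series(bounds).groupby(dts).median()
        x, y = s.index.to_numpy(dtype=float), s.to_numpy()
    else:
        x, y = dts.astype(float), bounds
    if len(np.unique(x)) < 2:
        warnings.warn("fewer than two distinct DT values", stacklevel=2)
        return None
    return float(np.polyfit(x, y, 1)[0])


def bound_change_regression(bounds: Sequence[float]) -> float | None:
    """OLS slope of (bound[t] − bound[t+1]) on bound[t] over consecutive trials.

    Under i.i.d. variation around a constant mean the slope is 1 (regression
    to the mean); for a true random walk across trials it is 0.  Returns
    ``None`` for fewer than 3 trials or a degenerate regressor.
    """
    b = np.asarray(bounds, dtype=float)
    if len(b) < 3:
        return None
    x = b[:-1]
    y = b[:-1] - b[1:]
    if np.var(x) == 0:
        return None
    return float(np.polyfit(x, y, 1)[0])


def zscore_bounds(bounds: Sequence[float]) -> np.ndarray:
    """Z-score bounds within a participant (sample SD, n−1 denominator)."""
    b = np.asarray(bounds, dtype=float)
    if len(b) < 2:
        raise ValueError("z-scoring needs at least two trials")
    sd = b.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; z-scores set to 0", stacklevel=2)
        return np.zeros_like(b)
    return (b - b.mean()) / sd


# ---------------------------------------------------------------------------
# table-level orchestration


def _snr_context(row: pd.Series, conditions=None) -> str:
    """SNR context label for per-participant-per-SNR NDT estimation.

    With block conditions available, contexts pool trials sharing the same
    per-step evidence SNR within and across blocks; changepoint blocks form
    their own context per direction.  Without conditions, the trial's SNR
    label (mixed blocks) or its block index is used.
    """
    if conditions is not None:
        cond = conditions[row["block_index"]]
        if cond.snr_mode == "changepoint":
            return f"cp_{cond.changepoint_direction}"
        if cond.snr_mode == "trial_mixed":
            mags = sorted(cond.mean_magnitudes)
            mu = mags[0] if row["snr_label"] == "low" else mags[1]
        else:
            mu = cond.step_mean_magnitude
        return f"snr_{round(mu / cond.step_std, 3)}"
    if row["snr_label"]:
        return f"snr_{row['snr_label']}"
    return f"block_{row['block_index']}"


def estimate_ndt_table(
    df: pd.DataFrame, granularity: str = "per_snr", conditions=None
) -> pd.DataFrame:
    """NDT per participant (and SNR context) from a trial table.

    ``granularity='per_snr'`` follows the convention of estimating one NDT
    per participant and SNR context; ``'per_participant'`` pools all trials.
    """
    if granularity not in ("per_snr", "per_participant"):
        raise ValueError("granularity must be 'per_snr' or 'per_participant'")
    work = df.copy()
    work["_positions"] = work["positions"].map(parse_positions)
    if granularity == "per_snr":
        work["_ctx"] = work.apply(_snr_context, axis=1, conditions=conditions)
    else:
        work["_ctx"] = "all"
    rows = []
    for (pid, ctx), grp in work.groupby(["participant_id", "_ctx"]):
        est = estimate_ndt(
            zip(grp["_positions"], grp["rt_steps"], grp["choice"])
        )
        rows.append(
            {
                "participant_id": pid,
                "snr_context": ctx,
                "ndt_steps": est.ndt_steps,
                "n_trials": est.n_trials,
                **{f"congruence_{d}": c for d, c in est.congruence_by_delay.items()},
            }
        )
    return pd.DataFrame(rows)


def trial_snr_at_dt(cond, snr_label: str, dt: int, changepoint_step) -> float:
    """Per-step SNR in effect at a trial's decision time."""
    sigma = cond.step_std
    if cond.snr_mode == "fixed":
        return cond.step_mean_magnitude / sigma
    mags = sorted(cond.mean_magnitudes)
    if cond.snr_mode == "trial_mixed":
        mu = mags[0] if snr_label == "low" else mags[1]
        return mu / sigma
    # changepoint: μ switches at the changepoint step
    mu1, mu2 = cond.mean_magnitudes
    cp = int(changepoint_step)
    return (mu1 if dt < cp else mu2) / sigma


def analyze_trials(
    df: pd.DataFrame,
    correction_tables: "Mapping[float, CorrectionTable] | CorrectionTable | None" = None,
    conditions: "Mapping[int, object] | None" = None,
    ndt_granularity: str = "per_snr",
) -> pd.DataFrame:
    """Augment a trial table with ndt, dt, raw/corrected bounds and z-bounds.

    ``correction_tables`` may be a single table or a mapping from per-step
    SNR (rounded to 3 decimals) to tables; in the mapping case
    ``conditions`` (block_index → BlockCondition) is required so each trial
    is corrected with the table matching the SNR in effect at its decision
    time.  Z-scoring of bounds is within participant × block over all its
    trials.
    """
    ndt_df = estimate_ndt_table(df, ndt_granularity, conditions)
    key = (
        ["participant_id", "snr_context"]
        if ndt_granularity == "per_snr"
        else ["participant_id"]
    )
    work = df.copy()
    work["_positions"] = work["positions"].map(parse_positions)
    if ndt_granularity == "per_snr":
        work["snr_context"] = work.apply(_snr_context, axis=1, conditions=conditions)
    else:
        ndt_df = ndt_df.drop(columns=["snr_context"])
    work = work.merge(ndt_df[key + ["ndt_steps"]], on=key, how="left")
    work["ndt"] = work["ndt_steps"].astype(int)
    work["dt"] = np.maximum(work["rt_steps"] - work["ndt"], 1)
    work["dt_floored"] = (work["rt_steps"] - work["ndt"]) < 1
    work["raw_bound"] = [
        measure_raw_bound(p, dt).raw_bound
        for p, dt in zip(work["_positions"], work["dt"])
    ]
    work["short_dt"] = work["dt"] <= SHORT_DT_MAX

    if correction_tables is None:
        work["corrected_bound"] = np.nan
    elif isinstance(correction_tables, CorrectionTable):
        work["corrected_bound"] = [
            correction_tables.correct(raw, dt)
            for raw, dt in zip(work["raw_bound"], work["dt"])
        ]
    else:
        if conditions is None:
            raise ValueError(
                "a mapping of correction tables requires block conditions"
            )
        corrected = np.empty(len(work))
        for i, (_, row) in enumerate(work.iterrows()):
            cond = conditions[row["block_index"]]
            snr = trial_snr_at_dt(
                cond, row["snr_label"], int(row["dt"]), row["changepoint_step"]
            )
            table = correction_tables[round(snr, 3)]
            corrected[i] = table.correct(row["raw_bound"], int(row["dt"]))
        work["corrected_bound"] = corrected

    bound_col = "corrected_bound" if correction_tables is not None else "raw_bound"
    zs = np.full(len(work), np.nan)
    for _, idx in work.groupby(["participant_id", "block_index"]).groups.items():
        vals = work.loc[idx, bound_col].to_numpy(dtype=float)
        if len(vals) >= 2 and np.nanstd(vals) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                zs[work.index.get_indexer(idx)] = zscore_bounds(vals)
    work["z_bound"] = zs
    return work.drop(columns=["_positions"])


def participant_summary(
    analyzed: pd.DataFrame, bound_col: str | None = None
) -> pd.DataFrame:
    """Per-participant accuracy, median DT, bound averages and reward rate.

    Bound averages use trials with DT beyond the short-DT exclusion and
    non-forced choices.
    """
    if bound_col is None:
        bound_col = (
            "corrected_bound"
            if "corrected_bound" in analyzed
            and analyzed["corrected_bound"].notna().any()
            else "raw_bound"
        )
    rows = []
    for pid, grp in analyzed.groupby("participant_id"):
        reliable = grp[(grp["dt"] > SHORT_DT_MAX)]
        if "forced" in grp:
            reliable = reliable[reliable["forced"] == 0]
        rows.append(
            {
                "participant_id": pid,
                "n_trials": len(grp),
                "accuracy": grp["correct"].mean(),
                "median_dt": float(grp["dt"].median()),
                "mean_bound": float(reliable[bound_col].mean())
                if len(reliable)
                else np.nan,
                "median_bound": float(reliable[bound_col].median())
                if len(reliable)
                else np.nan,
                "reward_rate": grp["coins_delta"].sum() / grp["steps_cost"].sum(),
            }
        )
    return pd.DataFrame(rows)


def accuracy_dt_correlation(summary: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation between accuracy and median DT."""
    res = stats.spearmanr(summary["accuracy"], summary["median_dt"])
    return float(res.statistic), float(res.pvalue)
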