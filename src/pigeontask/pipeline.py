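"""End-to-end orchestration: simulate or ingest a cohort, estimate
non-decision times and bounds, apply bias corrections, and emit
participant-level summaries, paired block contrasts, regression
diagnostics, and changepoint bound-change analyses with their
reward-rate gradients.

Every reported statistic is recomputable from the emitted per-trial table;
all randomness flows from a single master seed via spawned substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior_analysis as ba
from . import bound_correction as bc
from . import reward_rate as rr
from . import synthetic_cohort as sc
from .task_model import (
    SNR_CHANGEPOINT,
    SNR_FIXED,
    BlockCondition,
    ConfigurationError,
    cp_step_from_rts,
    get_condition,
)

logger = logging.getLogger("pigeontask")

__version__ = "0.1.0"


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    Either ``trials_csv`` (an existing trial table) or ``cohort`` (keyword
    arguments for :class:`~pigeontask.synthetic_cohort.CohortSpec`, with
    blocks given as (cohort, block) references into the packaged task
    table) must be provided, along with the block reference list used to
    resolve conditions.
    """

    blocks: Sequence[tuple[int, int]]
    trials_csv: str | None = None
    n_participants: int = 60
    cohort_id: int = 1
    seed: int = 0
    correction_n_sims: int = bc.DEFAULT_N_SIMS
    rr_n_reps: int = rr.DEFAULT_N_REPS
    reports: Sequence[str] = ("summary", "block_contrasts", "slopes")
    ndt_granularity: str = "per_snr"
    min_group_size: int = 5
    bonferroni: bool = False
    outdir: str | None = None

    def conditions(self) -> dict[int, BlockCondition]:
        return {
            i: get_condition(c, b) for i, (c, b) in enumerate(self.blocks)
        }

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        d["blocks"] = [tuple(b) for b in d["blocks"]]
        return cls(**d)


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance."""

    analyzed: pd.DataFrame
    summary: pd.DataFrame
    block_bounds: pd.DataFrame
    contrasts: pd.DataFrame | None
    slopes: pd.DataFrame | None
    changepoint: pd.DataFrame | None
    statistics: dict
    provenance: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.analyzed.to_csv(out / "trials_analyzed.csv", index=False,
                             lineterminator="\n")
        self.summary.to_csv(out / "participant_summary.csv", index=False,
                            lineterminator="\n")
        self.block_bounds.to_csv(out / "block_bounds.csv", index=False,
                                 lineterminator="\n")
        if self.contrasts is not None:
            self.contrasts.to_csv(out / "block_contrasts.csv", index=False,
                                  lineterminator="\n")
        if self.slopes is not None:
            self.slopes.to_csv(out / "slopes.csv", index=False,
                               lineterminator="\n")
        if self.changepoint is not None:
            self.changepoint.to_csv(out / "changepoint.csv", index=False,
                                    lineterminator="\n")
        (out / "statistics.json").write_text(
            json.dumps(
                {"statistics": self.statistics, "provenance": self.provenance},
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# helpers


def derive_cp_step(rts: Sequence[float], statistic: str = "median") -> int:
    """Changepoint step from a participant's fixed-SNR-block RTs (ceiling)."""
    return cp_step_from_rts(rts, statistic)


def required_snrs(conditions: Mapping[int, BlockCondition]) -> dict[float, tuple]:
    """All per-step SNRs the analysis can encounter, with their (μ, σ)."""
    out: dict[float, tuple] = {}
    for cond in conditions.values():
        for mu in cond.magnitudes:
            out[round(mu / cond.step_std, 3)] = (mu, cond.step_std)
    return out


def build_correction_tables(
    conditions: Mapping[int, BlockCondition],
    n_sims: int,
    rng: np.random.Generator,
) -> dict[float, bc.CorrectionTable]:
    tables = {}
    for snr, (mu, sigma) in sorted(required_snrs(conditions).items()):
        logger.info("building correction table for SNR %.3f", snr)
        tables[snr] = bc.build_correction_table(
            mu, sigma, n_sims_per_bound=n_sims, rng=rng
        )
    return tables


def _reliable(analyzed: pd.DataFrame) -> pd.DataFrame:
    keep = (analyzed["dt"] > ba.SHORT_DT_MAX) & (~analyzed["dt_floored"])
    if "forced" in analyzed:
        keep &= analyzed["forced"] == 0
    return analyzed[keep]


def block_bound_table(
    analyzed: pd.DataFrame, bound_col: str = "corrected_bound"
) -> pd.DataFrame:
    """Mean reliable bound per participant × block."""
    rel = _reliable(analyzed)
    g = (
        rel.groupby(["participant_id", "block_index"])[bound_col]
        .agg(["mean", "median", "count"])
        .reset_index()
    )
    return g.rename(
        columns={"mean": "mean_bound", "median": "median_bound", "count": "n"}
    )


def changepoint_bound_change(
    analyzed: pd.DataFrame,
    cp_steps: Mapping[int, int],
    block_index: int,
    bound_col: str = "corrected_bound",
) -> pd.DataFrame:
    """Per-participant mean bound before vs after the changepoint.

    Pre trials end before the participant's changepoint step (DT < cp), post
    trials at or after it; short-DT, floored and forced trials are excluded.
    Participants lacking pre or post trials are dropped with a log entry.
    """
    rel = _reliable(analyzed[analyzed["block_index"] == block_index])
    rows = []
    for pid, grp in rel.groupby("participant_id"):
        cp = int(cp_steps[pid])
        pre = grp[grp["dt"] < cp][bound_col]
        post = grp[grp["dt"] >= cp][bound_col]
        if len(pre) == 0 or len(post) == 0:
            logger.info(
                "participant %s excluded from changepoint analysis "
                "(pre=%d, post=%d trials)", pid, len(pre), len(post)
            )
            continue
        rows.append(
            {
                "participant_id": pid,
                "cp_step": cp,
                "pre_mean_bound": float(pre.mean()),
                "post_mean_bound": float(post.mean()),
                "bound_change": float(post.mean() - pre.mean()),
                "n_pre": len(pre),
                "n_post": len(post),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Run the full estimation and reporting chain for one configuration."""
    conditions = config.conditions()
    master = np.random.SeedSequence(config.seed)
    corr_seq, cohort_seed_seq = master.spawn(2)

    if config.trials_csv is not None:
        logger.info("reading trial table %s", config.trials_csv)
        trials = sc.read_trial_table(config.trials_csv)
        _validate_trial_table(trials)
    else:
        spec = sc.CohortSpec(
            n_participants=config.n_participants,
            blocks=list(conditions.values()),
            cohort_id=config.cohort_id,
            seed=int(cohort_seed_seq.generate_state(1)[0] % (2**31)),
        )
        logger.info(
            "simulating cohort: %d participants × %d blocks",
            spec.n_participants,
            len(spec.blocks),
        )
        trials = sc.generate_cohort(spec)

    tables = build_correction_tables(
        conditions, config.correction_n_sims, np.random.default_rng(corr_seq)
    )
    logger.info("estimating NDT/DT/bounds for %d trials", len(trials))
    analyzed = ba.analyze_trials(
        trials, tables, conditions, config.ndt_granularity
    )
    summary = ba.participant_summary(analyzed)
    block_bounds = block_bound_table(analyzed)

    statistics: dict = {}
    rho, p = ba.accuracy_dt_correlation(summary)
    statistics["accuracy_vs_median_dt"] = {
        "spearman_rho": rho, "p_value": p, "n": len(summary)
    }

    contrasts = None
    if "block_contrasts" in config.reports and len(conditions) > 1:
        contrasts = _block_contrasts(block_bounds, config)
        statistics["block_contrasts"] = contrasts.to_dict("records")

    slopes = None
    if "slopes" in config.reports:
        slopes = _slope_table(analyzed)
        med_dt = slopes["bound_vs_dt_slope"].dropna()
        med_ch = slopes["bound_change_slope"].dropna()
        statistics["slopes"] = {
            "median_bound_vs_dt_slope": float(med_dt.median()) if len(med_dt) else None,
            "median_bound_change_slope": float(med_ch.median()) if len(med_ch) else None,
            "wilcoxon_vs_dt_p": _wilcoxon_p(med_dt),
            "n": int(len(slopes)),
        }

    changepoint = None
    if "changepoint" in config.reports:
        changepoint = _changepoint_report(analyzed, conditions, config, master)
        if changepoint is not None and len(changepoint) >= config.min_group_size:
            res = stats.spearmanr(
                changepoint["rr_gradient"], changepoint["bound_change"]
            )
            statistics["changepoint_gradient_correlation"] = {
                "spearman_rho": float(res.statistic),
                "p_value": float(res.pvalue),
                "n": len(changepoint),
            }

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "n_trials": int(len(trials)),
        "n_participants": int(trials["participant_id"].nunique()),
    }
    return ReportBundle(
        analyzed=analyzed,
        summary=summary,
        block_bounds=block_bounds,
        contrasts=contrasts,
        slopes=slopes,
        changepoint=changepoint,
        statistics=statistics,
        provenance=provenance,
    )


def _wilcoxon_p(values: pd.Series) -> float | None:
    vals = values.dropna().to_numpy()
    vals = vals[vals != 0]
    if len(vals) < 5:
        return None
    return float(stats.wilcoxon(vals).pvalue)


def _block_contrasts(
    block_bounds: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    wide = block_bounds.pivot(
        index="participant_id", columns="block_index", values="mean_bound"
    )
    rows = []
    blocks = sorted(wide.columns)
    pairs = list(zip(blocks[:-1], blocks[1:]))
    for a, b in pairs:
        paired = wide[[a, b]].dropna()
        row = {
            "block_a": a,
            "block_b": b,
            "n": len(paired),
            "median_difference": float((paired[b] - paired[a]).median())
            if len(paired)
            else None,
            "flagged_small_n": len(paired) < config.min_group_size,
        }
        diffs = (paired[b] - paired[a]).to_numpy()
        diffs = diffs[diffs != 0]
        if len(paired) >= config.min_group_size and len(diffs) >= 5:
            p = float(stats.wilcoxon(diffs).pvalue)
            row["wilcoxon_p"] = (
                min(1.0, p * len(pairs)) if config.bonferroni else p
            )
        else:
            row["wilcoxon_p"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def _slope_table(analyzed: pd.DataFrame) -> pd.DataFrame:
    rel = _reliable(analyzed)
    bound_col = (
        "corrected_bound" if rel["corrected_bound"].notna().any() else "raw_bound"
    )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for (pid, blk), grp in rel.groupby(["participant_id", "block_index"]):
            grp = grp.sort_values("trial_index")
            rows.append(
                {
                    "participant_id": pid,
                    "block_index": blk,
                    "bound_vs_dt_slope": ba.bound_vs_dt_slope(
                        grp["dt"], grp[bound_col]
                    ),
                    "bound_change_slope": ba.bound_change_regression(
                        grp[bound_col].to_numpy()
                    ),
                    "n": len(grp),
                }
            )
    return pd.DataFrame(rows)


def _changepoint_report(
    analyzed: pd.DataFrame,
    conditions: Mapping[int, BlockCondition],
    config: AnalysisConfig,
    master: np.random.SeedSequence,
) -> pd.DataFrame | None:
    cp_blocks = [
        i for i, c in conditions.items() if c.snr_mode == SNR_CHANGEPOINT
    ]
    if not cp_blocks:
        return None
    frames = []
    rng = np.random.default_rng(master.spawn(1)[0])
    for blk in cp_blocks:
        cond = conditions[blk]
        sub = analyzed[analyzed["block_index"] == blk]
        cp_steps = {
            pid: int(grp["changepoint_step"].iloc[0])
            for pid, grp in sub.groupby("participant_id")
        }
        changes = changepoint_bound_change(analyzed, cp_steps, blk)
        grads = []
        for _, row in changes.iterrows():
            rrf = rr.rr_function_changepoint(
                cond,
                pre_bound=row["pre_mean_bound"],
                changepoint_step=int(row["cp_step"]),
                n_reps=config.rr_n_reps,
                rng=rng,
            )
            grads.append(rr.rr_gradient(rrf, row["pre_mean_bound"]).gradient)
        changes["rr_gradient"] = grads
        changes["block_index"] = blk
        frames.append(changes)
    return pd.concat(frames, ignore_index=True) if frames else None


def _validate_trial_table(df: pd.DataFrame) -> None:
    missing = [c for c in sc.TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"trial table is missing required columns: {missing}"
        )
    if (df["rt_steps"] < 1).any():
        bad = df.index[df["rt_steps"] < 1][0]
        raise ConfigurationError(f"rt_steps < 1 at row {bad}")


# ---------------------------------------------------------------------------
# normative changepoint experiment (gradient-following agents)


def gradient_following_experiment(
    direction: str = "low_to_high",
    n_agents: int = 60,
    seed: int = 0,
    rr_n_reps: int = 300,
    correction_n_sims: int = 50_000,
    follow_gain_range: tuple[float, float] | None = None,
    n_cp_blocks: int = 8,
    pre_bound_range: tuple[float, float] | None = None,
    correction_tables: dict | None = None,
) -> tuple[pd.DataFrame, float]:
    """Cohort-3-style experiment with agents that follow the RR gradient.

    Each agent first plays the fixed-SNR block matching the changepoint's
    starting SNR (fixing its changepoint time at the ceiling of its median
    RT), then plays changepoint blocks with a piecewise bound whose post
    level shifts from the pre level by its personal reward-rate gradient
    times a per-agent gain (bound units² per coin/step).  The analysis chain
    then measures each agent's realized pre→post bound change and the
    reward-rate gradient at its measured pre bound.  Returns the per-agent
    table and the Spearman correlation between realized change and gradient.

    Pre-changepoint bounds are drawn to span the regimes the design
    distinguishes: for low→high changes this includes bounds below the
    post-changepoint optimum (where the normative prescription is to raise
    the bound) as well as above it; for high→low changes it covers the
    range over which the prescribed decrease varies strongly while leaving
    enough pre-changepoint decision times to measure an initial bound.
    """
    if direction not in ("low_to_high", "high_to_low"):
        raise ValueError("direction must be 'low_to_high' or 'high_to_low'")
    if pre_bound_range is None:
        pre_bound_range = (
            (0.04, 0.25) if direction == "low_to_high" else (0.08, 0.28)
        )
    if follow_gain_range is None:
        # high→low gradients are several-fold larger in magnitude; the gain
        # is scaled down there so post bounds stay off the physical floor
        follow_gain_range = (
            (0.48, 0.72) if direction == "low_to_high" else (0.2, 0.3)
        )
    fixed_block = 1 if direction == "low_to_high" else 2
    cp_block = 4 if direction == "low_to_high" else 5
    cond_fixed = get_condition(3, fixed_block)
    cond_cp = get_condition(3, cp_block)

    master = np.random.SeedSequence([seed, 3 if direction == "low_to_high" else 5])
    corr_seq, *agent_seqs = master.spawn(n_agents + 1)

    if correction_tables is None:
        correction_tables = build_correction_tables(
            {0: get_condition(3, 1), 1: get_condition(3, 2)},
            correction_n_sims,
            np.random.default_rng(corr_seq),
        )

    all_rows = []
    true_info = []
    for a_idx, seq in enumerate(agent_seqs):
        rng = np.random.default_rng(seq)
        pre_level = float(rng.uniform(*pre_bound_range))
        ndt = int(rng.choice(list(sc.DEFAULT_NDT_CHOICES)))
        fg = float(rng.uniform(*sc.DEFAULT_FAST_GUESS_RANGE))
        base_policy = sc.AgentPolicy(
            bound_schedule=sc.BoundSchedule(sc.SCHEDULE_CONSTANT, level=pre_level),
            ndt_steps=ndt,
            fast_guess_prob=fg,
        )
        fixed_trials, _ = sc.simulate_block(base_policy, cond_fixed, rng)
        cp_step = cp_step_from_rts([t.rt_steps for t in fixed_trials])

        rrf_true = rr.rr_function_changepoint(
            cond_cp, pre_bound=pre_level, changepoint_step=cp_step,
            n_reps=rr_n_reps, rng=rng,
        )
        gain = float(rng.uniform(*follow_gain_range))
        grad = rr.rr_gradient(rrf_true, pre_level).gradient
        post_level = float(np.clip(pre_level + gain * grad, 0.01, 0.8))

        cp_policy = dataclasses.replace(
            base_policy,
            bound_schedule=sc.BoundSchedule(
                sc.SCHEDULE_PIECEWISE, level=pre_level, post_level=post_level
            ),
        )
        cond_cp_agent = dataclasses.replace(cond_cp, changepoint_step=cp_step)
        records = []
        for _ in range(n_cp_blocks):
            blk, _ = sc.simulate_block(cp_policy, cond_cp_agent, rng)
            records.extend(blk)
        all_rows.extend(
            sc._records_to_rows(records, a_idx, 3, 0, cp_step)
        )
        true_info.append(
            {
                "participant_id": a_idx,
                "cp_step": cp_step,
                "true_pre_bound": pre_level,
                "true_post_bound": post_level,
            }
        )

    trials = pd.DataFrame(all_rows, columns=sc.TRIAL_TABLE_COLUMNS)
    conditions = {0: cond_cp}
    analyzed = ba.analyze_trials(trials, correction_tables, conditions)
    cp_steps = {r["participant_id"]: r["cp_step"] for r in true_info}
    changes = changepoint_bound_change(analyzed, cp_steps, 0)

    rng = np.random.default_rng(master.spawn(1)[0])
    grads = []
    for _, row in changes.iterrows():
        rrf = rr.rr_function_changepoint(
            cond_cp,
            pre_bound=row["pre_mean_bound"],
            changepoint_step=int(row["cp_step"]),
            n_reps=rr_n_reps,
            rng=rng,
        )
        grads.append(rr.rr_gradient(rrf, row["pre_mean_bound"]).gradient)
    changes["rr_gradient"] = grads
    changes = changes.merge(pd.DataFrame(true_info), on=["participant_id", "cp_step"])
    rho = float(
        stats.spearmanr(changes["rr_gradient"], changes["bound_change"]).statistic
    )
    return changes, rho
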