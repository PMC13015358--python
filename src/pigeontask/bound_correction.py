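"""Simulation-based correction of short-DT biases in raw bound estimates.

The midpoint bound estimate |(pos[DT−1] + pos[DT])/2| is nearly unbiased at
long decision times, where the step locations are almost independent of the
chosen bound, but strongly biased at short DTs: the first steps are
distributed by the generative step distribution regardless of the bound, so
low bounds are overestimated and high bounds underestimated.  The
correction simulates fixed-bound decisions over a grid of true bounds,
pools trials by DT, fits a linear map of measured on true bound per DT, and
inverts that map so corrected measured values are calibrated to the true
simulated bounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .task_model import EDGE, DEFAULT_MAX_STEPS

#: The 16 true bound values simulated per SNR: 0.01 to 0.76 in steps of 0.05.
DEFAULT_BOUND_GRID = np.round(0.01 + 0.05 * np.arange(16), 2)
#: Scaled-down default simulation size per bound value.
DEFAULT_N_SIMS = 100_000
#: Minimum pooled trials in a DT cell for a fitted (non-identity) map.
MIN_CELL_TRIALS = 30


@dataclass
class CorrectionTable:
    """Per-DT linear maps from true to measured bound, used inverted.

    ``coeffs[dt] = (slope, intercept)`` of the OLS fit of measured on true
    bound among pooled simulated trials with that DT.  Correction inverts
    the fit: corrected = (raw − intercept) / slope, clipped to [0, 0.8].
    DTs outside the table (or cells that fell back) map to identity.
    """

    snr: float
    coeffs: dict[int, tuple[float, float]]
    metadata: dict = field(default_factory=dict)

    def correct(self, raw_bound: float, dt: int) -> float:
        slope, intercept = self.coeffs.get(int(dt), (1.0, 0.0))
        if slope <= 0:
            warnings.warn(
                f"non-positive slope at dt={dt}; identity fallback", stacklevel=2
            )
            slope, intercept = 1.0, 0.0
        return float(np.clip((raw_bound - intercept) / slope, 0.0, EDGE))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "snr": self.snr,
                "coeffs": {
                    str(dt): [s, i] for dt, (s, i) in sorted(self.coeffs.items())
                },
                "metadata": self.metadata,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrectionTable":
        d = json.loads(text)
        return cls(
            snr=d["snr"],
            coeffs={int(k): (v[0], v[1]) for k, v in d["coeffs"].items()},
            metadata=d.get("metadata", {}),
        )


def build_correction_table(
    mu: float,
    sigma: float,
    bound_grid: np.ndarray | None = None,
    n_sims_per_bound: int = DEFAULT_N_SIMS,
    ndt_range: tuple[int, int] = (0, 2),
    rng: np.random.Generator | int | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> CorrectionTable:
    """Simulate fixed-bound decisions and fit the per-DT measured↔true maps.

    For each true bound on the grid, ``n_sims_per_bound`` trials are
    simulated with per-trial motor delays drawn uniformly from
    ``ndt_range``; the walk continues during the delay, and the measured DT
    used for pooling is the commitment step (the estimation chain recovers
    session non-decision times exactly in this regime, so measured and true
    DT coincide).  Trials forced at the step cap are excluded.  DT cells
    with fewer than 30 pooled trials fall back to the identity map.
    """
    if bound_grid is None:
        bound_grid = DEFAULT_BOUND_GRID
    if n_sims_per_bound < 1_000:
        raise ValueError("n_sims_per_bound must be >= 1000")
    rng = np.random.default_rng(rng)
    ndt_lo, ndt_hi = ndt_range

    dts_all, measured_all, true_all = [], [], []
    for b in bound_grid:
        batch = _kernels.simulate_trial_batch(
            n_sims_per_bound,
            mu_schedule=np.float64(mu),
            sigma=sigma,
            bounds=float(b),
            rng=rng,
            max_steps=max_steps,
            n_steps=max_steps + ndt_hi,
        )
        # per-trial motor delay; drawn for protocol fidelity (the walk runs
        # on during it) though the measured DT below equals the commit step
        rng.integers(ndt_lo, ndt_hi + 1, size=n_sims_per_bound)
        keep = ~batch.forced
        dt = batch.commit_step[keep]
        pos = batch.positions[keep]
        prev = np.where(dt > 1, pos[np.arange(len(dt)), dt - 2], 0.0)
        at = pos[np.arange(len(dt)), dt - 1]
        measured = np.abs((prev + at) / 2.0)
        dts_all.append(dt)
        measured_all.append(measured)
        true_all.append(np.full(len(dt), float(b)))

    dt = np.concatenate(dts_all)
    measured = np.concatenate(measured_all)
    true = np.concatenate(true_all)

    coeffs: dict[int, tuple[float, float]] = {}
    for d in np.unique(dt):
        mask = dt == d
        if mask.sum() < MIN_CELL_TRIALS:
            warnings.warn(
                f"DT={d}: {int(mask.sum())} trials < {MIN_CELL_TRIALS}; "
                "identity fallback",
                stacklevel=2,
            )
            coeffs[int(d)] = (1.0, 0.0)
            continue
        t, m = true[mask], measured[mask]
        if np.var(t) == 0:
            coeffs[int(d)] = (1.0, 0.0)
            continue
        slope, intercept = np.polyfit(t, m, 1)
        coeffs[int(d)] = (float(slope), float(intercept))

    return CorrectionTable(
        snr=round(mu / sigma, 6),
        coeffs=coeffs,
        metadata={
            "mu": mu,
            "sigma": sigma,
            "bound_grid": [float(b) for b in bound_grid],
            "n_sims_per_bound": int(n_sims_per_bound),
            "ndt_range": list(ndt_range),
            "max_steps": int(max_steps),
        },
    )


def correct_bound(raw_bound: float, dt: int, table: CorrectionTable) -> float:
    """Functional form of :meth:`CorrectionTable.correct`."""
    return table.correct(raw_bound, dt)


def bias_by_true_bound(
    mu: float,
    sigma: float,
    dt_max_short: int = 2,
    bound_grid: np.ndarray | None = None,
    n_sims_per_bound: int = 20_000,
    rng: np.random.Generator | int | None = None,
) -> "dict[float, float]":
    """Mean (measured − true) bound at short DTs, per true bound.

    Diagnostic used to verify the direction of the short-DT biases.
    """
    if bound_grid is None:
        bound_grid = DEFAULT_BOUND_GRID
    rng = np.random.default_rng(rng)
    out = {}
    for b in bound_grid:
        batch = _kernels.simulate_trial_batch(
            n_sims_per_bound,
            mu_schedule=np.float64(mu),
            sigma=sigma,
            bounds=float(b),
            rng=rng,
        )
        keep = (~batch.forced) & (batch.commit_step <= dt_max_short)
        if keep.sum() == 0:
            out[float(b)] = np.nan
            continue
        dt = batch.commit_step[keep]
        pos = batch.positions[keep]
        prev = np.where(dt > 1, pos[np.arange(len(dt)), dt - 2], 0.0)
        at = pos[np.arange(len(dt)), dt - 1]
        measured = np.abs((prev + at) / 2.0)
        out[float(b)] = float(np.mean(measured - b))
    return out
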