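"""Posterior predictive checks on step-length and turn-angle distributions.

Continuous trajectories are discretized into steps of a fixed duration
(e.g. 2 h or 4 h); the displacement lengths and signed heading changes are
the standard movement-ecology summaries compared between observed and
model-simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .model import Trajectory

__all__ = ["StepTurnSummary", "ComparisonReport", "steps_and_turns", "compare_distributions"]


@dataclass
class StepTurnSummary:
    """Discretized steps of one window duration: lengths and signed turns."""

    window: float
    step_lengths: np.ndarray
    turn_angles: np.ndarray

    def __post_init__(self) -> None:
        self.step_lengths = np.asarray(self.step_lengths, dtype=float)
        self.turn_angles = np.asarray(self.turn_angles, dtype=float)


def steps_and_turns(
    traj: Trajectory, window: float, tolerance_frac: float = 0.1
) -> StepTurnSummary:
    """Resample at window boundaries and summarize displacements.

    Positions are taken from the nearest fix within ``tolerance_frac`` of
    the window at each boundary time; boundaries with no fix close enough
    break the sequence into separate blocks.  Steps are Euclidean
    displacements between consecutive resampled points; turns are signed
    angles in (-pi, pi] between consecutive displacement vectors within a
    block.
    """
    dt_med = float(np.median(np.diff(traj.times))) if len(traj) > 1 else np.inf
    if window < 2 * dt_med:
        raise ValueError("window must be at least twice the median fix interval")
    bounds = np.arange(traj.times[0], traj.times[-1] + 1e-12, window)
    tol = tolerance_frac * window
    # nearest fix per boundary
    idx = np.searchsorted(traj.times, bounds)
    blocks: list = []
    cur: list = []
    for b, i in zip(bounds, idx):
        cands = [j for j in (i - 1, i) if 0 <= j < len(traj)]
        j_best = min(cands, key=lambda j: abs(traj.times[j] - b))
        if abs(traj.times[j_best] - b) <= tol:
            cur.append(traj.values[j_best])
        else:
            if len(cur) >= 2:
                blocks.append(np.asarray(cur))
            cur = []
    if len(cur) >= 2:
        blocks.append(np.asarray(cur))
    n_points = sum(len(b) for b in blocks)
    if n_points < 3:
        raise ValueError("fewer than 3 resampled points; window too coarse")
    steps: list = []
    turns: list = []
    for b in blocks:
        d = np.diff(b, axis=0)
        lens = np.hypot(d[:, 0], d[:, 1])
        steps.append(lens)
        if len(d) >= 2:
            u, v = d[:-1], d[1:]
            cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
            dot = np.sum(u * v, axis=1)
            turns.append(np.arctan2(cross, dot))
    return StepTurnSummary(
        window=window,
        step_lengths=np.concatenate(steps),
        turn_angles=np.concatenate(turns) if turns else np.empty(0),
    )


@dataclass
class ComparisonReport:
    """Quantile and divergence comparison between two step/turn summaries."""

    step_quantiles_real: np.ndarray
    step_quantiles_sim: np.ndarray
    ks_distance: float
    ks_pvalue: float
    turn_tv_distance: float
    quantile_levels: np.ndarray

    def table(self) -> str:
        rows = ["quantile\treal\tsim"]
        for q, a, b in zip(
            self.quantile_levels, self.step_quantiles_real, self.step_quantiles_sim
        ):
            rows.append(f"{q:.2f}\t{a:.4g}\t{b:.4g}")
        rows.append(f"KS distance (steps)\t{self.ks_distance:.4f}")
        rows.append(f"KS p-value\t{self.ks_pvalue:.4g}")
        rows.append(f"TV distance (turns)\t{self.turn_tv_distance:.4f}")
        return "\n".join(rows)


def compare_distributions(
    real: StepTurnSummary, sim: StepTurnSummary, n_turn_bins: int = 24
) -> ComparisonReport:
    """Compare step-length and turn-angle distributions (report only).

    Step lengths get a two-sample Kolmogorov-Smirnov distance; turn angles
    get a total-variation distance between circular histograms on
    ``n_turn_bins`` equal angular bins.  No pass/fail verdict is issued.
    """
    if len(real.step_lengths) == 0 or len(sim.step_lengths) == 0:
        raise ValueError("both summaries must be nonempty")
    qs = np.array([0.05, 0.25, 0.5, 0.75, 0.95])
    ks = ks_2samp(real.step_lengths, sim.step_lengths)
    edges = np.linspace(-np.pi, np.pi, n_turn_bins + 1)
    if len(real.turn_angles) and len(sim.turn_angles):
        h_r, _ = np.histogram(real.turn_angles, bins=edges)
        h_s, _ = np.histogram(sim.turn_angles, bins=edges)
        p = h_r / h_r.sum()
        q = h_s / h_s.sum()
        tv = 0.5 * float(np.abs(p - q).sum())
    else:
        tv = float("nan")
    return ComparisonReport(
        step_quantiles_real=np.quantile(real.step_lengths, qs),
        step_quantiles_sim=np.quantile(sim.step_lengths, qs),
        ks_distance=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        turn_tv_distance=tv,
        quantile_levels=qs,
    )
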