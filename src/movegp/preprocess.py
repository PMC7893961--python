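"""Trajectory preparation: velocities, segmentation, support-point placement.

Long trajectories are split into consecutive segments that are treated as
conditionally independent local GPs sharing the latent movement parameters;
this replaces one O(k^3) likelihood with a sum of much cheaper ones and is
accurate when each segment spans many correlation lengthscales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationPlan",
    "finite_difference_velocity",
    "segment_trajectory",
    "place_support_points",
]


@dataclass(frozen=True)
class SegmentationPlan:
    """Split into consecutive blocks of ``segment_length`` points.

    ``tail_policy='keep-short-tail'`` keeps a final shorter segment;
    ``'merge-into-last'`` appends the tail to the previous segment.
    """

    segment_length: int
    tail_policy: str = "keep-short-tail"

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        if self.tail_policy not in ("keep-short-tail", "merge-into-last"):
            raise ValueError("unknown tail_policy")


def finite_difference_velocity(traj: Trajectory) -> Trajectory:
    """Forward-difference velocities assigned to the left timestamp.

    v_i = (x_{i+1} - x_i) / (t_{i+1} - t_i), reported at t_i; output has
    n - 1 points.
    """
    if traj.value_kind != "position":
        raise ValueError("finite_difference_velocity expects positions")
    if len(traj) < 2:
        raise ValueError("need at least two fixes to difference")
    dt = np.diff(traj.times)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in trajectory")
    v = np.diff(traj.values, axis=0) / dt[:, None]
    return Trajectory(
        individual_id=traj.individual_id,
        times=traj.times[:-1].copy(),
        values=v,
        value_kind="velocity",
    )


def segment_trajectory(traj: Trajectory, plan: SegmentationPlan) -> list:
    """Consecutive, non-overlapping segments whose concatenation is the input."""
    n = len(traj)
    j = plan.segment_length
    if n < j:
        logger.info("trajectory shorter than segment length; returning one segment")
        return [traj]
    starts = list(range(0, n, j))
    bounds = [(s, min(s + j, n)) for s in starts]
    if plan.tail_policy == "merge-into-last" and len(bounds) > 1:
        last = bounds[-1]
        if last[1] - last[0] < j:
            prev = bounds[-2]
            bounds = bounds[:-2] + [(prev[0], last[1])]
    out = []
    for a, b in bounds:
        out.append(
            Trajectory(
                individual_id=traj.individual_id,
                times=traj.times[a:b].copy(),
                values=traj.values[a:b].copy(),
                value_kind=traj.value_kind,
            )
        )
    return out


def place_support_points(
    start: float,
    stop: float,
    count: int = None,
    spacing: float = None,
    periodic: bool = False,
) -> np.ndarray:
    """Evenly spaced support points over ``[start, stop]``.

    For a periodic domain (period ``stop - start``) the points tile the
    circle with no duplicate at the wrap; otherwise both endpoints are
    included.  Exactly one of ``count`` and ``spacing`` must be given, and
    the spacing must not exceed the domain extent.
    """
    extent = stop - start
    if extent <= 0:
        raise ValueError("domain must have positive extent")
    if (count is None) == (spacing is None):
        raise ValueError("give exactly one of count or spacing")
    if spacing is not None:
        if spacing > extent:
            raise ValueError("spacing exceeds domain extent")
        count = int(round(extent / spacing)) + (0 if periodic else 1)
    if count < 2:
        raise ValueError("need at least 2 support points")
    if periodic:
        return start + extent * np.arange(count) / count
    return np.linspace(start, stop, count)
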