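"""Lifetime classification of trajectories and per-group statistics.

A diffraction spot stays visible only while its nanocrystal keeps the
reflection inside the recorded energy band, so fast-moving molecules produce
short-lived spots and slow movers long-lived ones.  Grouping trajectories by
lifetime therefore stratifies the ensemble by overall mobility.  The four
groups follow the convention: immediate (LT < 1.5 s), short (1.5–4.0 s),
medium (4.0–7.5 s) and long (≥ 7.5 s), with lower bounds inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import Transition, mean_transition
from .stats import DiffusionFit, MSDCurve, ensemble_msd_with_band, \
    fit_diffusion_coefficient
from .trajectory import AngularTrajectory

GROUP_LABELS = ("LT1", "LT2", "LT3", "LT4")


@dataclass
class LifetimeThresholds:
    """Group boundaries in seconds: LT1 < t1 ≤ LT2 < t2 ≤ LT3 < t3 ≤ LT4."""

    t1: float = 1.5
    t2: float = 4.0
    t3: float = 7.5

    def __post_init__(self) -> None:
        if not 0 < self.t1 < self.t2 < self.t3:
            raise ValueError("thresholds must satisfy 0 < t1 < t2 < t3")


def classify_lifetime(lifetime,
                      thresholds: LifetimeThresholds | None = None):
    """Map lifetime(s) in seconds to a group label LT1–LT4.

    Accepts a scalar, an array of lifetimes, or an
    :class:`~dxtrack.trajectory.AngularTrajectory`.  Boundaries belong to the
    upper group (1.5 s → LT2, 7.5 s → LT4).
    """
    if thresholds is None:
        thresholds = LifetimeThresholds()
    if isinstance(lifetime, AngularTrajectory):
        lifetime = lifetime.lifetime
    lt = np.asarray(lifetime, dtype=float)
    if np.any(lt < 0):
        raise ValueError("lifetime must be >= 0")
    edges = [thresholds.t1, thresholds.t2, thresholds.t3]
    idx = np.searchsorted(edges, lt, side="right")
    labels = np.asarray(GROUP_LABELS)[idx]
    if labels.ndim == 0:
        return str(labels)
    return labels


def partition_by_lifetime(trajs, thresholds: LifetimeThresholds | None = None
                          ) -> dict[str, list[AngularTrajectory]]:
    """Split trajectories into the four lifetime groups (possibly empty)."""
    groups: dict[str, list] = {g: [] for g in GROUP_LABELS}
    for tr in trajs:
        groups[classify_lifetime(tr.lifetime, thresholds)].append(tr)
    return groups


@dataclass
class GroupStatistics:
    """Per-group statistics bundle (None where the group is too small)."""

    label: str
    count: int
    percentage: float           # of total, one decimal
    msd: MSDCurve | None = None
    fit: DiffusionFit | None = None
    mean_transition: Transition | None = None


@dataclass
class GroupSummary:
    """Counts, percentages and statistics for all four lifetime groups."""

    total: int
    groups: dict[str, GroupStatistics] = field(default_factory=dict)
    condition: str = ""
    region: str = ""

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            (self.condition, self.region, self.total, g.label, g.count,
             g.percentage)
            for g in self.groups.values()
        ]
        return pd.DataFrame(rows, columns=[
            "condition", "region", "total", "group", "count", "percentage",
        ])


def group_summary(trajs, thresholds: LifetimeThresholds | None = None,
                  axis: str = "chi", lags=None, fit_lags=None,
                  dt_grid=None, n_boot: int = 1000, seed: int = 0,
                  min_samples: int = 10,
                  condition: str = "", region: str = "") -> GroupSummary:
    """Classify trajectories and run the statistics suite per group.

    Counts and one-decimal percentages are always reported; MSD curve,
    diffusion fit and mean transition are computed for each group with
    enough members (at least 2 trajectories reaching the first lag), and
    omitted otherwise.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("group_summary needs at least 1 trajectory")
    parts = partition_by_lifetime(trajs, thresholds)
    total = len(trajs)

    frame_interval = trajs[0].frame_interval
    if lags is None:
        lags = frame_interval * np.arange(1, 11)
    if dt_grid is None:
        dt_grid = lags

    summary = GroupSummary(total=total, condition=condition, region=region)
    for label in GROUP_LABELS:
        members = parts[label]
        gs = GroupStatistics(
            label=label,
            count=len(members),
            percentage=round(100.0 * len(members) / total, 1),
        )
        reach_first = [
            tr for tr in members if tr.lifetime >= lags[0] - 1e-12
        ]
        if len(reach_first) >= 2:
            gs.msd = ensemble_msd_with_band(
                members, axis, lags, n_boot=n_boot, seed=seed
            )
            if len(gs.msd.lags) >= 2:
                gs.fit = fit_diffusion_coefficient(gs.msd, fit_lags)
            gs.mean_transition = mean_transition(
                members, axis, dt_grid, min_samples=min_samples, group=label
            )
        summary.groups[label] = gs
    return summary
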