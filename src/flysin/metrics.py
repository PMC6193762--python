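"""Dyadic affiliation statistics: interactivity index and coincidental approaches.

The interactivity index of a dyad is the Pearson correlation between the
two flies' distance-to-barrier time series over a session. Its sign is
meaningful (coordinated approach vs avoidance); its magnitude measures
interaction strength. Coincidental approaches count the maximal episodes
in which both flies are simultaneously within one body length (3 mm) of
the barrier; an episode is one event regardless of duration, and a new
event requires at least one fly to have left and re-entered the zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedMetricError
from .geometry import ArenaSpec, BarrierSpec, barrier_distance_series
from .trajectory import AnalysisConfig, Trajectory, compute_speed


@dataclass
class DyadRecord:
    """Two time-aligned trajectories in opposite compartments of one arena."""

    dyad_id: str
    fly_a: Trajectory
    fly_b: Trajectory
    arena: ArenaSpec
    barrier: BarrierSpec
    genotype: str = "wild_type"

    def __post_init__(self):
        a, b = self.fly_a, self.fly_b
        if a.fps != b.fps:
            raise ValueError("dyad members must share fps")
        if len(a) != len(b) or not np.array_equal(a.frame, b.frame):
            raise ValueError("dyad members must share the frame range")
        if a.compartment == b.compartment:
            raise ValueError("dyad members must occupy opposite compartments")

    @property
    def day(self) -> int:
        return self.fly_a.day

    @property
    def session(self) -> int:
        return self.fly_a.session


@dataclass
class DyadMetricRow:
    """Per-dyad, per-session statistics (one row of the central table)."""

    dyad_id: str
    day: int
    session: int
    fly_a: str
    fly_b: str
    barrier_type: str
    genotype: str
    interactivity_index: float
    n_frames_used: int
    coincidental_approaches: int
    normalized_approaches: float
    dyad_mean_speed: float
    mean_speed_a: float
    mean_speed_b: float
    excluded: bool = False
    exclusion_reason: str = ""


def interactivity_index(dist_a, dist_b) -> tuple[float, int]:
    """Pearson correlation of two barrier-distance series.

    Frames where either series is NaN are deleted pairwise. Returns
    (index, n_frames_used). Raises UndefinedMetricError when fewer than
    3 paired frames remain or either series has zero variance (the dyad
    is excluded, never silently scored 0).
    """
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if a.shape != b.shape:
        raise ValueError("distance series must be equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise UndefinedMetricError(f"only {len(a)} paired frames (need >= 3)")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedMetricError("zero-variance distance series")
    r = stats.pearsonr(a, b).statistic
    return float(r), int(len(a))


def coincidental_approaches(dist_a, dist_b, body_length: float = 3.0) -> int:
    """Count coincidental-approach episodes.

    An episode is a maximal run of frames in which both distances are
    <= body_length simultaneously; it scores one event irrespective of
    duration, and a subsequent event requires at least one fly to have
    left the zone in between. Frames where either series is NaN are
    unknown: they neither extend nor terminate an episode, so runs of
    co-occupancy separated only by unknown frames merge into one event.
    """
    if body_length <= 0:
        raise ValueError("body_length must be positive")
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    known = np.isfinite(a) & np.isfinite(b)
    both_in = (a[known] <= body_length) & (b[known] <= body_length)
    if both_in.size == 0:
        return 0
    # count entries into the co-occupancy state among known frames
    entries = int(both_in[0]) + int(np.sum(both_in[1:] & ~both_in[:-1]))
    return entries


def normalize_approaches(count: int, mean_speed_a: float, mean_speed_b: float) -> float:
    """Approach count per unit dyad mean speed (grand mean of the two flies)."""
    dyad_speed = (mean_speed_a + mean_speed_b) / 2.0
    if not np.isfinite(dyad_speed) or dyad_speed <= 0:
        raise UndefinedMetricError("dyad mean speed must be positive")
    return count / dyad_speed


def barrier_distances(traj: Trajectory, arena: ArenaSpec, include_imputed: bool = True):
    """Distance-to-barrier series for one fly; NaN at unusable frames.

    Out-of-bounds samples (centroid outside the arena circle) are dropped
    as invalid rather than clipped.
    """
    d, in_bounds = barrier_distance_series(traj.x, traj.y, arena, traj.compartment)
    usable = traj.valid & in_bounds
    if not include_imputed:
        usable &= ~traj.imputed
    return np.where(usable, d, np.nan)


def dyad_metrics(dyad: DyadRecord, config: AnalysisConfig | None = None) -> DyadMetricRow:
    """All per-session statistics for one dyad.

    Composes the barrier-distance geometry with the interactivity index,
    coincidental-approach count, speed normalisation, and the immobility
    rule. A dyad whose index is undefined (immobile fly, zero variance,
    too few frames) is returned flagged excluded with the reason, with
    NaN statistics.
    """
    config = config or AnalysisConfig()
    da = barrier_distances(dyad.fly_a, dyad.arena, config.use_imputed)
    db = barrier_distances(dyad.fly_b, dyad.arena, config.use_imputed)

    def _mean_speed(t: Trajectory) -> float:
        s = compute_speed(t)
        return float(np.nanmean(s)) if not np.all(np.isnan(s)) else np.nan

    try:
        ms_a = _mean_speed(dyad.fly_a)
        ms_b = _mean_speed(dyad.fly_b)
    except UndefinedMetricError as exc:
        return _excluded_row(dyad, str(exc))
    dyad_speed = (ms_a + ms_b) / 2.0

    reason = ""
    if not np.isfinite(ms_a) or ms_a <= config.speed_threshold:
        reason = f"fly {dyad.fly_a.fly_id} immobile (mean speed <= {config.speed_threshold} mm/s)"
    elif not np.isfinite(ms_b) or ms_b <= config.speed_threshold:
        reason = f"fly {dyad.fly_b.fly_id} immobile (mean speed <= {config.speed_threshold} mm/s)"
    if reason:
        return _excluded_row(dyad, reason, ms_a, ms_b, dyad_speed)

    try:
        idx, n_used = interactivity_index(da, db)
    except UndefinedMetricError as exc:
        return _excluded_row(dyad, exc.reason, ms_a, ms_b, dyad_speed)

    n_events = coincidental_approaches(da, db, config.body_length)
    norm = normalize_approaches(n_events, ms_a, ms_b)
    return DyadMetricRow(
        dyad_id=dyad.dyad_id, day=dyad.day, session=dyad.session,
        fly_a=dyad.fly_a.fly_id, fly_b=dyad.fly_b.fly_id,
        barrier_type=dyad.barrier.barrier_type, genotype=dyad.genotype,
        interactivity_index=idx, n_frames_used=n_used,
        coincidental_approaches=n_events, normalized_approaches=norm,
        dyad_mean_speed=dyad_speed, mean_speed_a=ms_a, mean_speed_b=ms_b,
    )


def _excluded_row(dyad: DyadRecord, reason: str,
                  ms_a=np.nan, ms_b=np.nan, dyad_speed=np.nan) -> DyadMetricRow:
    return DyadMetricRow(
        dyad_id=dyad.dyad_id, day=dyad.day, session=dyad.session,
        fly_a=dyad.fly_a.fly_id, fly_b=dyad.fly_b.fly_id,
        barrier_type=dyad.barrier.barrier_type, genotype=dyad.genotype,
        interactivity_index=np.nan, n_frames_used=0,
        coincidental_approaches=0, normalized_approaches=np.nan,
        dyad_mean_speed=dyad_speed, mean_speed_a=ms_a, mean_speed_b=ms_b,
        excluded=True, exclusion_reason=reason,
    )


def metric_table(rows: list[DyadMetricRow]):
    """DyadMetricRow list -> the central long-format table."""
    import pandas as pd

    return pd.DataFrame([vars(r) for r in rows])
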