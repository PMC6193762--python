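"""Trajectory data model, CSV I/O, speeds, gap interpolation, immobility filter.

A trajectory is one fly's centroid time series for one session: frame
index plus (x, y) in mm at a fixed frame rate (29.9 fps by default, the
tracking rate of the assays this pipeline analyses). Frames where the
tracker lost the fly are carried as invalid samples (NaN coordinates)
rather than silently dropped, so downstream statistics can do pairwise
deletion and episode logic correctly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import FormatError, UndefinedMetricError

TRAJECTORY_COLUMNS = [
    "day", "session", "arena_id", "compartment", "fly_id", "frame", "x_mm", "y_mm",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters.

    body_length: proximity scale (mm) defining the barrier approach zone.
    speed_threshold: immobility cutoff on session-mean speed (mm/s).
    fps: video frame rate (frames/s).
    n_boot: bootstrap resamples for standard errors.
    alpha: significance level for adjusted tests.
    max_gap_frames: longest tracking dropout (frames) filled by linear
        interpolation (~0.5 s at 29.9 fps by default).
    use_imputed: whether interpolated frames enter the interactivity index.
    rng_seed: base seed for every stochastic routine.
    """

    body_length: float = 3.0
    speed_threshold: float = 0.1
    fps: float = 29.9
    n_boot: int = 1000
    alpha: float = 0.05
    max_gap_frames: int = 15
    use_imputed: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("body_length", "speed_threshold", "fps", "n_boot", "max_gap_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class Trajectory:
    """One fly's centroid track for one session."""

    fly_id: str
    day: int
    session: int
    arena_id: str
    compartment: str
    frame: np.ndarray          # int, strictly increasing
    x: np.ndarray              # mm, NaN where invalid
    y: np.ndarray              # mm, NaN where invalid
    valid: np.ndarray          # bool
    imputed: np.ndarray = field(default=None)  # bool, True for gap-filled frames
    fps: float = 29.9

    def __post_init__(self):
        self.frame = np.asarray(self.frame, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros(len(self.frame), dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if not (len(self.frame) == len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("frame/x/y/valid must have equal length")
        if len(self.frame) > 1 and not np.all(np.diff(self.frame) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if bad.any():
            raise ValueError("valid frames must have finite coordinates")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def key(self):
        return (self.fly_id, self.day, self.session)


def read_trajectories(path_or_buf, config: AnalysisConfig | None = None) -> list[Trajectory]:
    """Read a trajectory CSV into one Trajectory per (fly, day, session).

    Rows are grouped and frame-sorted; rows with empty coordinates are
    marked invalid. Missing required columns or duplicate (fly, day,
    session, frame) rows raise FormatError.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path_or_buf, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.duplicated(subset=["fly_id", "day", "session", "frame"]).any():
        raise FormatError("duplicate (fly_id, day, session, frame) rows")
    out = []
    for (fly, day, session), grp in df.groupby(["fly_id", "day", "session"], sort=True):
        grp = grp.sort_values("frame")
        x = grp["x_mm"].to_numpy(dtype=float)
        y = grp["y_mm"].to_numpy(dtype=float)
        valid = np.isfinite(x) & np.isfinite(y)
        out.append(Trajectory(
            fly_id=str(fly), day=int(day), session=int(session),
            arena_id=str(grp["arena_id"].iloc[0]),
            compartment=str(grp["compartment"].iloc[0]),
            frame=grp["frame"].to_numpy(dtype=int),
            x=x, y=y, valid=valid, fps=config.fps,
        ))
    return out


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Inverse of read_trajectories; emits the same CSV dialect."""
    parts = []
    for t in trajs:
        parts.append(pd.DataFrame({
            "day": t.day, "session": t.session, "arena_id": t.arena_id,
            "compartment": t.compartment, "fly_id": t.fly_id,
            "frame": t.frame,
            "x_mm": np.where(t.valid, t.x, np.nan),
            "y_mm": np.where(t.valid, t.y, np.nan),
        }))
    return pd.concat(parts, ignore_index=True)


def write_trajectories(trajs: list[Trajectory], path, header_lines: list[str] | None = None):
    """Write trajectories as CSV (UTF-8, comma-separated, '#' comment header)."""
    buf = io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    trajectories_to_frame(trajs).to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def interpolate_gaps(traj: Trajectory, max_gap_frames: int) -> Trajectory:
    """Fill short tracking dropouts by linear interpolation.

    Runs of at most ``max_gap_frames`` consecutive invalid frames that are
    bracketed by valid frames are imputed (marked both valid and imputed);
    longer runs and runs touching the track ends are left invalid. Valid
    original samples are never altered.
    """
    valid = traj.valid.copy()
    x = traj.x.copy()
    y = traj.y.copy()
    imputed = traj.imputed.copy()
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run = j - i
        if i > 0 and j < n and run <= max_gap_frames:
            f0, f1 = traj.frame[i - 1], traj.frame[j]
            w = (traj.frame[i:j] - f0) / (f1 - f0)
            x[i:j] = traj.x[i - 1] + w * (traj.x[j] - traj.x[i - 1])
            y[i:j] = traj.y[i - 1] + w * (traj.y[j] - traj.y[i - 1])
            valid[i:j] = True
            imputed[i:j] = True
        i = j
    return replace(traj, x=x, y=y, valid=valid, imputed=imputed)


def compute_speed(traj: Trajectory) -> np.ndarray:
    """Per-step speed series (mm/s), length n_frames - 1.

    Step i covers frames i -> i+1: Euclidean displacement divided by the
    frame gap, times fps. Steps touching an invalid frame are NaN and are
    excluded from means.
    """
    if traj.n_valid < 2:
        raise UndefinedMetricError("need at least 2 valid frames to compute speed")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    gap = np.diff(traj.frame).astype(float)
    ok = traj.valid[:-1] & traj.valid[1:]
    speed = np.where(ok, np.hypot(dx, dy) * traj.fps / gap, np.nan)
    return speed


def mean_speed(traj: Trajectory) -> float:
    """Session-mean speed over valid steps (mm/s)."""
    s = compute_speed(traj)
    if np.all(np.isnan(s)):
        raise UndefinedMetricError("no valid speed steps")
    return float(np.nanmean(s))


def immobility_filter(metrics_rows: pd.DataFrame, config: AnalysisConfig):
    """Split metric rows into (kept, discarded) by the immobility rule.

    A row is discarded when its mean speed is at or below
    ``config.speed_threshold``. Per-fly rows must carry ``mean_speed``;
    per-dyad rows carry ``mean_speed_a`` and ``mean_speed_b`` and are
    discarded when *either* fly is immobile (the interactivity index is
    undefined for a near-constant distance series). Returns
    (kept, discarded, discard_fraction).
    """
    thr = config.speed_threshold
    if {"mean_speed_a", "mean_speed_b"} <= set(metrics_rows.columns):
        immobile = (
            (metrics_rows["mean_speed_a"] <= thr)
            | (metrics_rows["mean_speed_b"] <= thr)
            | metrics_rows["mean_speed_a"].isna()
            | metrics_rows["mean_speed_b"].isna()
        )
    elif "mean_speed" in metrics_rows.columns:
        immobile = (metrics_rows["mean_speed"] <= thr) | metrics_rows["mean_speed"].isna()
    else:
        raise FormatError("rows must carry mean_speed or mean_speed_a/mean_speed_b")
    kept = metrics_rows.loc[~immobile].copy()
    discarded = metrics_rows.loc[immobile].copy()
    frac = float(immobile.mean()) if len(metrics_rows) else 0.0
    return kept, discarded, frac
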