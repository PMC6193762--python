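"""Locomotor control metrics: activity fraction, Y-maze handedness, KDE bands.

The Y-maze handedness assay scores the left/right choices a fly makes at
the central choice point of a symmetric three-armed maze (arms 15.5 mm
long, 120 degrees apart, circular 5.2 mm arm ends). Turning bias is the
fraction of turns that are rightward — an individuality metric that is
stable within flies.

Turn classifier convention (deterministic, fixed for testability): every
frame is assigned to the 120-degree sector of the nearest arm; an arm
*visit* registers when the fly enters the distal half of an arm
(radius > arm_length / 2); consecutive distinct visits produce one turn;
a turn is R when the new arm is the clockwise neighbour of the previous
arm (arms are indexed clockwise), else L. Any consistent convention
yields the same bias distribution up to a global L/R flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import UndefinedMetricError
from .trajectory import Trajectory


@dataclass(frozen=True)
class YMazeSpec:
    """Geometry of one symmetric Y-maze arena."""

    arm_length: float = 15.5      # mm
    arm_angle_separation: float = 120.0  # degrees
    arm_end_diameter: float = 5.2  # mm
    center: tuple[float, float] = (0.0, 0.0)
    arm0_angle: float = 90.0       # degrees; arms indexed clockwise from here

    def __post_init__(self):
        if self.arm_angle_separation != 120.0:
            raise ValueError("three arms at 120 degree spacing required")

    def arm_angles(self) -> np.ndarray:
        """Arm axis directions in degrees, clockwise indexing."""
        return np.array([self.arm0_angle - 120.0 * i for i in range(3)])


@dataclass
class TurnSequence:
    """Ordered left/right choices of one fly at the Y-maze choice point."""

    fly_id: str
    turns: list = field(default_factory=list)  # entries "L" or "R"

    @property
    def n_turns(self) -> int:
        return len(self.turns)


def detect_turns(traj: Trajectory, maze: YMazeSpec | None = None) -> TurnSequence:
    """Classify a Y-maze trajectory into a turn sequence.

    A trajectory that never leaves one arm yields an empty sequence.
    Invalid frames are ignored.
    """
    maze = maze or YMazeSpec()
    ok = traj.valid
    x = traj.x[ok] - maze.center[0]
    y = traj.y[ok] - maze.center[1]
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x))
    arm_dirs = maze.arm_angles()
    # angular offset to each arm axis, wrapped to [-180, 180)
    diffs = np.abs((theta[:, None] - arm_dirs[None, :] + 180.0) % 360.0 - 180.0)
    arm = np.argmin(diffs, axis=1)
    distal = r > maze.arm_length / 2.0

    visits = arm[distal]
    if visits.size == 0:
        return TurnSequence(fly_id=traj.fly_id)
    changed = np.concatenate([[True], np.diff(visits) != 0])
    seq = visits[changed]
    turns = ["R" if b == (a + 1) % 3 else "L" for a, b in zip(seq[:-1], seq[1:])]
    return TurnSequence(fly_id=traj.fly_id, turns=turns)


def turning_bias(seq: TurnSequence) -> float:
    """Fraction of turns that are rightward: #R / #total."""
    if seq.n_turns == 0:
        raise UndefinedMetricError(f"fly {seq.fly_id}: no turns (excluded)")
    return seq.turns.count("R") / seq.n_turns


def activity_fraction(mean_speeds, threshold: float = 0.1) -> float:
    """Percentage of flies with supra-threshold activity (mean speed > threshold)."""
    s = np.asarray(mean_speeds, float)
    if s.size == 0:
        raise ValueError("need at least one fly")
    return float(100.0 * np.mean(s > threshold))


@dataclass
class KDEBand:
    """A kernel density estimate with a pointwise bootstrap confidence band."""

    grid: np.ndarray
    density: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    bandwidth_rule: str = "silverman"


def kde_with_bootstrap_band(values, n_boot: int = 1000, seed: int = 0,
                            grid_size: int = 256,
                            ci: float = 95.0) -> KDEBand:
    """Gaussian KDE with a pointwise bootstrap percentile band.

    The point estimate uses Silverman's bandwidth rule on a fixed grid
    spanning the data plus three bandwidths; each bootstrap resample is
    re-estimated with the same rule and evaluated on the same grid, and
    the band is the pointwise (100-ci)/2 and (100+ci)/2 percentiles.
    """
    values = np.asarray(values, float)
    if len(values) < 5:
        raise ValueError("need at least 5 values for a KDE")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    bw = kde.factor * values.std(ddof=1)
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    density = kde(grid)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, grid_size))
    for i in range(n_boot):
        sample = rng.choice(values, size=len(values), replace=True)
        if sample.std(ddof=1) == 0:  # degenerate resample: a point mass
            boot[i] = np.where(np.isclose(grid, sample[0]), np.inf, 0.0)
            continue
        boot[i] = stats.gaussian_kde(sample, bw_method="silverman")(grid)
    q = (100.0 - ci) / 2.0
    lower, upper = np.percentile(boot, [q, 100.0 - q], axis=0)
    return KDEBand(grid=grid, density=density, lower=lower, upper=upper)
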