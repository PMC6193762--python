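"""Arena geometry, barrier sensory channels, and dyad-pairing designs.

A social arena is a 30 mm circular chamber bisected by a 1.5 mm thick
removable barrier, giving two semicircular compartments that each hold one
fly. The barrier comes in four types that factorially gate the two sensory
channels between partners: clear vs black acrylic (vision) and open
air-channels vs solid bottom (olfaction).

Coordinate convention: millimetres, origin at the arena center, the barrier
lying along the y-axis, compartments labelled ``left`` (x < 0) and ``right``
(x > 0). Each compartment's barrier *face* is the chord-parallel segment
offset half the barrier thickness into that compartment; a fly's barrier
distance is the Euclidean point-to-segment distance to its own face.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InfeasibleDesignError, OutOfBoundsError

COMPARTMENTS = ("left", "right")

#: barrier_type -> (allows_vision, allows_olfaction)
BARRIER_CHANNELS = {
    "open_clear": (True, True),
    "solid_clear": (True, False),
    "open_black": (False, True),
    "solid_black": (False, False),
}

SCHEMES = ("scheme1_disjoint", "scheme2_kregular", "scheme3_saturated")


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of one bisected circular arena."""

    arena_id: str = "arena0"
    center: tuple[float, float] = (0.0, 0.0)
    diameter: float = 30.0
    barrier_thickness: float = 1.5
    compartments: tuple[str, str] = COMPARTMENTS

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not 0 <= self.barrier_thickness < self.diameter:
            raise ValueError("barrier_thickness must be in [0, diameter)")
        if len(self.compartments) != 2:
            raise ValueError("exactly two compartments required")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def half_chord(self) -> float:
        """Half-length of a barrier face segment."""
        half_t = self.barrier_thickness / 2.0
        return math.sqrt(self.radius**2 - half_t**2)

    def face_x(self, compartment: str) -> float:
        """x-coordinate of the barrier face seen from `compartment`."""
        half_t = self.barrier_thickness / 2.0
        if compartment == self.compartments[0]:
            return self.center[0] - half_t
        if compartment == self.compartments[1]:
            return self.center[0] + half_t
        raise ValueError(f"unknown compartment {compartment!r}")

    def face_segment(self, compartment: str):
        """The barrier face as ((x, y0), (x, y1)) endpoints, mm."""
        x = self.face_x(compartment)
        cy = self.center[1]
        h = self.half_chord
        return ((x, cy - h), (x, cy + h))

    def contains(self, x, y, tol: float = 1e-9):
        """Whether position(s) lie within the circular arena boundary."""
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        return dx * dx + dy * dy <= (self.radius + tol) ** 2

    def compartment_polygon(self, compartment: str, n_arc: int = 32):
        """Vertex list (closed) of a semicircular compartment outline."""
        (fx, y0), (_, y1) = self.face_segment(compartment)
        cx, cy = self.center
        a0 = math.atan2(y1 - cy, fx - cx)
        a1 = math.atan2(y0 - cy, fx - cx)
        sign = -1.0 if compartment == self.compartments[0] else 1.0
        if sign < 0:
            # traverse the far (x<0) arc
            a1 += 2 * math.pi if a1 < a0 else 0.0
            angles = np.linspace(a0, a1, n_arc)
        else:
            angles = np.linspace(a0, a1, n_arc)
        pts = [(cx + self.radius * math.cos(a), cy + self.radius * math.sin(a)) for a in angles]
        return [(fx, y1)] + pts + [(fx, y0), (fx, y1)]


@dataclass(frozen=True)
class BarrierSpec:
    """Sensory-channel flags of an interchangeable interaction barrier.

    The four physical types map onto the two channels as:
    open_clear -> vision+olfaction, solid_clear -> vision only,
    open_black -> olfaction only, solid_black -> neither.
    """

    barrier_type: str
    allows_vision: bool
    allows_olfaction: bool

    def __post_init__(self):
        expected = BARRIER_CHANNELS.get(self.barrier_type)
        if expected is None:
            raise ValueError(f"unknown barrier_type {self.barrier_type!r}")
        if (self.allows_vision, self.allows_olfaction) != expected:
            raise ValueError(
                f"channel flags {self.allows_vision, self.allows_olfaction} "
                f"inconsistent with barrier_type {self.barrier_type!r}"
            )

    @classmethod
    def from_type(cls, barrier_type: str) -> "BarrierSpec":
        vision, olfaction = BARRIER_CHANNELS[barrier_type]
        return cls(barrier_type, vision, olfaction)


def barrier_distance(position, arena: ArenaSpec, compartment: str) -> float:
    """Euclidean distance (mm) from a centroid to its compartment's barrier face.

    Distance is point-to-segment: laterally beyond the face's chord
    endpoints the nearest endpoint governs. Raises OutOfBoundsError for a
    position outside the arena circle; the caller decides whether to drop
    or clip such samples.
    """
    x, y = float(position[0]), float(position[1])
    if not arena.contains(x, y, tol=1e-6):
        raise OutOfBoundsError(f"position {position} outside arena {arena.arena_id}")
    d, _ = barrier_distance_series(np.array([x]), np.array([y]), arena, compartment)
    return float(d[0])


def barrier_distance_series(x, y, arena: ArenaSpec, compartment: str):
    """Vectorised barrier distance with an in-bounds mask.

    Returns (distances, in_bounds); out-of-bounds samples still get a
    distance so the caller may clip instead of dropping.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fx = arena.face_x(compartment)  # validates compartment
    cy = arena.center[1]
    h = arena.half_chord
    dy = np.maximum(np.abs(y - cy) - h, 0.0)
    dist = np.hypot(x - fx, dy)
    return dist, arena.contains(x, y, tol=1e-6)


# ---------------------------------------------------------------------------
# Dyad-pairing designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DyadScheme:
    """One of the three pairing designs used to form dyads.

    scheme1_disjoint: a random perfect matching (each fly in one dyad).
    scheme2_kregular: each fly in exactly ``k`` dyads (a simple k-regular
    pairing graph). scheme3_saturated: all C(n, 2) dyads, optionally
    repeated ``repeats`` times in a round-robin schedule.
    """

    scheme: str
    n_flies: int
    k: int | None = None
    repeats: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_flies < 2:
            raise InfeasibleDesignError("need at least 2 flies")
        if self.scheme == "scheme1_disjoint" and self.n_flies % 2:
            raise InfeasibleDesignError("scheme 1 requires an even number of flies")
        if self.scheme == "scheme2_kregular":
            if self.k is None or self.k < 1:
                raise InfeasibleDesignError("scheme 2 requires k >= 1")
            if self.k >= self.n_flies:
                raise InfeasibleDesignError("scheme 2 requires k < n_flies")
            if (self.n_flies * self.k) % 2:
                raise InfeasibleDesignError("scheme 2 requires n_flies * k even")
        if self.scheme == "scheme3_saturated" and self.n_flies % 2:
            raise InfeasibleDesignError(
                "scheme 3 requires even n_flies for conflict-free rounds"
            )
        if self.repeats < 1:
            raise InfeasibleDesignError("repeats must be >= 1")


def enumerate_dyads(design: DyadScheme) -> list[tuple[int, int]]:
    """All dyads (unordered fly-id pairs over 0..n-1) under a pairing design."""
    n = design.n_flies
    if design.scheme == "scheme1_disjoint":
        rng = np.random.default_rng(design.seed)
        order = rng.permutation(n)
        return [tuple(sorted((int(order[2 * i]), int(order[2 * i + 1]))))
                for i in range(n // 2)]
    if design.scheme == "scheme2_kregular":
        # pairing-model construction (repeated until simple), as implemented
        # by networkx; any simple k-regular graph is admissible
        try:
            g = nx.random_regular_graph(design.k, n, seed=design.seed)
        except nx.NetworkXError as exc:  # pragma: no cover - guarded above
            raise InfeasibleDesignError(str(exc)) from exc
        return sorted(tuple(sorted(e)) for e in g.edges)
    return [tuple(p) for p in itertools.combinations(range(n), 2)]


def schedule_rounds(dyads, n_flies: int, repeats: int = 1):
    """Round-robin (circle method) schedule for the saturated scheme.

    Returns (n_flies - 1) * repeats rounds; each round is a list of
    n_flies/2 disjoint dyads covering every fly exactly once, and across
    each block of (n_flies - 1) rounds every dyad appears exactly once.
    """
    if n_flies % 2:
        raise InfeasibleDesignError("round-robin scheduling requires even n_flies")
    full = set(itertools.combinations(range(n_flies), 2))
    if set(map(tuple, (tuple(sorted(d)) for d in dyads))) != full:
        raise InfeasibleDesignError("schedule_rounds expects all C(n,2) dyads")
    arr = list(range(n_flies))
    one_cycle = []
    for _ in range(n_flies - 1):
        rnd = [tuple(sorted((arr[i], arr[n_flies - 1 - i]))) for i in range(n_flies // 2)]
        one_cycle.append(rnd)
        # rotate all but the first element
        arr = [arr[0], arr[-1]] + arr[1:-1]
    return one_cycle * repeats


@dataclass(frozen=True)
class ArrayLayout:
    """A rows x cols grid of behavioural arenas at regular pitch."""

    rows: int
    cols: int
    kind: str  # social | ymaze | flyplate
    arena_positions: tuple[ArenaSpec, ...] = field(default=())

    @property
    def n_arenas(self) -> int:
        return self.rows * self.cols

    @property
    def n_compartments(self) -> int:
        return self.n_arenas * (2 if self.kind == "social" else 1)


def build_array_layout(kind: str, rows: int, cols: int, pitch: float = 33.0) -> ArrayLayout:
    """Lay out a grid of arenas; social arenas contribute two compartments each."""
    if kind not in ("social", "ymaze", "flyplate"):
        raise ValueError(f"unknown array kind {kind!r}")
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    arenas = tuple(
        ArenaSpec(arena_id=f"a{r * cols + c}", center=(c * pitch, r * pitch))
        for r in range(rows)
        for c in range(cols)
    )
    return ArrayLayout(rows=rows, cols=cols, kind=kind, arena_positions=arenas)


def layout_to_frame(layout: ArrayLayout) -> pd.DataFrame:
    """Arena centers and compartment polygon vertex lists as a table."""
    rows = []
    for arena in layout.arena_positions:
        if layout.kind == "social":
            for comp in arena.compartments:
                poly = arena.compartment_polygon(comp)
                rows.append({
                    "arena_id": arena.arena_id,
                    "center_x_mm": arena.center[0],
                    "center_y_mm": arena.center[1],
                    "compartment": comp,
                    "polygon_mm": ";".join(f"{px:.3f},{py:.3f}" for px, py in poly),
                })
        else:
            rows.append({
                "arena_id": arena.arena_id,
                "center_x_mm": arena.center[0],
                "center_y_mm": arena.center[1],
                "compartment": "whole",
                "polygon_mm": "",
            })
    return pd.DataFrame(rows)
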