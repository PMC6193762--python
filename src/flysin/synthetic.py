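"""Synthetic trajectory generators with the statistical structure the analyses assume.

Each fly performs a reflected Gaussian random walk confined to its
semicircular compartment. Social coupling enters as a drift term toward
the fly's own barrier face proportional to a saturating "proximity
signal" of its partner's barrier distance, routed through the two sensory
channels (vision, olfaction) that the barrier type and the genotypes
gate. With both channels closed the two walks are independent, giving an
exact null for the interactivity index.

In experiment mode each fly carries a latent sociability that evolves
across days as a stationary AR(1) process with parameter
``persistence_rho``; a dyad's coupling is the product of its members'
latent values times the open channel gain, so day-to-day persistence of
dyadic indices is controlled by rho (expected coupling correlation
rho**2 between successive days) and both coupling signs arise naturally.

The generator also emulates immobile flies (session-long, sub-threshold
jitter), per-frame tracking dropouts, and emits the exact trajectory and
design CSV dialects the pipeline reads. All generators are pure
functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .exceptions import InfeasibleDesignError
from .geometry import ArenaSpec, BarrierSpec, DyadScheme, enumerate_dyads, schedule_rounds
from .locomotor import TurnSequence
from .metrics import DyadRecord
from .trajectory import Trajectory

# Channel weights (mm/frame of barrier-ward drift at full proximity signal),
# set by calibrate_channel_weights so that simulated group means reproduce
# the qualitative ordering of the real assay: open-clear wild type highest,
# anosmic flies behind open-clear barriers at roughly a third of the
# wild-type mean |index|, and solid-black at the null level.
W_VISION_DEFAULT = 0.015
W_OLFACTION_DEFAULT = 0.20


@dataclass(frozen=True)
class CouplingParams:
    """Generator parameters for coupled random-walk dyads.

    Weights are in mm/frame of drift; step_sd is the per-axis Gaussian
    step (mm/frame); barrier_attraction is a small baseline drift toward
    the fly's own barrier face; persistence_rho controls day-to-day
    retention of each fly's latent sociability.
    """

    w_vision: float = W_VISION_DEFAULT
    w_olfaction: float = W_OLFACTION_DEFAULT
    sign: int = 1
    step_sd: float = 0.5
    barrier_attraction: float = 0.01
    persistence_rho: float = 0.8
    immobile_prob: float = 0.03
    dropout_prob: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.step_sd <= 0:
            raise ValueError("step_sd must be positive")
        for name in ("immobile_prob", "dropout_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if not 0 <= self.persistence_rho <= 1:
            raise ValueError("persistence_rho must be in [0, 1]")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class GenotypeProfile:
    """Sensory capabilities of a genotype as channel masks."""

    name: str
    vision_mask: int = 1
    olfaction_mask: int = 1
    vision_noise_factor: float = 1.0  # >=1; scales latent-sociability spread

    def __post_init__(self):
        if self.vision_mask not in (0, 1) or self.olfaction_mask not in (0, 1):
            raise ValueError("masks must be 0 or 1")
        if self.vision_noise_factor < 1:
            raise ValueError("vision_noise_factor must be >= 1")


WILD_TYPE = GenotypeProfile("wild_type")
ANOSMIC = GenotypeProfile("anosmic", olfaction_mask=0)          # Orco-like
BLIND = GenotypeProfile("blind", vision_mask=0)                 # NorpA-like
LOW_ACUITY = GenotypeProfile("low_acuity", vision_noise_factor=1.8)  # w1118-like

GENOTYPES = {g.name: g for g in (WILD_TYPE, ANOSMIC, BLIND, LOW_ACUITY)}


def channel_gain(params: CouplingParams, barrier: BarrierSpec,
                 geno_a: GenotypeProfile, geno_b: GenotypeProfile) -> float:
    """Effective coupling gain through the open, unmasked sensory channels."""
    vision = params.w_vision * barrier.allows_vision * geno_a.vision_mask * geno_b.vision_mask
    olfaction = (params.w_olfaction * barrier.allows_olfaction
                 * geno_a.olfaction_mask * geno_b.olfaction_mask)
    return vision + olfaction


def _proximity_signal(dist: np.ndarray, scale: float = 3.0) -> np.ndarray:
    """Saturating signal of the partner's barrier distance.

    Logistic in distance with half-saturation at one body length (3 mm),
    so coupling is strongest exactly where coincidental approaches are
    scored.
    """
    return 1.0 / (1.0 + np.exp((dist - scale) / scale))


def _reflect_into_compartment(x, y, face_x, radius):
    """Reflect positions into the left-convention compartment {x <= face_x}.

    face_x is negative (left compartment of an origin-centred arena);
    mirror the inputs to reuse for the right side. A few reflection passes
    handle the common single-boundary crossings; a final projection
    guarantees containment.
    """
    for _ in range(3):
        over = x > face_x
        if over.any():
            x = np.where(over, 2.0 * face_x - x, x)
        rad = np.hypot(x, y)
        out = rad > radius
        if out.any():
            scale = np.where(out, (2.0 * radius - rad) / rad, 1.0)
            x = x * scale
            y = y * scale
    x = np.clip(x, -radius, face_x)
    ymax = np.sqrt(np.maximum(radius**2 - x**2, 0.0))
    y = np.clip(y, -ymax, ymax)
    return x, y


def _face_distance(x, y, face_x_abs, half_chord):
    """Distance to the barrier face for left-convention coordinates."""
    dy = np.maximum(np.abs(y) - half_chord, 0.0)
    return np.hypot(x + face_x_abs, dy)


def _init_positions(n, face_x_abs, radius, rng):
    """Uniform positions in the left-convention compartment."""
    x = np.empty(n)
    y = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        xs = rng.uniform(-radius, -face_x_abs, m)
        ys = rng.uniform(-radius, radius, m)
        good = xs * xs + ys * ys <= radius**2
        idx = np.flatnonzero(todo)[good]
        x[idx] = xs[good]
        y[idx] = ys[good]
        todo[idx] = False
    return x, y


def _simulate_walk_batch(kappas, n_frames, params: CouplingParams,
                         arena: ArenaSpec, rng,
                         immobile_a=None, immobile_b=None,
                         burn_in: int = 500):
    """Core coupled-random-walk integrator for a batch of dyads.

    kappas: per-dyad signed coupling drift (mm/frame at full signal).
    Returns (xa, ya, xb, yb) arrays of shape (n_frames, n_dyads) in
    left-convention coordinates for both flies (the right fly's true x is
    the negation). Immobile flies sit at their start with sub-threshold
    jitter.

    The first ``burn_in`` integration steps are discarded so the emitted
    frames start from the walk's stationary distribution; without this,
    the shared relaxation from the uniform start toward the
    barrier-attraction equilibrium would positively bias the index of
    even fully uncoupled dyads.
    """
    kappas = np.asarray(kappas, float)
    n = len(kappas)
    radius = arena.radius
    face = arena.barrier_thickness / 2.0
    half_chord = arena.half_chord
    base = params.barrier_attraction
    step = params.step_sd

    xa, ya = _init_positions(n, face, radius, rng)
    xb, yb = _init_positions(n, face, radius, rng)
    imm_a = np.zeros(n, bool) if immobile_a is None else np.asarray(immobile_a, bool)
    imm_b = np.zeros(n, bool) if immobile_b is None else np.asarray(immobile_b, bool)
    mobile_a = ~imm_a
    mobile_b = ~imm_b

    total = n_frames + burn_in
    noise = rng.normal(0.0, 1.0, size=(total, 4, n))
    jitter_sd = 5e-4  # mm/frame; keeps immobile flies below the speed threshold
    out = np.empty((total, 4, n))
    out[0] = (xa, ya, xb, yb)
    for t in range(1, total):
        da = _face_distance(xa, ya, face, half_chord)
        db = _face_distance(xb, yb, face, half_chord)
        # drift toward own face (+x in left convention) driven by partner signal
        drift_a = base + kappas * _proximity_signal(db)
        drift_b = base + kappas * _proximity_signal(da)
        sd_a = np.where(mobile_a, step, jitter_sd)
        sd_b = np.where(mobile_b, step, jitter_sd)
        xa = xa + np.where(mobile_a, drift_a, 0.0) + sd_a * noise[t, 0]
        ya = ya + sd_a * noise[t, 1]
        xb = xb + np.where(mobile_b, drift_b, 0.0) + sd_b * noise[t, 2]
        yb = yb + sd_b * noise[t, 3]
        xa, ya = _reflect_into_compartment(xa, ya, -face, radius)
        xb, yb = _reflect_into_compartment(xb, yb, -face, radius)
        out[t] = (xa, ya, xb, yb)
    out = out[burn_in:]
    return out[:, 0], out[:, 1], out[:, 2], out[:, 3]


def _make_trajectory(fly_id, day, session, arena_id, compartment,
                     x, y, dropout_mask, fps) -> Trajectory:
    n = len(x)
    valid = ~dropout_mask
    return Trajectory(
        fly_id=fly_id, day=day, session=session, arena_id=arena_id,
        compartment=compartment, frame=np.arange(n),
        x=np.where(valid, x, np.nan), y=np.where(valid, y, np.nan),
        valid=valid, fps=fps,
    )


def simulate_dyad(params: CouplingParams, barrier: BarrierSpec,
                  genotypes=(WILD_TYPE, WILD_TYPE),
                  arena: ArenaSpec | None = None,
                  n_frames: int = 10_000, fps: float = 29.9,
                  dyad_id: str = "dyad0", fly_ids=("flyA", "flyB"),
                  day: int = 1, session: int = 1) -> DyadRecord:
    """Simulate one dyad with fixed coupling sign * channel gain.

    Deterministic given params.seed. With all channels closed (e.g. a
    solid-black barrier) the flies' walks are independent.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    arena = arena or ArenaSpec()
    geno_a, geno_b = genotypes
    rng = np.random.default_rng(params.seed)
    kappa = params.sign * channel_gain(params, barrier, geno_a, geno_b)
    imm = rng.random(2) < params.immobile_prob
    xa, ya, xb, yb = _simulate_walk_batch(
        [kappa], n_frames, params, arena, rng,
        immobile_a=imm[:1], immobile_b=imm[1:])
    drop = rng.random((2, n_frames)) < params.dropout_prob
    left, right = arena.compartments
    traj_a = _make_trajectory(fly_ids[0], day, session, arena.arena_id, left,
                              xa[:, 0], ya[:, 0], drop[0], fps)
    traj_b = _make_trajectory(fly_ids[1], day, session, arena.arena_id, right,
                              -xb[:, 0], yb[:, 0], drop[1], fps)
    genotype = geno_a.name if geno_a.name == geno_b.name else f"{geno_a.name}x{geno_b.name}"
    return DyadRecord(dyad_id=dyad_id, fly_a=traj_a, fly_b=traj_b,
                      arena=arena, barrier=barrier, genotype=genotype)


def simulate_dyad_batch(n_dyads: int, params: CouplingParams, barrier: BarrierSpec,
                        genotype: GenotypeProfile = WILD_TYPE,
                        arena: ArenaSpec | None = None,
                        n_frames: int = 10_000, fps: float = 29.9,
                        coupling: str = "latent", seed: int | None = None):
    """Simulate a batch of independent same-genotype dyads.

    coupling="latent" draws each fly's sociability from a standard normal
    (scaled by the genotype's vision_noise_factor) and couples the dyad by
    the product of the two latent values times the channel gain, so both
    signs and a realistic spread of coupling strengths arise;
    coupling="fixed" uses sign * gain for every dyad. Returns a list of
    DyadRecords.
    """
    arena = arena or ArenaSpec()
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    gain = channel_gain(params, barrier, genotype, genotype)
    if coupling == "latent":
        lam = rng.normal(0.0, genotype.vision_noise_factor, size=(n_dyads, 2))
        kappas = gain * lam[:, 0] * lam[:, 1]
    elif coupling == "fixed":
        kappas = np.full(n_dyads, params.sign * gain)
    else:
        raise ValueError(f"unknown coupling mode {coupling!r}")
    imm = rng.random((2, n_dyads)) < params.immobile_prob
    xa, ya, xb, yb = _simulate_walk_batch(kappas, n_frames, params, arena, rng,
                                          immobile_a=imm[0], immobile_b=imm[1])
    drop = rng.random((2, n_dyads, n_frames)) < params.dropout_prob
    left, right = arena.compartments
    records = []
    for i in range(n_dyads):
        a = ArenaSpec(arena_id=f"a{i}", center=arena.center,
                      diameter=arena.diameter,
                      barrier_thickness=arena.barrier_thickness)
        ta = _make_trajectory(f"d{i}_left", 1, 1, a.arena_id, left,
                              xa[:, i], ya[:, i], drop[0, i], fps)
        tb = _make_trajectory(f"d{i}_right", 1, 1, a.arena_id, right,
                              -xb[:, i], yb[:, i], drop[1, i], fps)
        records.append(DyadRecord(dyad_id=f"dyad{i}", fly_a=ta, fly_b=tb,
                                  arena=a, barrier=barrier, genotype=genotype.name))
    return records


# ---------------------------------------------------------------------------
# Whole-experiment generator
# ---------------------------------------------------------------------------

@dataclass
class ExperimentData:
    """A complete synthetic experiment: trajectories plus design tables."""

    trajectories: list
    design: pd.DataFrame
    arena: ArenaSpec
    barrier: BarrierSpec
    genotypes: dict
    manifest: dict

    def dyad_records(self) -> list[DyadRecord]:
        """Pair the per-session trajectories back into DyadRecords."""
        by_key = {}
        for t in self.trajectories:
            by_key.setdefault((t.day, t.session, t.arena_id), []).append(t)
        records = []
        design_idx = self.design.set_index(
            ["day", "session", "arena_id", "fly_id"])["dyad_id"]
        left_label = self.arena.compartments[0]
        for (day, session, arena_id), pair in sorted(by_key.items()):
            if len(pair) != 2:
                raise ValueError(f"arena {arena_id} day {day} session {session}: "
                                 f"expected 2 flies, found {len(pair)}")
            a, b = sorted(pair, key=lambda t: t.compartment != left_label)
            dyad_id = str(design_idx.loc[(day, session, arena_id, a.fly_id)])
            arena = ArenaSpec(arena_id=arena_id, diameter=self.arena.diameter,
                              barrier_thickness=self.arena.barrier_thickness)
            geno_a = self.genotypes[a.fly_id].name
            geno_b = self.genotypes[b.fly_id].name
            genotype = geno_a if geno_a == geno_b else f"{geno_a}x{geno_b}"
            records.append(DyadRecord(dyad_id=dyad_id, fly_a=a, fly_b=b,
                                      arena=arena, barrier=self.barrier,
                                      genotype=genotype))
        return records

    def write(self, out_dir):
        """Emit trajectory CSVs (one per day), the design CSV, and a manifest."""
        from pathlib import Path

        from .trajectory import write_trajectories

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for day in sorted({t.day for t in self.trajectories}):
            day_trajs = [t for t in self.trajectories if t.day == day]
            write_trajectories(day_trajs, out / f"trajectories_day{day}.csv")
        self.design.to_csv(out / "design.csv", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)


def _session_dyad_schedule(scheme: DyadScheme, days: int, sessions_per_day: int):
    """Assign dyads to (day, session) slots so no fly appears twice per session."""
    dyads = enumerate_dyads(scheme)
    if scheme.scheme == "scheme1_disjoint":
        per_slot = [list(dyads)]
    elif scheme.scheme == "scheme3_saturated":
        per_slot = schedule_rounds(dyads, scheme.n_flies, repeats=1)
    else:  # scheme 2: cover the k-regular graph by greedy maximal matchings
        per_slot = _matching_cover(dyads)
    slots = []
    i = 0
    for day in range(1, days + 1):
        for session in range(1, sessions_per_day + 1):
            slots.append((day, session, per_slot[i % len(per_slot)]))
            i += 1
    return dyads, slots


def _matching_cover(edges):
    """Greedy cover of an edge set by maximal matchings (one sweep)."""
    remaining = list(edges)
    rounds = []
    while remaining:
        used = set()
        rnd = []
        rest = []
        for a, b in remaining:
            if a not in used and b not in used:
                rnd.append((a, b))
                used.update((a, b))
            else:
                rest.append((a, b))
        rounds.append(rnd)
        remaining = rest
    return rounds


def simulate_experiment(n_flies: int, scheme: DyadScheme, days: int = 2,
                        sessions_per_day: int = 1,
                        params: CouplingParams | None = None,
                        barrier: BarrierSpec | None = None,
                        genotype: GenotypeProfile = WILD_TYPE,
                        arena: ArenaSpec | None = None,
                        n_frames: int = 10_000, fps: float = 29.9) -> ExperimentData:
    """Simulate a multi-day dyad experiment end to end.

    Each fly draws a latent sociability once (scaled by its genotype's
    vision_noise_factor) that evolves across days as a stationary AR(1)
    with parameter ``params.persistence_rho``; each measured dyad's
    coupling on a given day is the channel gain times the product of its
    members' latent values that day. Sessions within a day share the
    day's latents.
    """
    params = params or CouplingParams()
    barrier = barrier or BarrierSpec.from_type("open_clear")
    arena = arena or ArenaSpec()
    if scheme.n_flies != n_flies:
        raise InfeasibleDesignError("scheme.n_flies must match n_flies")
    rng = np.random.default_rng(params.seed)
    gain = channel_gain(params, barrier, genotype, genotype)

    # latent sociability per fly per day: stationary AR(1)
    rho = params.persistence_rho
    lam = np.empty((days, n_flies))
    lam[0] = rng.normal(0.0, 1.0, n_flies)
    for d in range(1, days):
        lam[d] = rho * lam[d - 1] + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, n_flies)
    lam *= genotype.vision_noise_factor

    dyads, slots = _session_dyad_schedule(scheme, days, sessions_per_day)
    dyad_ids = {tuple(sorted(d)): f"dyad_{d[0]}_{d[1]}" for d in dyads}
    left, right = arena.compartments

    trajectories = []
    design_rows = []
    for day, session, slot_dyads in slots:
        if not slot_dyads:
            continue
        kappas = np.array([gain * lam[day - 1, a] * lam[day - 1, b]
                           for a, b in slot_dyads])
        n = len(slot_dyads)
        imm = rng.random((2, n)) < params.immobile_prob
        xa, ya, xb, yb = _simulate_walk_batch(kappas, n_frames, params, arena, rng,
                                              immobile_a=imm[0], immobile_b=imm[1])
        drop = rng.random((2, n, n_frames)) < params.dropout_prob
        for i, (fa, fb) in enumerate(slot_dyads):
            arena_id = f"a{i}"
            ta = _make_trajectory(f"fly{fa}", day, session, arena_id, left,
                                  xa[:, i], ya[:, i], drop[0, i], fps)
            tb = _make_trajectory(f"fly{fb}", day, session, arena_id, right,
                                  -xb[:, i], yb[:, i], drop[1, i], fps)
            trajectories.extend([ta, tb])
            did = dyad_ids[tuple(sorted((fa, fb)))]
            for fly, comp in ((fa, left), (fb, right)):
                design_rows.append({
                    "day": day, "session": session, "round": session,
                    "arena_id": arena_id, "compartment": comp,
                    "fly_id": f"fly{fly}", "dyad_id": did,
                    "barrier_type": barrier.barrier_type,
                    "genotype": genotype.name,
                })

    manifest = {
        "n_flies": n_flies, "scheme": scheme.scheme, "k": scheme.k,
        "days": days, "sessions_per_day": sessions_per_day,
        "n_frames": n_frames, "fps": fps,
        "barrier_type": barrier.barrier_type, "genotype": genotype.name,
        "params": {k: (float(v) if isinstance(v, (int, float)) else v)
                   for k, v in vars(params).items()},
    }
    genotypes = {t.fly_id: genotype for t in trajectories}
    return ExperimentData(trajectories=trajectories,
                          design=pd.DataFrame(design_rows),
                          arena=arena, barrier=barrier,
                          genotypes=genotypes, manifest=manifest)


def load_experiment(run_dir, fps: float = 29.9) -> ExperimentData:
    """Read back a run directory written by ExperimentData.write."""
    from pathlib import Path

    from .trajectory import AnalysisConfig, read_trajectories

    run_dir = Path(run_dir)
    design = pd.read_csv(run_dir / "design.csv")
    manifest_path = run_dir / "manifest.yaml"
    manifest = yaml.safe_load(manifest_path.read_text()) if manifest_path.exists() else {}
    fps = float(manifest.get("fps", fps))
    barrier = BarrierSpec.from_type(
        manifest.get("barrier_type", str(design["barrier_type"].iloc[0])))
    cfg = AnalysisConfig(fps=fps)
    trajectories = []
    for f in sorted(run_dir.glob("trajectories_day*.csv")):
        trajectories.extend(read_trajectories(f, cfg))
    geno_names = design.drop_duplicates("fly_id").set_index("fly_id")["genotype"]
    genotypes = {str(fid): GENOTYPES.get(str(g), GenotypeProfile(str(g)))
                 for fid, g in geno_names.items()}
    return ExperimentData(trajectories=trajectories, design=design,
                          arena=ArenaSpec(), barrier=barrier,
                          genotypes=genotypes, manifest=manifest)


# ---------------------------------------------------------------------------
# Calibration and small fixtures
# ---------------------------------------------------------------------------

def calibrate_channel_weights(target_ratio: float = 0.35,
                              n_dyads: int = 100, n_frames: int = 6000,
                              seed: int = 0,
                              grid=None) -> CouplingParams:
    """Coarse grid search for channel weights.

    Searches (w_vision, w_olfaction) so that the mean |index| of anosmic
    dyads behind open-clear barriers is close to ``target_ratio`` times
    the wild-type open-clear mean, mirroring the strong reduction seen in
    olfactory mutants while keeping open-clear the strongest condition.
    The shipped defaults W_VISION_DEFAULT / W_OLFACTION_DEFAULT were
    produced by this routine and are not recomputed at import time.
    """
    from .metrics import dyad_metrics

    if grid is None:
        grid = [(wv, wo) for wv in (0.01, 0.015, 0.02) for wo in (0.15, 0.20, 0.25)]
    barrier = BarrierSpec.from_type("open_clear")

    def mean_abs(params, genotype, s):
        recs = simulate_dyad_batch(n_dyads, params, barrier, genotype=genotype,
                                   n_frames=n_frames, seed=s)
        vals = [row.interactivity_index for row in map(dyad_metrics, recs)
                if not row.excluded]
        return float(np.mean(np.abs(vals)))

    best, best_err = None, np.inf
    for i, (wv, wo) in enumerate(grid):
        p = CouplingParams(w_vision=wv, w_olfaction=wo, seed=seed)
        ratio = mean_abs(p, ANOSMIC, seed + 2 * i + 1) / mean_abs(p, WILD_TYPE, seed + 2 * i)
        err = abs(ratio - target_ratio)
        if err < best_err:
            best, best_err = p, err
    return best


def simulate_turns(bias_p: float, n_turns: int, seed: int = 0,
                   fly_id: str = "fly0") -> TurnSequence:
    """I.i.d. Bernoulli turn sequence with P(R) = bias_p."""
    if not 0 <= bias_p <= 1:
        raise ValueError("bias_p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    turns = ["R" if r else "L" for r in rng.random(n_turns) < bias_p]
    return TurnSequence(fly_id=fly_id, turns=turns)


def simulate_speed_population(mixture=None, n: int = 100, seed: int = 0) -> np.ndarray:
    """Fly mean-speed population as a truncated-normal mixture (mm/s).

    mixture: list of (weight, mean, sd) components; defaults to 97%
    active walkers around 8 mm/s plus 3% immobile flies near zero,
    matching the discard fraction reported for the real assay.
    """
    mixture = mixture or [(0.97, 8.0, 3.0), (0.03, 0.02, 0.01)]
    weights = np.array([w for w, _, _ in mixture], float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(mixture), size=n, p=weights)
    means = np.array([m for _, m, _ in mixture])[comp]
    sds = np.array([s for _, _, s in mixture])[comp]
    return np.abs(rng.normal(means, sds))
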