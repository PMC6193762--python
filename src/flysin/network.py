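"""Social interaction network (SIN) construction and day-to-day persistence.

A SIN is a graph over flies whose edges are the dyads with absolute
interactivity index above a population-derived threshold: the mean of the
first and third quartiles of all dyads' |index| values. Day-to-day
persistence of dyadic affiliation is quantified by the Pearson
correlation of per-dyad indices across successive days, tested with the
Fisher z-transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PersistenceResult:
    """Cross-day correlation of dyad indices with its Fisher z-test."""

    day_i: int
    day_j: int
    r: float
    n_dyads: int
    z: float
    p: float


def day_persistence(table: pd.DataFrame, day_i: int, day_j: int,
                    value_col: str = "interactivity_index",
                    use_absolute: bool = False) -> PersistenceResult:
    """Pearson correlation of per-dyad indices between two days.

    Only dyads measured on both days enter (the identity-matched
    intersection); with multiple sessions per day the per-dyad day mean is
    used. The test statistic is z = atanh(r) * sqrt(n - 3), two-tailed
    against the standard normal. By default the signed indices are
    correlated; ``use_absolute=True`` correlates |index| instead.
    """
    df = table.copy()
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    df = df.dropna(subset=[value_col])
    if use_absolute:
        df[value_col] = df[value_col].abs()
    per_day = df.groupby(["dyad_id", "day"])[value_col].mean().unstack("day")
    if day_i not in per_day.columns or day_j not in per_day.columns:
        raise ValueError(f"days {day_i}, {day_j} not both present in table")
    paired = per_day[[day_i, day_j]].dropna()
    n = len(paired)
    if n < 3:
        raise ValueError(f"only {n} dyads measured on both days (need >= 3)")
    r = float(stats.pearsonr(paired[day_i], paired[day_j]).statistic)
    z, p = fisher_z_test(r, n)
    return PersistenceResult(day_i=day_i, day_j=day_j, r=r, n_dyads=n, z=z, p=p)


def fisher_z_test(r: float, n: int) -> tuple[float, float]:
    """Fisher-transform z statistic for a correlation and its two-tailed p."""
    if not -1 < r < 1:
        z = np.inf if abs(r) >= 1 else np.nan
        return float(np.sign(r) * z), 0.0
    z = float(np.arctanh(r) * np.sqrt(n - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


def aggregate_sessions(table: pd.DataFrame, window: int = 2,
                       value_col: str = "interactivity_index") -> pd.DataFrame:
    """Per-dyad means over the first and last `window` phenotyping sessions.

    Sessions are ordered chronologically by (day, session). Dyads with
    fewer than `window` measurements in either window are excluded with a
    warning. Returns a DataFrame indexed by dyad_id with columns
    ``early`` and ``late``.
    """
    df = table.copy()
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    df = df.dropna(subset=[value_col]).sort_values(["day", "session"])
    out = {}
    dropped = []
    for dyad, grp in df.groupby("dyad_id"):
        vals = grp[value_col].to_numpy()
        if len(vals) < 2 * window:
            dropped.append(dyad)
            continue
        out[dyad] = {"early": float(vals[:window].mean()),
                     "late": float(vals[-window:].mean())}
    if dropped:
        warnings.warn(f"{len(dropped)} dyad(s) with <{2 * window} sessions excluded")
    res = pd.DataFrame.from_dict(out, orient="index")
    res.index.name = "dyad_id"
    return res


def sin_threshold(indices) -> float:
    """SIN connection threshold: mean of Q1 and Q3 of the |index| population.

    Quartiles use linear interpolation between order statistics (the
    common "type 7" convention).
    """
    a = np.abs(np.asarray(indices, float))
    a = a[np.isfinite(a)]
    if len(a) < 4:
        raise ValueError("need at least 4 dyad indices to set a threshold")
    q1, q3 = np.percentile(a, [25, 75])
    return float((q1 + q3) / 2.0)


def build_sin(indices: dict, threshold: float, nodes=None, day: int | None = None,
              threshold_rule: str = "mean(Q1,Q3) of |index|, strict >") -> nx.Graph:
    """Threshold per-dyad indices into a social interaction network.

    ``indices`` maps fly-id pairs to interactivity indices. An edge is kept
    iff |index| > threshold (strict); the node set includes all measured
    flies (isolates kept), plus any extra ``nodes``. The threshold, rule,
    and day are recorded as graph attributes so a day-1 threshold applied
    to day 2 is traceable.
    """
    g = nx.Graph(threshold=float(threshold), threshold_rule=threshold_rule, day=day)
    for pair in indices:
        g.add_nodes_from(pair)
    if nodes is not None:
        g.add_nodes_from(nodes)
    for (a, b), idx in indices.items():
        if a == b:
            raise ValueError("self-pairings are not valid dyads")
        if np.isfinite(idx) and abs(idx) > threshold:
            g.add_edge(a, b, interactivity_index=float(idx))
    return g


def sin_for_day(table: pd.DataFrame, day: int, threshold: float | None = None) -> nx.Graph:
    """Build the SIN for one day from the metric table.

    When ``threshold`` is None it is derived from that day's |index|
    population; passing a previous day's threshold reproduces the
    identical-threshold comparison across days.
    """
    df = table.loc[table["day"] == day]
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    per_dyad = df.groupby(["fly_a", "fly_b"])["interactivity_index"].mean()
    indices = {tuple(sorted(k)): float(v) for k, v in per_dyad.items()}
    rule = "mean(Q1,Q3) of |index|, strict >"
    if threshold is None:
        threshold = sin_threshold(list(indices.values()))
    else:
        rule += " (threshold carried over)"
    return build_sin(indices, threshold, day=day, threshold_rule=rule)


def sin_overlap(g1: nx.Graph, g2: nx.Graph) -> tuple[int, float]:
    """Shared-edge count and Jaccard index of two SINs on the same flies.

    Jaccard is reported as 1.0 when both edge sets are empty (degenerate,
    noted here rather than raised).
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("SINs must share the same node universe")
    e1 = {frozenset(e) for e in g1.edges}
    e2 = {frozenset(e) for e in g2.edges}
    shared = len(e1 & e2)
    union = len(e1 | e2)
    jaccard = 1.0 if union == 0 else shared / union
    return shared, jaccard


def write_graphml(g: nx.Graph, path):
    """GraphML export (graph attributes stringified for portability)."""
    h = g.copy()
    for k, v in list(h.graph.items()):
        if v is None:
            h.graph[k] = ""
    nx.write_graphml(h, path)


def edges_to_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [{"fly_a": a, "fly_b": b, **attrs} for a, b, attrs in g.edges(data=True)]
    return pd.DataFrame(rows)
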