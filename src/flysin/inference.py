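"""Null models, resampling, and hypothesis tests for dyadic statistics.

The central null model re-pairs simultaneously recorded flies into
fictive dyads ("shuffled dyads") and recomputes the interactivity index
on the genuinely time-aligned distance series of those fictive pairs.
Because the index is a temporal correlation, only flies recorded in the
same session may be shuffled together, and all true pairings are
excluded from the null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import UndefinedMetricError
from .metrics import DyadRecord, barrier_distances, interactivity_index
from .trajectory import AnalysisConfig


@dataclass
class NullDistribution:
    """Pooled interactivity indices of fictive (shuffled) dyads."""

    values: np.ndarray
    n_perm: int
    construction: str  # side_free | side_preserving
    seed: int
    fictive_pairs: list = field(default_factory=list)  # (fly_key, fly_key) per value

    def __post_init__(self):
        self.values = np.asarray(self.values, float)


def available_fictive_pairs(dyads: list[DyadRecord]):
    """All cross-pairings of the session's flies that are not true dyads."""
    flies = []
    true_pairs = set()
    for d in dyads:
        ka, kb = d.fly_a.fly_id, d.fly_b.fly_id
        flies.extend([ka, kb])
        true_pairs.add(frozenset((ka, kb)))
    return [tuple(sorted(p)) for p in itertools.combinations(sorted(set(flies)), 2)
            if frozenset(p) not in true_pairs]


def shuffled_null(dyads: list[DyadRecord], n_perm: int, seed: int,
                  mode: str = "side_free",
                  config: AnalysisConfig | None = None) -> NullDistribution:
    """Shuffled-dyad null distribution of the interactivity index.

    For each of ``n_perm`` permutations the session's flies are re-paired
    into a perfect matching containing no true dyad, and the index of each
    fictive pair is computed on the time-aligned distance series. With
    ``mode="side_preserving"`` left-compartment flies are only re-paired
    with right-compartment flies of other arenas; ``"side_free"`` allows
    any cross-pairing.
    """
    if len(dyads) < 2:
        raise ValueError("need at least 2 dyads recorded in the same session")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("side_free", "side_preserving"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    sessions = {(d.day, d.session) for d in dyads}
    if len(sessions) != 1:
        raise ValueError("shuffled pairing requires dyads from a single session")

    config = config or AnalysisConfig()
    series = {}
    partner = {}
    lefts, rights = [], []
    for d in dyads:
        for t, side_list in ((d.fly_a, lefts), (d.fly_b, rights)):
            series[t.fly_id] = barrier_distances(t, d.arena, config.use_imputed)
            side_list.append(t.fly_id)
        partner[d.fly_a.fly_id] = d.fly_b.fly_id
        partner[d.fly_b.fly_id] = d.fly_a.fly_id

    rng = np.random.default_rng(seed)
    values, pairs_out = [], []
    for _ in range(n_perm):
        pairs = (_matching_side_preserving(lefts, rights, partner, rng)
                 if mode == "side_preserving"
                 else _matching_side_free(lefts + rights, partner, rng))
        for fa, fb in pairs:
            try:
                r, _ = interactivity_index(series[fa], series[fb])
            except UndefinedMetricError:
                continue
            values.append(r)
            pairs_out.append((fa, fb))
    return NullDistribution(values=np.array(values), n_perm=n_perm,
                            construction=mode, seed=seed, fictive_pairs=pairs_out)


def _matching_side_preserving(lefts, rights, partner, rng, max_tries=1000):
    for _ in range(max_tries):
        perm = rng.permutation(len(rights))
        if all(rights[perm[i]] != partner[lefts[i]] for i in range(len(lefts))):
            return [(lefts[i], rights[perm[i]]) for i in range(len(lefts))]
    raise RuntimeError("could not find a partner-free permutation")


def _matching_side_free(flies, partner, rng, max_tries=1000):
    flies = list(flies)
    for _ in range(max_tries):
        order = rng.permutation(len(flies))
        pairs = [(flies[order[2 * i]], flies[order[2 * i + 1]])
                 for i in range(len(flies) // 2)]
        if all(partner[a] != b for a, b in pairs):
            return pairs
    raise RuntimeError("could not find a partner-free matching")


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute ECDF difference; the p-value comes from the
    asymptotic Kolmogorov distribution with effective sample size
    n_x n_y / (n_x + n_y). Suitable for the sample sizes in scope (tens of
    dyads and up); not exact for very small samples.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def bootstrap_se(values, statistic=np.mean, n_boot: int = 1000, seed: int = 0) -> float:
    """Bootstrap standard error of a statistic.

    Resamples with replacement at the original size ``n_boot`` times; the
    SE estimate is the standard deviation (n_boot - 1 denominator) of the
    resampled statistics.
    """
    values = np.asarray(values, float)
    n = len(values)
    if n < 2 or n_boot < 2:
        raise ValueError("need n >= 2 values and n_boot >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.array([statistic(values[row]) for row in idx])
    return float(np.std(boots, ddof=1))


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values: p * m clipped at 1."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


@dataclass
class GroupSummary:
    """Mean absolute interactivity index of one barrier x genotype group."""

    group: tuple
    mean_abs_index: float
    se: float
    n_dyads: int


def group_contrast(table: pd.DataFrame, group_cols=("barrier_type", "genotype"),
                   config: AnalysisConfig | None = None):
    """Group means of |interactivity index| with bootstrap SEs and Welch t-tests.

    Excluded rows are dropped. Groups with fewer than 2 dyads are excluded
    with a warning. All pairwise group contrasts are tested with Welch's
    unequal-variance t-test on |index| and Bonferroni-adjusted. Returns
    (summaries, tests) where tests is a DataFrame with one row per pair.
    """
    config = config or AnalysisConfig()
    group_cols = list(group_cols)
    df = table.copy()
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    df = df.dropna(subset=["interactivity_index"])
    df["_abs"] = df["interactivity_index"].abs()

    summaries = []
    samples = {}
    for i, (key, grp) in enumerate(df.groupby(group_cols, sort=True)):
        key = key if isinstance(key, tuple) else (key,)
        if len(grp) < 2:
            warnings.warn(f"group {key} has <2 dyads; excluded from contrasts")
            continue
        vals = grp["_abs"].to_numpy()
        se = bootstrap_se(vals, np.mean, config.n_boot, seed=config.rng_seed + i)
        summaries.append(GroupSummary(group=key, mean_abs_index=float(vals.mean()),
                                      se=se, n_dyads=len(vals)))
        samples[key] = vals

    rows = []
    for (k1, v1), (k2, v2) in itertools.combinations(samples.items(), 2):
        t, p = stats.ttest_ind(v1, v2, equal_var=False)
        rows.append({"group_1": k1, "group_2": k2, "t": float(t), "p": float(p)})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_bonferroni"] = bonferroni(tests["p"].to_numpy())
        tests["significant"] = tests["p_bonferroni"] < config.alpha
    return summaries, tests
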