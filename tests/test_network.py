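"""SIN thresholding, persistence statistics, and network comparison."""

import numpy as np
import pandas as pd
import pytest

from flysin import (aggregate_sessions, build_sin, day_persistence,
                    fisher_z_test, sin_for_day, sin_overlap, sin_threshold)


def _table(day_vals):
    """day -> {dyad_id: index} into a metric table."""
    rows = []
    for day, vals in day_vals.items():
        for dyad, v in vals.items():
            a, b = dyad.split("-")
            rows.append({"dyad_id": dyad, "fly_a": a, "fly_b": b, "day": day,
                         "session": 1, "interactivity_index": v, "excluded": False})
    return pd.DataFrame(rows)


class TestDayPersistence:
    def test_identical_vectors_r_one(self):
        vals = {f"a{i}-b{i}": v for i, v in enumerate([0.1, 0.5, -0.2, 0.3])}
        res = day_persistence(_table({1: vals, 2: vals}), 1, 2)
        assert res.r == pytest.approx(1.0)
        assert res.n_dyads == 4

    def test_fisher_z_closed_form(self):
        # r = 0.5, n = 30: z = atanh(0.5) * sqrt(27) ~ 2.854, p ~ 0.0043
        z, p = fisher_z_test(0.5, 30)
        assert z == pytest.approx(np.arctanh(0.5) * np.sqrt(27))
        assert z == pytest.approx(2.854, abs=0.001)
        assert p == pytest.approx(0.00432, abs=0.0002)

    def test_zero_correlation_z_zero_p_one(self):
        z, p = fisher_z_test(0.0, 25)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_unmatched_dyads_use_intersection(self):
        d1 = {"a-b": 0.1, "c-d": 0.2, "e-f": 0.3, "g-h": 0.4}
        d2 = {"a-b": 0.1, "c-d": 0.2, "e-f": 0.3, "x-y": 0.9}
        res = day_persistence(_table({1: d1, 2: d2}), 1, 2)
        assert res.n_dyads == 3

    def test_too_few_matched_dyads_errors(self):
        d = {"a-b": 0.1, "c-d": 0.2}
        with pytest.raises(ValueError, match="need >= 3"):
            day_persistence(_table({1: d, 2: d}), 1, 2)


class TestAggregateSessions:
    def _multi_session(self, dyad_sessions):
        rows = []
        for dyad, vals in dyad_sessions.items():
            for s, v in enumerate(vals, start=1):
                rows.append({"dyad_id": dyad, "day": 1, "session": s,
                             "interactivity_index": v, "excluded": False})
        return pd.DataFrame(rows)

    def test_first_and_last_two_sessions_averaged(self):
        table = self._multi_session({"d0": [0.2, 0.4, 0.1, 0.3]})
        res = aggregate_sessions(table, window=2)
        assert res.loc["d0", "early"] == pytest.approx(0.3)
        assert res.loc["d0", "late"] == pytest.approx(0.2)

    def test_dyad_with_too_few_sessions_excluded(self):
        table = self._multi_session({"d0": [0.2, 0.4, 0.1, 0.3], "d1": [0.5]})
        with pytest.warns(UserWarning):
            res = aggregate_sessions(table, window=2)
        assert list(res.index) == ["d0"]

    def test_window_order_invariance(self):
        t1 = self._multi_session({"d0": [0.2, 0.4, 0.1, 0.3]})
        t2 = self._multi_session({"d0": [0.4, 0.2, 0.3, 0.1]})
        r1 = aggregate_sessions(t1)
        r2 = aggregate_sessions(t2)
        assert r1.loc["d0", "early"] == pytest.approx(r2.loc["d0", "early"])


class TestSinThreshold:
    def test_quartile_midpoint_linear_interpolation(self):
        # |indices| = [0.1, 0.2, 0.3, 0.4]: Q1=0.175, Q3=0.325 -> 0.25
        assert sin_threshold([0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.25)

    def test_uses_absolute_values(self):
        assert sin_threshold([-0.1, 0.2, -0.3, 0.4]) == pytest.approx(0.25)

    def test_all_equal_threshold_equals_value(self):
        assert sin_threshold([0.2, 0.2, 0.2, 0.2]) == pytest.approx(0.2)

    def test_scaling_homogeneity(self):
        vals = [0.05, 0.12, 0.31, 0.44, 0.27]
        assert sin_threshold([3 * v for v in vals]) == pytest.approx(3 * sin_threshold(vals))

    def test_too_few_dyads_errors(self):
        with pytest.raises(ValueError):
            sin_threshold([0.1, 0.2, 0.3])


class TestBuildSin:
    IDX = {("a", "b"): 0.1, ("b", "c"): -0.2, ("c", "d"): 0.3, ("a", "d"): 0.4}

    def test_strict_threshold_edge_count(self):
        g = build_sin(self.IDX, threshold=0.25)
        assert g.number_of_edges() == 2  # 0.3 and 0.4
        assert set(g.nodes) == {"a", "b", "c", "d"}

    def test_threshold_above_max_gives_isolates(self):
        g = build_sin(self.IDX, threshold=0.5)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 4

    def test_threshold_below_min_gives_complete_measured_graph(self):
        g = build_sin(self.IDX, threshold=0.05)
        assert g.number_of_edges() == len(self.IDX)

    def test_equal_indices_yield_no_edges_under_strict_rule(self):
        idx = {("a", "b"): 0.2, ("c", "d"): 0.2}
        assert build_sin(idx, threshold=0.2).number_of_edges() == 0

    def test_edge_attributes_and_metadata(self):
        g = build_sin(self.IDX, threshold=0.25, day=1)
        assert g.edges[("a", "d")]["interactivity_index"] == pytest.approx(0.4)
        assert g.graph["threshold"] == pytest.approx(0.25)
        assert g.graph["day"] == 1


class TestSinOverlap:
    def test_identical_graphs_jaccard_one(self):
        g = build_sin(TestBuildSin.IDX, 0.25)
        assert sin_overlap(g, g) == (2, 1.0)

    def test_disjoint_edge_sets_jaccard_zero(self):
        g1 = build_sin({("a", "b"): 0.9, ("c", "d"): 0.0}, 0.5)
        g2 = build_sin({("a", "b"): 0.0, ("c", "d"): 0.9}, 0.5)
        shared, jacc = sin_overlap(g1, g2)
        assert shared == 0 and jacc == 0.0

    def test_partial_overlap(self):
        g1 = build_sin({("a", "b"): 0.9, ("b", "c"): 0.9, ("c", "d"): 0.0}, 0.5)
        g2 = build_sin({("a", "b"): 0.0, ("b", "c"): 0.9, ("c", "d"): 0.9}, 0.5)
        shared, jacc = sin_overlap(g1, g2)
        assert shared == 1 and jacc == pytest.approx(1 / 3)

    def test_empty_graphs_degenerate_jaccard(self):
        g1 = build_sin({("a", "b"): 0.0}, 0.5)
        g2 = build_sin({("a", "b"): 0.1}, 0.5)
        assert sin_overlap(g1, g2) == (0, 1.0)

    def test_node_mismatch_errors(self):
        g1 = build_sin({("a", "b"): 0.9}, 0.5)
        g2 = build_sin({("a", "c"): 0.9}, 0.5)
        with pytest.raises(ValueError):
            sin_overlap(g1, g2)


class TestSinForDay:
    def test_day1_threshold_carried_to_day2(self):
        rng = np.random.default_rng(8)
        d1 = {f"f{i}-g{i}": v for i, v in enumerate(rng.normal(0, 0.3, 20))}
        d2 = {k: v + rng.normal(0, 0.05) for k, v in d1.items()}
        table = _table({1: d1, 2: d2})
        g1 = sin_for_day(table, 1)
        g2 = sin_for_day(table, 2, threshold=g1.graph["threshold"])
        assert g2.graph["threshold"] == g1.graph["threshold"]
        assert "carried over" in g2.graph["threshold_rule"]

    def test_edge_fraction_between_quartiles(self):
        # threshold sits between Q1 and Q3 of |index|, so for continuous
        # data the edge fraction lies in [0.25, 0.75]
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 0.3, 41)
        thr = sin_threshold(vals)
        frac = np.mean(np.abs(vals) > thr)
        assert 0.25 <= frac <= 0.75
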