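"""Properties of the synthetic trajectory and experiment generators."""

import numpy as np
import pytest

from flysin import (BarrierSpec, CouplingParams, DyadScheme,
                    channel_gain, dyad_metrics, metric_table, simulate_dyad,
                    simulate_dyad_batch, simulate_experiment,
                    simulate_speed_population, simulate_turns, turning_bias,
                    ANOSMIC, BLIND, WILD_TYPE)


class TestChannelGain:
    def test_solid_black_closes_both_channels(self):
        p = CouplingParams()
        assert channel_gain(p, BarrierSpec.from_type("solid_black"),
                            WILD_TYPE, WILD_TYPE) == 0.0

    def test_genotype_masks_gate_channels(self):
        p = CouplingParams(w_vision=0.1, w_olfaction=0.2)
        open_clear = BarrierSpec.from_type("open_clear")
        assert channel_gain(p, open_clear, WILD_TYPE, WILD_TYPE) == pytest.approx(0.3)
        assert channel_gain(p, open_clear, ANOSMIC, WILD_TYPE) == pytest.approx(0.1)
        assert channel_gain(p, open_clear, BLIND, BLIND) == pytest.approx(0.2)

    def test_barrier_ordering_open_clear_geq_open_black(self):
        p = CouplingParams()
        oc = channel_gain(p, BarrierSpec.from_type("open_clear"), WILD_TYPE, WILD_TYPE)
        ob = channel_gain(p, BarrierSpec.from_type("open_black"), WILD_TYPE, WILD_TYPE)
        assert oc >= ob > 0


class TestSimulateDyad:
    def test_same_seed_bitwise_identical(self):
        p = CouplingParams(seed=123)
        b = BarrierSpec.from_type("open_clear")
        d1 = simulate_dyad(p, b, n_frames=400)
        d2 = simulate_dyad(p, b, n_frames=400)
        assert np.array_equal(d1.fly_a.x, d2.fly_a.x, equal_nan=True)
        assert np.array_equal(d1.fly_b.y, d2.fly_b.y, equal_nan=True)
        assert np.array_equal(d1.fly_a.valid, d2.fly_a.valid)

    def test_flies_confined_to_their_compartments(self, arena):
        p = CouplingParams(seed=5, dropout_prob=0.0)
        d = simulate_dyad(p, BarrierSpec.from_type("open_clear"), n_frames=2000)
        half_t = arena.barrier_thickness / 2.0
        r = arena.radius + 1e-9
        assert np.all(d.fly_a.x <= -half_t + 1e-9)
        assert np.all(d.fly_b.x >= half_t - 1e-9)
        assert np.all(np.hypot(d.fly_a.x, d.fly_a.y) <= r)
        assert np.all(np.hypot(d.fly_b.x, d.fly_b.y) <= r)

    def test_dropout_frames_marked_invalid(self):
        p = CouplingParams(seed=2, dropout_prob=0.2, immobile_prob=0.0)
        d = simulate_dyad(p, BarrierSpec.from_type("open_clear"), n_frames=2000)
        frac = 1.0 - d.fly_a.n_valid / len(d.fly_a)
        assert 0.1 < frac < 0.3
        assert np.isnan(d.fly_a.x[~d.fly_a.valid]).all()

    def test_uncoupled_batch_index_near_zero(self):
        p = CouplingParams(seed=31, immobile_prob=0.0, dropout_prob=0.0)
        recs = simulate_dyad_batch(60, p, BarrierSpec.from_type("solid_black"),
                                   n_frames=3000, seed=31)
        vals = np.array([r.interactivity_index for r in map(dyad_metrics, recs)])
        assert abs(vals.mean()) < 0.06  # null band at this batch size

    def test_coupled_exceeds_uncoupled_mean_index(self):
        # moderate fixed positive coupling shifts the signed index well above
        # the (zero-mean) uncoupled level
        p = CouplingParams(w_vision=0.004, w_olfaction=0.05, seed=17,
                           immobile_prob=0.0, dropout_prob=0.0)
        coupled = simulate_dyad_batch(40, p, BarrierSpec.from_type("open_clear"),
                                      n_frames=3000, coupling="fixed", seed=17)
        null = simulate_dyad_batch(40, p, BarrierSpec.from_type("solid_black"),
                                   n_frames=3000, seed=18)
        mc = np.mean([r.interactivity_index for r in map(dyad_metrics, coupled)])
        mn = np.mean([r.interactivity_index for r in map(dyad_metrics, null)])
        assert mc > mn + 0.1
        assert abs(mn) < 0.07

    def test_negative_sign_gives_negative_indices(self):
        p = CouplingParams(seed=19, sign=-1, immobile_prob=0.0, dropout_prob=0.0)
        recs = simulate_dyad_batch(30, p, BarrierSpec.from_type("open_clear"),
                                   n_frames=3000, coupling="fixed", seed=19)
        vals = np.array([r.interactivity_index for r in map(dyad_metrics, recs)])
        assert np.mean(vals < 0) > 0.8


class TestSimulateExperiment:
    def _run(self, rho, seed, n_flies=20, days=2, n_frames=1200):
        scheme = DyadScheme("scheme1_disjoint", n_flies, seed=seed)
        p = CouplingParams(persistence_rho=rho, seed=seed)
        return simulate_experiment(n_flies, scheme, days=days, params=p,
                                   n_frames=n_frames)

    def test_design_and_trajectory_consistency(self):
        exp = self._run(0.5, seed=1)
        assert len(exp.trajectories) == 20 * 2  # flies x days
        assert set(exp.design.columns) >= {"day", "session", "arena_id",
                                           "compartment", "fly_id", "dyad_id",
                                           "barrier_type", "genotype"}
        recs = exp.dyad_records()
        assert len(recs) == 10 * 2
        assert all(r.fly_a.compartment != r.fly_b.compartment for r in recs)

    def test_dyad_identity_maintained_across_days(self):
        exp = self._run(0.5, seed=2)
        by_day = exp.design.groupby("day")["dyad_id"].apply(set)
        assert by_day[1] == by_day[2]

    def test_round_trip_through_files(self, tmp_path):
        from flysin.synthetic import load_experiment

        exp = self._run(0.5, seed=3, n_flies=6, n_frames=300)
        exp.write(tmp_path)
        back = load_experiment(tmp_path)
        assert len(back.trajectories) == len(exp.trajectories)
        t0 = sorted(exp.trajectories, key=lambda t: (t.day, t.fly_id))[0]
        t1 = sorted(back.trajectories, key=lambda t: (t.day, t.fly_id))[0]
        assert np.allclose(t0.x[t0.valid], t1.x[t1.valid])
        assert back.barrier.barrier_type == exp.barrier.barrier_type
        rows = metric_table([dyad_metrics(d) for d in back.dyad_records()])
        assert len(rows) == 6

    def test_full_persistence_limit(self):
        # rho = 1: same couplings both days, so day-to-day index correlation
        # is high even at desk-scale frame counts
        from flysin import day_persistence

        exp = self._run(1.0, seed=4, n_flies=40, n_frames=2500)
        table = metric_table([dyad_metrics(d) for d in exp.dyad_records()])
        res = day_persistence(table, 1, 2)
        assert res.r > 0.5

    def test_scheme3_schedule_covers_all_dyads(self):
        scheme = DyadScheme("scheme3_saturated", 6, seed=0)
        exp = simulate_experiment(6, scheme, days=1, sessions_per_day=5,
                                  n_frames=200)
        assert exp.design["dyad_id"].nunique() == 15  # C(6,2)
        per_session = exp.design.groupby("session")["fly_id"].nunique()
        assert (per_session == 6).all()


class TestSmallGenerators:
    def test_all_right_turns(self):
        seq = simulate_turns(1.0, 50, seed=0)
        assert turning_bias(seq) == 1.0

    def test_unbiased_turns_near_half(self):
        seq = simulate_turns(0.5, 10_000, seed=1)
        assert turning_bias(seq) == pytest.approx(0.5, abs=0.02)

    def test_seeded_reproducibility(self):
        assert simulate_turns(0.3, 100, seed=9).turns == simulate_turns(0.3, 100, seed=9).turns

    def test_speed_population_mixture_composition(self):
        speeds = simulate_speed_population(n=2000, seed=3)
        immobile = np.mean(speeds < 0.1)
        assert immobile == pytest.approx(0.03, abs=0.015)
        assert speeds.min() >= 0.0
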