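"""The cascade engine: dependences, primary targets, waves, sequences."""
import numpy as np
import pytest

import coextdiv as cd
from coextdiv.coextinction import cascade_wave
from coextdiv.errors import InternalConsistencyError

from _oracles import enumerate_episode_outcomes


class TestDependences:
    def test_single_cell(self):
        net = cd.QuantitativeNetwork(("X",), ("P",), np.array([[5]]))
        dp = cd.dependence_matrices(net)
        assert dp.pollinator_on_plant[0, 0] == 1.0
        assert dp.plant_on_pollinator[0, 0] == 1.0

    def test_worked_example(self, worked_network):
        dp = cd.dependence_matrices(worked_network)
        np.testing.assert_allclose(dp.pollinator_on_plant,
                                   [[0.75, 0.25], [0.0, 1.0]])
        np.testing.assert_allclose(dp.plant_on_pollinator,
                                   [[1.0, 0.0], [1 / 3, 2 / 3]])

    def test_renormalization_after_death(self, worked_network):
        dp = cd.dependence_matrices(worked_network, alive_pollinators={"X"})
        # with Y dead, Q's remaining interactions are all with X
        np.testing.assert_allclose(dp.plant_on_pollinator,
                                   [[1.0, 0.0], [1.0, 0.0]])

    def test_rows_sum_to_one_or_zero(self, small_bundle):
        net = small_bundle.network
        rng = np.random.default_rng(0)
        pol = set(rng.choice(net.pollinators, size=8, replace=False))
        pla = set(rng.choice(net.plants, size=6, replace=False))
        dp = cd.dependence_matrices(net, pol, pla)
        for row in dp.pollinator_on_plant:
            assert row.sum() == pytest.approx(1.0) or row.sum() == 0.0
        for row in dp.plant_on_pollinator:
            assert row.sum() == pytest.approx(1.0) or row.sum() == 0.0


class TestPrimaryTargets:
    def test_inverse_frequency(self):
        net = cd.QuantitativeNetwork(("X", "Y"), ("P",), np.array([[1], [3]]))
        probs = cd.primary_target_probabilities(net)
        assert probs["X"] == pytest.approx(0.75)
        assert probs["Y"] == pytest.approx(0.25)

    def test_uniform_when_totals_equal(self):
        net = cd.QuantitativeNetwork(("X", "Y", "Z"), ("P",),
                                     np.array([[2], [2], [2]]))
        probs = cd.primary_target_probabilities(net)
        np.testing.assert_allclose(probs.to_numpy(), 1 / 3)

    def test_single_pollinator(self, worked_network):
        probs = cd.primary_target_probabilities(worked_network, {"Y"})
        assert probs["Y"] == pytest.approx(1.0)

    def test_zero_frequency_pollinator_is_inconsistent(self):
        net = cd.QuantitativeNetwork(("X", "Y"), ("P", "Q"),
                                     np.array([[0, 0], [1, 2]]))
        with pytest.raises(InternalConsistencyError):
            cd.primary_target_probabilities(net)


class TestCascadeWave:
    def test_certain_extinction_at_full_dependence(self, worked_network):
        deps = cd.dependence_matrices(worked_network)
        params = cd.SimParams()
        rng = np.random.default_rng(0)
        # plant P depends fully on its sole pollinator X
        fallen = cascade_wave(deps, ["X"], "pollinator", ["P", "Q"], params, rng)
        assert "P" in fallen

    def test_r_zero_never_kills(self, worked_network):
        deps = cd.dependence_matrices(worked_network)
        params = cd.SimParams(r_plant=0.0, r_animal=0.0)
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert cascade_wave(deps, ["X"], "pollinator", ["P", "Q"],
                                params, rng) == []

    def test_partial_dependence_frequency(self, worked_network):
        """Q depends 2/3 on Y; extinction frequency over many draws must
        match the Bernoulli rate within 3 standard errors."""
        deps = cd.dependence_matrices(worked_network)
        params = cd.SimParams()
        rng = np.random.default_rng(2)
        n = 100_000
        hits = sum("Q" in cascade_wave(deps, ["Y"], "pollinator", ["Q"],
                                       params, rng) for _ in range(n))
        p = 2 / 3
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestSequences:
    def test_r_zero_sequence(self, small_bundle):
        net = small_bundle.network
        params = cd.SimParams(r_plant=0.0, r_animal=0.0, seed=5)
        seq = cd.simulate_sequence(net, params, np.random.default_rng(5))
        assert seq.n_episodes == net.n_pollinators
        assert all(not ep.losses for ep in seq.episodes)
        assert seq.plant_snapshots[-1].all()
        assert (seq.persistence == net.n_pollinators).all()

    def test_specialist_plants_die_with_their_pollinator(self):
        """One-to-one specialist network at R=1: each plant falls in the
        same episode as its sole pollinator, deterministically."""
        counts = np.diag([3, 1, 7])
        net = cd.QuantitativeNetwork(("X", "Y", "Z"), ("P", "Q", "S"), counts)
        params = cd.SimParams(seed=0)
        for seed in range(50):
            seq = cd.simulate_sequence(net, params, np.random.default_rng(seed))
            assert seq.n_episodes == 3
            for k, ep in enumerate(seq.episodes, start=1):
                sides = {side for side, _ in ep.losses}
                assert sides == {"plant"}
                (loss,) = [lab for _, lab in ep.losses]
                idx = net.plants.index(loss)
                assert net.pollinators.index(ep.primary) == idx
                assert seq.persistence[idx] == k - 1

    def test_everyone_dies_at_r_one(self, worked_network):
        for seed in range(50):
            seq = cd.simulate_sequence(worked_network, cd.SimParams(),
                                       np.random.default_rng(seed))
            assert not seq.plant_snapshots[-1].any()

    def test_monotone_shrinkage(self, small_bundle):
        seq = cd.simulate_sequence(small_bundle.network, cd.SimParams(),
                                   np.random.default_rng(42))
        prev = np.ones(small_bundle.network.n_plants, dtype=bool)
        for snap in seq.plant_snapshots:
            assert (snap <= prev).all()
            prev = snap

    def test_persistence_matches_loss_episode(self, small_bundle):
        seq = cd.simulate_sequence(small_bundle.network, cd.SimParams(),
                                   np.random.default_rng(7))
        alive = np.ones(small_bundle.network.n_plants, dtype=bool)
        for k, snap in enumerate(seq.plant_snapshots, start=1):
            lost_now = alive & ~snap
            for j in np.flatnonzero(lost_now):
                assert seq.persistence[j] == k - 1
            alive = snap


class TestEnsembles:
    def test_same_seed_identical(self, worked_network):
        params = cd.SimParams(n_runs=50, seed=3)
        a = cd.run_ensemble(worked_network, params)
        b = cd.run_ensemble(worked_network, params)
        np.testing.assert_array_equal(a.persistence_matrix, b.persistence_matrix)

    def test_single_run(self, worked_network):
        ens = cd.run_ensemble(worked_network, cd.SimParams(n_runs=1, seed=0))
        assert ens.n_runs == 1

    def test_rare_pollinators_die_first_on_average(self):
        """Specialist network with very unequal totals: the rarest
        pollinator's plant has the lowest mean persistence."""
        counts = np.diag([1, 10, 100])
        net = cd.QuantitativeNetwork(("X", "Y", "Z"), ("P", "Q", "S"), counts)
        ens = cd.run_ensemble(net, cd.SimParams(n_runs=2000, seed=11))
        mp = ens.mean_persistence()
        assert mp["P"] < mp["Q"] < mp["S"]


class TestEpisodeDistribution:
    def test_worked_network_exact_enumeration(self, worked_network):
        """Surviving-plant-set distribution after episode 1 matches the
        exhaustive probability-tree expansion (hand-checked: survivors
        {} w.p. 2/9, {Q} 2/9, {P} 1/3, {P,Q} 2/9)."""
        exact = enumerate_episode_outcomes(worked_network.counts)
        key = {frozenset(): 2 / 9, frozenset({1}): 2 / 9,
               frozenset({0}): 1 / 3, frozenset({0, 1}): 2 / 9}
        for k, v in key.items():
            assert exact.get(k, 0.0) == pytest.approx(v, abs=1e-12)

        n = 20_000
        ens = cd.run_ensemble(worked_network, cd.SimParams(n_runs=n, seed=21))
        counts = {}
        for seq in ens.sequences:
            k = frozenset(np.flatnonzero(seq.plant_snapshots[0]))
            counts[k] = counts.get(k, 0) + 1
        for k, p in exact.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(k, 0) / n - p) <= 3 * se
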