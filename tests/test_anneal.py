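"""Simulated annealing: proposals, acceptance, incremental engine, oracle."""

from itertools import product

import numpy as np
import pytest

from muncut.anneal import (
    SAConfig,
    _CellEngine,
    accept_step,
    donor_receiver_probs,
    initialize_partition,
    propose_move,
    run_sa,
    temperature,
)
from muncut.data import Partition
from muncut.ncut import muncut_objective, ncut_measure


class TestInitialize:
    def test_one_per_cluster_when_m_equals_K(self):
        labels = initialize_partition(4, 4, seed=0)
        assert sorted(labels) == [0, 1, 2, 3]

    def test_deterministic_given_seed(self):
        a = initialize_partition(30, 3, seed=11)
        b = initialize_partition(30, 3, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_every_cluster_nonempty(self):
        for seed in range(20):
            labels = initialize_partition(6, 3, seed=seed)
            assert np.bincount(labels, minlength=3).min() > 0

    def test_approximately_uniform(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(3)
        for _ in range(2000):
            counts += np.bincount(initialize_partition(12, 3, rng), minlength=3)
        freqs = counts / counts.sum()
        np.testing.assert_allclose(freqs, 1 / 3, atol=0.02)

    def test_K_larger_than_m_rejected(self):
        with pytest.raises(ValueError):
            initialize_partition(3, 5, seed=0)


class TestProposal:
    def test_donor_probability_size_squared(self):
        donor, _ = donor_receiver_probs(np.array([9, 2]), smoothing=1.0)
        np.testing.assert_allclose(donor, [81 / 85, 4 / 85])

    def test_singleton_cannot_donate(self):
        donor, _ = donor_receiver_probs(np.array([9, 1]), smoothing=1.0)
        np.testing.assert_allclose(donor, [1.0, 0.0])

    def test_receiver_inverse_weighting(self):
        _, receiver = donor_receiver_probs(np.array([2, 3]), smoothing=1.0)
        np.testing.assert_allclose(receiver, [1 / 5, 1 / 10])

    def test_move_changes_exactly_one_label(self):
        rng = np.random.default_rng(5)
        labels = initialize_partition(20, 3, rng)
        sizes = np.bincount(labels, minlength=3)
        i, a, b = propose_move(labels, sizes, rng)
        assert labels[i] == a
        assert a != b

    def test_empty_clusters_never_donate(self):
        rng = np.random.default_rng(3)
        labels = np.zeros(5, dtype=int)  # cluster 1 empty
        sizes = np.array([5, 0])
        for _ in range(50):
            i, a, b = propose_move(labels, sizes, rng)
            assert a == 0 and b == 1


class TestAcceptance:
    def config(self, schedule, L=1000.0):
        return SAConfig(K=2, B=10, L=L, schedule=schedule)

    def test_improving_always_accepted(self):
        cfg = self.config("inverse_log")
        assert accept_step(1.0, 0.5, t=1, config=cfg, rng=np.random.default_rng(0))
        assert accept_step(1.0, 1.0, t=1, config=cfg, rng=np.random.default_rng(0))

    @pytest.mark.parametrize("schedule", ["inverse_log", "cooling", "heating"])
    def test_delta_equal_temperature_accepts_at_e_minus_one(self, schedule):
        cfg = self.config(schedule, L=2.0)
        T = temperature(5, 2.0, schedule)
        accepts = sum(
            accept_step(0.0, T, t=5, config=cfg, rng=np.random.default_rng(s))
            for s in range(4000)
        )
        assert accepts / 4000 == pytest.approx(np.exp(-1), abs=0.03)

    def test_inverse_log_probability_vanishes_late(self):
        cfg = self.config("inverse_log", L=1000.0)
        accepts = sum(
            accept_step(0.0, 0.05, t=10_000, config=cfg, rng=np.random.default_rng(s))
            for s in range(100)
        )
        assert accepts == 0

    def test_cooling_temperature_decreases_heating_increases(self):
        ts = [1, 10, 100, 1000]
        cool = [temperature(t, 5.0, "cooling") for t in ts]
        heat = [temperature(t, 5.0, "heating") for t in ts]
        inv = [temperature(t, 5.0, "inverse_log") for t in ts]
        assert all(a > b for a, b in zip(cool, cool[1:]))
        assert all(a < b for a, b in zip(heat, heat[1:]))
        assert all(a > b for a, b in zip(inv, inv[1:]))


def partitions_up_to_K(m, K):
    """All label vectors over m items with at most K blocks, one per
    set-partition equivalence class (restricted growth strings)."""

    def rec(prefix, used):
        i = len(prefix)
        if i == m:
            yield np.array(prefix)
            return
        for lab in range(min(used + 1, K)):
            yield from rec(prefix + [lab], max(used, lab + 1))

    yield from rec([], 0)


class TestRunSA:
    def test_matches_exhaustive_search_on_toy(self, toy_weights):
        # the chain keeps all K clusters nonempty, so the oracle enumerates
        # partitions into exactly K nonempty blocks
        layer_of = np.repeat(["P", "G", "C"], 3)
        best = np.inf
        for labels in partitions_up_to_K(9, 3):
            if len(np.unique(labels)) != 3:
                continue
            part = Partition(labels, layer_of, K=3)
            best = min(best, muncut_objective(part, toy_weights, gamma=0.5))
        st = run_sa(toy_weights, layer_of, SAConfig(K=3, B=4000, seed=0), gamma=0.5)
        assert st.best_objective == pytest.approx(best, rel=1e-9)
        # and that minimizer is the channel partition
        channel = np.tile(np.arange(3), 3)
        chan_part = Partition(channel, layer_of, K=3)
        assert muncut_objective(chan_part, toy_weights, gamma=0.5) == pytest.approx(best)

    def test_trace_reproducible_and_best_consistent(self, toy_weights):
        layer_of = np.repeat(["P", "G", "C"], 3)
        cfg = SAConfig(K=3, B=500, seed=7)
        s1 = run_sa(toy_weights, layer_of, cfg, gamma=0.5)
        s2 = run_sa(toy_weights, layer_of, cfg, gamma=0.5)
        np.testing.assert_array_equal(s1.objective_trace, s2.objective_trace)
        np.testing.assert_array_equal(s1.best_partition.labels, s2.best_partition.labels)
        # the incumbent can never exceed any traced objective
        assert s1.best_objective <= s1.objective_trace.min() + 1e-9

    def test_incremental_engine_matches_full_objective(self, rng):
        # random weights, random moves: engine value equals recomputation
        m, K = 12, 3
        W = rng.uniform(size=(m, m))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        cells = rng.integers(0, K, size=m)
        eng = _CellEngine(W, cells, K, eps=1e-8)
        for _ in range(60):
            i = rng.integers(m)
            a = cells[i]
            b = (a + 1 + rng.integers(K - 1)) % K
            delta = eng.delta_move(i, a, b)
            before = eng.value()
            eng.apply_move(i, a, b)
            cells[i] = b
            after = ncut_measure(cells, W, K, include_diag=False)
            assert eng.value() == pytest.approx(after, rel=1e-6, abs=1e-7)
            assert before + delta == pytest.approx(after, rel=1e-6, abs=1e-7)

    def test_incremental_engine_with_diagonal(self, rng):
        m, K = 10, 2
        W = rng.uniform(size=(m, m))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 1.0)
        cells = rng.integers(0, K, size=m)
        eng = _CellEngine(W, cells, K, eps=1e-8, include_diag=True)
        for _ in range(40):
            i = rng.integers(m)
            a, b = cells[i], 1 - cells[i]
            eng.apply_move(i, a, b)
            cells[i] = b
            assert eng.value() == pytest.approx(
                ncut_measure(cells, W, K, include_diag=True), abs=1e-7
            )

    def test_reported_best_objective_is_exact(self, toy_weights):
        layer_of = np.repeat(["P", "G", "C"], 3)
        st = run_sa(toy_weights, layer_of, SAConfig(K=3, B=800, seed=1), gamma=0.3)
        recomputed = muncut_objective(st.best_partition, toy_weights, gamma=0.3)
        assert st.best_objective == pytest.approx(recomputed, rel=1e-12)
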