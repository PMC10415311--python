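import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mitonet import connectivity, multislice, synthetic
from mitonet.core import MultilayerNetwork
from mitonet.multislice import MultilayerPartition

from conftest import enumerate_set_partitions


def brute_force_q(slices, assignment, gamma, omega):
    """Independent quadruple-loop evaluation of the multi-slice quality."""
    n = slices[0].shape[0]
    n_slices = len(slices)
    ks, two_ms = [], []
    for a in slices:
        a = a.copy()
        np.fill_diagonal(a, 0.0)
        ks.append(a.sum(axis=1))
        two_ms.append(a.sum())
    total = 0.0
    for i in range(n):
        for j in range(n):
            for s in range(n_slices):
                for r in range(n_slices):
                    if assignment[i, s] != assignment[j, r]:
                        continue
                    if s == r:
                        a = slices[s].copy()
                        np.fill_diagonal(a, 0.0)
                        null = gamma * ks[s][i] * ks[s][j] / two_ms[s] \
                            if two_ms[s] else 0.0
                        total += a[i, j] - null
                    elif i == j:
                        total += omega
    two_mu = sum(two_ms) + omega * n * n_slices * (n_slices - 1)
    return total / two_mu


def _random_network(rng, n, n_slices):
    slices = []
    for _ in range(n_slices):
        raw = rng.uniform(-0.5, 1.0, size=(n, n))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        slices.append(a)
    return MultilayerNetwork(labels=[f"a{i}" for i in range(n)],
                             slices=slices)


def _partition(network, assignment):
    return MultilayerPartition(network.labels, np.asarray(assignment))


class TestMultisliceQ:
    def test_matches_bruteforce_on_random_assignments(self, rng):
        net = _random_network(rng, 4, 3)
        for _ in range(25):
            assignment = rng.integers(0, 3, size=(4, 3))
            q = multislice.multislice_q(net, _partition(net, assignment),
                                        gamma=1.0, omega=0.1)
            expected = brute_force_q(net.slices, assignment, 1.0, 0.1)
            assert q == pytest.approx(expected)

    def test_single_slice_reduces_to_newman(self):
        # two disconnected dyads, hand-computed Q = 0.5
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        net = MultilayerNetwork(labels=list("wxyz"), slices=[a])
        assignment = np.array([[0], [0], [1], [1]])
        q = multislice.multislice_q(net, _partition(net, assignment),
                                    gamma=1.0, omega=0.0)
        assert q == pytest.approx(0.5)

    def test_all_in_one_community_leaves_coupling_only(self, rng):
        net = _random_network(rng, 5, 2)
        assignment = np.zeros((5, 2), dtype=int)
        omega = 0.2
        q = multislice.multislice_q(net, _partition(net, assignment),
                                    gamma=1.0, omega=omega)
        # intra-slice part sums to zero by the degree identity; only the
        # (saturated) coupling term remains
        two_ms = []
        for a in net.slices:
            a = a.copy()
            np.fill_diagonal(a, 0.0)
            two_ms.append(a.sum())
        coupling = omega * 5 * 2 * 1
        assert q == pytest.approx(coupling / (sum(two_ms) + coupling))

    def test_exhaustive_oracle_all_partitions(self, rng):
        # every set partition of the 6 node-slices (3 areas x 2 slices)
        net = _random_network(rng, 3, 2)
        elements = [(i, s) for i in range(3) for s in range(2)]
        for part in enumerate_set_partitions(elements):
            assignment = np.zeros((3, 2), dtype=int)
            for label, block in enumerate(part):
                for (i, s) in block:
                    assignment[i, s] = label
            q = multislice.multislice_q(net, _partition(net, assignment),
                                        gamma=1.0, omega=0.1)
            expected = brute_force_q(net.slices, assignment, 1.0, 0.1)
            assert q == pytest.approx(expected)

    def test_label_permutation_invariance(self, rng):
        net = _random_network(rng, 5, 3)
        assignment = rng.integers(0, 4, size=(5, 3))
        q1 = multislice.multislice_q(net, _partition(net, assignment))
        remap = {0: 7, 1: 2, 2: 9, 3: 0}
        remapped = np.vectorize(remap.get)(assignment)
        q2 = multislice.multislice_q(net, _partition(net, remapped))
        assert q1 == pytest.approx(q2)

    def test_mismatched_shapes_rejected(self, rng):
        net = _random_network(rng, 4, 2)
        with pytest.raises(ValueError):
            multislice.multislice_q(net, _partition(
                MultilayerNetwork(labels=list("abc"),
                                  slices=[np.eye(3)] * 2),
                np.zeros((3, 2), dtype=int)))


class TestOptimize:
    def test_two_disconnected_blocks(self):
        a = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            a[i, j] = a[j, i] = 1.0
        net = MultilayerNetwork(labels=[f"n{i}" for i in range(6)],
                                slices=[a, a])
        part = multislice.optimize_communities(net, omega=0.1, seed=0)
        g = part.assignment
        # slice-consistent, exactly the two planted blocks
        assert (g[:, 0] == g[:, 1]).all()
        assert len(set(g[:3, 0])) == 1
        assert len(set(g[3:, 0])) == 1
        assert g[0, 0] != g[3, 0]

    def test_quality_is_local_optimum(self, rng):
        net = _random_network(rng, 6, 2)
        part = multislice.optimize_communities(net, omega=0.1, seed=1)
        q0 = part.quality
        labels = part.assignment.copy()
        # no single-node-slice move improves Q
        for i in range(6):
            for s in range(2):
                for new in set(labels.ravel()) | {labels.max() + 1}:
                    if new == labels[i, s]:
                        continue
                    trial = labels.copy()
                    trial[i, s] = new
                    q = multislice.multislice_q(net, _partition(net, trial),
                                                omega=0.1)
                    assert q <= q0 + 1e-9

    def test_attains_exhaustive_max_on_toys(self, rng):
        hits = 0
        n_trials = 30
        for trial in range(n_trials):
            trng = np.random.default_rng(trial)
            net = _random_network(trng, 4, 2)
            elements = [(i, s) for i in range(4) for s in range(2)]
            best = -np.inf
            for part in enumerate_set_partitions(elements):
                assignment = np.zeros((4, 2), dtype=int)
                for label, block in enumerate(part):
                    for (i, s) in block:
                        assignment[i, s] = label
                q = multislice.multislice_q(net, _partition(net, assignment),
                                            omega=0.1)
                best = max(best, q)
            achieved = multislice.optimize_communities(net, omega=0.1,
                                                       seed=trial).quality
            if achieved >= best - 1e-9:
                hits += 1
        assert hits >= int(0.9 * n_trials)

    def test_large_omega_forces_slice_coherence(self, rng):
        net = _random_network(rng, 6, 3)
        part = multislice.optimize_communities(net, omega=50.0, seed=2)
        g = part.assignment
        assert (g == g[:, [0]]).all()

    def test_omega_zero_decouples_slices(self, rng):
        net = _random_network(rng, 5, 2)
        part = multislice.optimize_communities(net, omega=0.0, seed=3)
        for s in range(2):
            single = MultilayerNetwork(labels=net.labels,
                                       slices=[net.slices[s]])
            solo = multislice.optimize_communities(single, omega=0.0, seed=3)
            q_joint_slice = multislice.multislice_q(
                single,
                MultilayerPartition(net.labels, part.assignment[:, [s]]),
                omega=0.0)
            assert q_joint_slice == pytest.approx(solo.quality, abs=1e-9)

    def test_seed_deterministic(self, rng):
        net = _random_network(rng, 8, 3)
        p1 = multislice.optimize_communities(net, seed=7)
        p2 = multislice.optimize_communities(net, seed=7)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)


class TestAllegiance:
    def test_identical_labels_binary(self):
        assignment = np.array([[0, 0], [0, 0], [1, 1]])
        part = MultilayerPartition(("a", "b", "c"), assignment)
        alleg = multislice.module_allegiance(part)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1.0]])
        np.testing.assert_allclose(alleg.values, expected)

    def test_half_co_assignment(self):
        assignment = np.array([[0, 0, 0, 1, 1, 1],
                               [0, 0, 0, 0, 0, 0],
                               [2, 2, 2, 2, 2, 2]])
        part = MultilayerPartition(("a", "b", "c"), assignment)
        alleg = multislice.module_allegiance(part)
        assert alleg.values[0, 1] == pytest.approx(0.5)

    def test_symmetric_random(self, rng):
        assignment = rng.integers(0, 3, size=(6, 4))
        part = MultilayerPartition(tuple("abcdef"), assignment)
        alleg = multislice.module_allegiance(part)
        np.testing.assert_allclose(alleg.values, alleg.values.T)


class TestConsensus:
    def test_perfect_block_allegiance_idempotent(self):
        a = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            a[i, j] = a[j, i] = 1.0
        net = MultilayerNetwork(labels=[f"n{i}" for i in range(6)],
                                slices=[a, a])
        part = multislice.consensus_communities(net, n_runs=10, seed=0)
        assert part.n_communities == 2
        assert part.meta["converged"]

    def test_planted_cohort_recovery(self, strong_cohort):
        net = connectivity.per_feature_slices(strong_cohort)
        part = multislice.consensus_communities(net, n_runs=25, seed=1)
        planted = [synthetic.DEFAULT_PARTITION[a] for a in net.labels]
        found = [part.assignment[a] for a in net.labels]
        assert adjusted_rand_score(planted, found) == 1.0

    def test_run_order_invariance(self, rng):
        net = _random_network(rng, 8, 3)
        p1 = multislice.consensus_communities(net, n_runs=20, seed=4)
        p2 = multislice.consensus_communities(net, n_runs=20, seed=4)
        assert p1.assignment == p2.assignment
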