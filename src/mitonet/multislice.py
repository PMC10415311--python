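"""Categorical multi-slice community detection on feature slices.

Quality function: generalized modularity with categorical all-to-all
interslice coupling,

    Q = 1/(2 mu) * sum_ijsr [ (A_ijs - gamma_s k_is k_js / 2 m_s) d_sr
                              + d_ij C_jsr ] d(g_is, g_jr)

with C_jsr = omega for every ordered pair of distinct slices.  Optimization
is greedy single-node-slice moves plus community merges until a local
optimum; consensus over many runs goes through the module allegiance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MultilayerNetwork, Partition

log = logging.getLogger(__name__)


@dataclass
class MultilayerPartition:
    """Community label per (area, slice)."""

    labels: tuple[str, ...]
    assignment: np.ndarray            # shape (n_areas, n_slices), int labels
    quality: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.shape[0] != len(self.labels):
            raise ValueError("assignment rows must match labels")

    def slice_labels(self, s: int) -> np.ndarray:
        return self.assignment[:, s]


@dataclass
class AllegianceMatrix:
    """Fraction of (slice, run) columns in which two areas share a community."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("allegiance shape mismatch")


# ---------------------------------------------------------------------------
# quality function
# ---------------------------------------------------------------------------

def _slice_terms(network: MultilayerNetwork, gamma) -> tuple[list, np.ndarray]:
    """Per-slice modularity gain matrices A - gamma k k^T / 2m (diag zeroed
    in A first) and the per-slice total weights 2m_s."""
    gammas = np.broadcast_to(np.asarray(gamma, dtype=float),
                             (network.n_slices,))
    gains, two_ms = [], np.zeros(network.n_slices)
    for s, a in enumerate(network.slices):
        a = a.copy()
        np.fill_diagonal(a, 0.0)
        a = np.nan_to_num(a, nan=0.0)
        k = a.sum(axis=1)
        two_m = a.sum()
        two_ms[s] = two_m
        null = np.outer(k, k) / two_m if two_m != 0 else np.zeros_like(a)
        gains.append(a - gammas[s] * null)
    return gains, two_ms


def multislice_q(
    network: MultilayerNetwork,
    partition: MultilayerPartition,
    gamma=1.0,
    omega: float = 0.1,
) -> float:
    """Exact evaluation of the multi-slice quality for a given assignment."""
    if partition.assignment.shape != (network.n_nodes, network.n_slices):
        raise ValueError("partition does not match network dimensions")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    gains, two_ms = _slice_terms(network, gamma)
    g = partition.assignment
    intra = 0.0
    for s in range(network.n_slices):
        same = g[:, s][:, None] == g[:, s][None, :]
        intra += gains[s][same].sum()
    coupling = 0.0
    for j in range(network.n_nodes):
        same = g[j][:, None] == g[j][None, :]
        coupling += omega * (same.sum() - network.n_slices)
    two_mu = two_ms.sum() + omega * network.n_nodes * network.n_slices * \
        (network.n_slices - 1)
    if two_mu == 0:
        return 0.0
    return float((intra + coupling) / two_mu)


# ---------------------------------------------------------------------------
# greedy optimization
# ---------------------------------------------------------------------------

def _relabel(assignment: np.ndarray) -> np.ndarray:
    """Canonical labels 0..C-1 in order of first appearance (column-major)."""
    flat = assignment.T.ravel()
    mapping: dict[int, int] = {}
    out = np.empty_like(flat)
    for idx, lab in enumerate(flat):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[idx] = mapping[lab]
    return out.reshape(assignment.T.shape).T


def _local_moves(gains, omega, labels, rng, tol=1e-12) -> bool:
    """One or more sweeps of best single-node-slice moves; returns whether
    any move improved the (unnormalized) quality."""
    n, n_slices = labels.shape
    improved_any = False
    while True:
        improved = False
        order = rng.permutation(n * n_slices)
        n_labels = labels.max() + 2
        for flat in order:
            i, s = divmod(int(flat), n_slices)
            current = labels[i, s]
            w = gains[s][i].copy()
            w[i] = 0.0
            comm_gain = np.bincount(labels[:, s], weights=w,
                                    minlength=n_labels)
            if n_slices > 1:
                others = np.delete(labels[i], s)
                comm_gain = comm_gain + omega * np.bincount(
                    others, minlength=n_labels)
            base = comm_gain[current]
            best = int(np.argmax(comm_gain))
            gain = comm_gain[best] - base
            # also consider splitting off into a fresh singleton community
            if -base > gain + tol:
                labels[i, s] = n_labels - 1
                n_labels += 1
                improved = improved_any = True
                continue
            if gain > tol and best != current:
                labels[i, s] = best
                improved = improved_any = True
        if not improved:
            break
    return improved_any


def _merge_moves(gains, omega, labels, tol=1e-12) -> bool:
    """Merge the community pair with the largest positive quality gain;
    repeat until none improves."""
    improved_any = False
    while True:
        labs = np.unique(labels)
        c = len(labs)
        if c < 2:
            break
        remap = {lab: idx for idx, lab in enumerate(labs)}
        lab_idx = np.vectorize(remap.get)(labels)
        n, n_slices = labels.shape
        inter = np.zeros((c, c))
        for s in range(n_slices):
            ind = np.zeros((n, c))
            ind[np.arange(n), lab_idx[:, s]] = 1.0
            inter += ind.T @ gains[s] @ ind
        # interslice coupling between communities: count per node of slices
        # in each community, cross-products summed over nodes
        counts = np.zeros((n, c))
        for s in range(n_slices):
            np.add.at(counts, (np.arange(n), lab_idx[:, s]), 1.0)
        inter += omega * (counts.T @ counts - np.diag((counts ** 2).sum(0)))
        np.fill_diagonal(inter, -np.inf)
        a, b = np.unravel_index(np.argmax(inter), inter.shape)
        if inter[a, b] <= tol:
            break
        labels[labels == labs[b]] = labs[a]
        improved_any = True
    return improved_any


def optimize_communities(
    network: MultilayerNetwork,
    gamma=1.0,
    omega: float = 0.1,
    seed: int = 0,
) -> MultilayerPartition:
    """Greedy maximization of the multi-slice quality.

    Alternates single-node-slice moves with community merges until neither
    improves; the result is a local optimum under single moves, and the
    quality is non-decreasing throughout.  Deterministic for a fixed seed.
    """
    if network.n_nodes < 2:
        raise ValueError("need >=2 areas")
    gains, _ = _slice_terms(network, gamma)
    rng = np.random.default_rng(seed)
    labels = np.arange(network.n_nodes * network.n_slices).reshape(
        network.n_slices, network.n_nodes).T.copy()
    while True:
        moved = _local_moves(gains, omega, labels, rng)
        merged = _merge_moves(gains, omega, labels)
        if merged:
            moved = _local_moves(gains, omega, labels, rng) or moved
        if not (moved or merged):
            break
    labels = _relabel(labels)
    part = MultilayerPartition(network.labels, labels,
                               params={"gamma": gamma, "omega": omega,
                                       "seed": seed})
    part.quality = multislice_q(network, part, gamma=gamma, omega=omega)
    return part


# ---------------------------------------------------------------------------
# allegiance + consensus
# ---------------------------------------------------------------------------

def module_allegiance(partitions) -> AllegianceMatrix:
    """Fraction of (slice, run) assignments in which areas co-occur."""
    if isinstance(partitions, MultilayerPartition):
        partitions = [partitions]
    if not partitions:
        raise ValueError("need >=1 partition")
    labels = partitions[0].labels
    cols = []
    for p in partitions:
        if p.labels != labels:
            raise ValueError("partitions disagree on area labels")
        for s in range(p.assignment.shape[1]):
            cols.append(p.assignment[:, s])
    stack = np.stack(cols, axis=1)          # areas x (runs*slices)
    same = (stack[:, None, :] == stack[None, :, :]).mean(axis=2)
    np.fill_diagonal(same, 1.0)
    return AllegianceMatrix(labels, same)


def _single_layer_optimize(b: np.ndarray, seed: int) -> np.ndarray:
    """Greedy maximization of sum_ij B_ij d(g_i, g_j) for symmetric B with
    zero diagonal (the allegiance matrix minus its null expectation)."""
    rng = np.random.default_rng(seed)
    labels = np.arange(b.shape[0])[:, None].copy()
    gains = [b]
    while True:
        moved = _local_moves(gains, 0.0, labels, rng)
        merged = _merge_moves(gains, 0.0, labels)
        if not (moved or merged):
            break
    return _relabel(labels)[:, 0]


def consensus_communities(
    network: MultilayerNetwork,
    n_runs: int = 1000,
    omega: float = 0.1,
    gamma=1.0,
    seed: int = 0,
    max_iter: int = 50,
    n_consensus_runs: int = 20,
) -> Partition:
    """Multi-run consensus: ``n_runs`` optimizations -> allegiance matrix
    over runs x slices -> iterative re-clustering of the allegiance matrix
    (minus its permutation-null expectation, the off-diagonal mean) until
    the partition is stable between iterations."""
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2 ** 31 - 1, size=n_runs)
    parts = [optimize_communities(network, gamma=gamma, omega=omega,
                                  seed=int(s)) for s in run_seeds]
    alleg = module_allegiance(parts)
    p = alleg.values.copy()
    converged = False
    current = np.zeros(network.n_nodes, dtype=int)
    for _ in range(max_iter):
        off = ~np.eye(p.shape[0], dtype=bool)
        b = p - p[off].mean()
        np.fill_diagonal(b, 0.0)
        sub_seeds = rng.integers(0, 2 ** 31 - 1, size=n_consensus_runs)
        runs = [_single_layer_optimize(b, int(s)) for s in sub_seeds]
        stack = np.stack(runs, axis=1)
        current = _relabel(runs[0][:, None])[:, 0]
        # stable once every re-clustering run returns the same partition
        if all(np.array_equal(_relabel(r[:, None])[:, 0], current)
               for r in runs[1:]):
            converged = True
            break
        p = (stack[:, None, :] == stack[None, :, :]).mean(axis=2)
        np.fill_diagonal(p, 1.0)
    if not converged:
        log.warning("consensus did not fully converge in %d iterations; "
                    "returning current best partition", max_iter)
    assignment = {area: int(lab) for area, lab in zip(network.labels, current)}
    return Partition(network.labels, assignment,
                     meta={"n_runs": n_runs, "omega": omega, "gamma": gamma,
                           "allegiance": alleg.values, "converged": converged})


def omega_sweep(network: MultilayerNetwork, omegas=(0.05, 0.1, 0.15, 0.2),
                n_runs: int = 100, seed: int = 0) -> dict[float, Partition]:
    """Consensus partitions across a range of interslice couplings."""
    return {w: consensus_communities(network, n_runs=n_runs, omega=w,
                                     seed=seed + i)
            for i, w in enumerate(omegas)}
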