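"""Validation of an area partition against independent modality matrices
(gene co-expression, structural connectome) by label permutation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Partition

log = logging.getLogger(__name__)

#: default merge: the reference atlases do not distinguish dorsal/ventral DG
DEFAULT_MERGE_MAP = {"DG": ["DGd", "DGv"]}


@dataclass
class ModalityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "coexpression"

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("modality matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("modality matrix must be symmetric")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "coexpression"):
        return cls(tuple(df.index), df.to_numpy(), kind=kind)


def align_partition(
    partition: Partition,
    matrix: ModalityMatrix,
    merge_map: dict[str, list[str]] | None = None,
) -> Partition:
    """Restrict/merge a partition onto the matrix's label set.

    A merged label (e.g. DG <- DGd + DGv) inherits the community of its
    members; members in different communities make inheritance undefined and
    raise.
    """
    merge_map = DEFAULT_MERGE_MAP if merge_map is None else merge_map
    assignment: dict[str, int] = {}
    for label in matrix.labels:
        if label in partition.assignment:
            assignment[label] = partition.assignment[label]
        elif label in merge_map:
            members = merge_map[label]
            comms = {partition.assignment[m] for m in members
                     if m in partition.assignment}
            if not comms:
                raise ValueError(f"no partition areas found for merged "
                                 f"label {label!r}")
            if len(comms) > 1:
                raise ValueError(
                    f"merged label {label!r} members span communities "
                    f"{sorted(comms)}: inheritance undefined")
            assignment[label] = comms.pop()
        else:
            raise ValueError(f"matrix label {label!r} not in partition and "
                             "not covered by the merge map")
    return Partition(matrix.labels, assignment)


def _offdiag_sums(values: np.ndarray, assign: np.ndarray):
    tri = np.triu_indices(len(assign), k=1)
    w = values[tri]
    within = assign[tri[0]] == assign[tri[1]]
    return w, within


def strength_fraction(matrix: ModalityMatrix, partition: Partition) -> float:
    """Within-community edge weight over total edge weight (each pair once)."""
    assign = _aligned_assignment(matrix, partition)
    w, within = _offdiag_sums(matrix.values, assign)
    total = np.nansum(w)
    if total == 0:
        log.warning("strength fraction undefined: zero total edge weight")
        return np.nan
    return float(np.nansum(w[within]) / total)


def modularity_q(matrix: ModalityMatrix, partition: Partition) -> float:
    """Weighted Newman modularity sum_within (A_ij - k_i k_j / 2m) / 2m."""
    assign = _aligned_assignment(matrix, partition)
    a = matrix.values.copy()
    np.fill_diagonal(a, 0.0)
    a = np.nan_to_num(a, nan=0.0)
    k = a.sum(axis=1)
    two_m = a.sum()
    if two_m == 0:
        log.warning("modularity undefined: zero total edge weight")
        return np.nan
    same = assign[:, None] == assign[None, :]
    return float(((a - np.outer(k, k) / two_m)[same]).sum() / two_m)


def _aligned_assignment(matrix: ModalityMatrix, partition: Partition):
    if tuple(partition.labels) != tuple(matrix.labels):
        partition = align_partition(partition, matrix)
    return partition.as_array()


def permutation_test(
    matrix: ModalityMatrix,
    partition: Partition,
    metric: str = "SF",
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """One-sided (enrichment) test of within-community connectedness.

    The null shuffles the area -> community labels, preserving community
    sizes; p = (1 + #null >= observed) / (n_perm + 1).
    """
    if n_perm < 100:
        log.warning("n_perm=%d is low; p-value resolution is coarse", n_perm)
    if metric not in ("SF", "Q"):
        raise ValueError("metric must be 'SF' or 'Q'")
    if tuple(partition.labels) != tuple(matrix.labels):
        partition = align_partition(partition, matrix)
    assign = partition.as_array()
    values = matrix.values

    if metric == "SF":
        w, _ = _offdiag_sums(values, assign)
        total = np.nansum(w)

        def stat(a):
            _, within = _offdiag_sums(values, a)
            return np.nansum(w[within]) / total
    else:
        a0 = values.copy()
        np.fill_diagonal(a0, 0.0)
        a0 = np.nan_to_num(a0, nan=0.0)
        k = a0.sum(axis=1)
        two_m = a0.sum()
        gain = a0 - np.outer(k, k) / two_m

        def stat(a):
            same = a[:, None] == a[None, :]
            return gain[same].sum() / two_m

    observed = float(stat(assign))
    rng = np.random.default_rng(seed)
    count = 0
    null = np.empty(n_perm)
    for t in range(n_perm):
        null[t] = stat(rng.permutation(assign))
        if null[t] >= observed:
            count += 1
    return {"metric": metric, "statistic": observed,
            "p": (1 + count) / (n_perm + 1), "n_perm": n_perm, "null": null}
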