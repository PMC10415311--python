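"""Mapper shape-graph pipeline on stress-vs-naive delta matrices.

Filter (neighborhood-preserving 2-D embedding) -> overlapping 2-D binning ->
partial clustering on the original high-dimensional rows -> shared-row edges,
plus the participation-coefficient segregation statistic and a
phase-randomized surrogate null for group contrasts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.neighbors import kneighbors_graph

from .core import BRAIN_FEATURES, CohortTable

log = logging.getLogger(__name__)


@dataclass
class MapperConfig:
    embed_dim: int = 2
    n_bins: int = 64          # total bins in the 2-D cover (8 x 8 grid)
    overlap: float = 0.70     # fractional bin overlap
    n_neighbors: int = 10     # kNN graph size for the embedding filter
    gap_bins: int = 10        # histogram bins for the clustering gap heuristic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim != 2:
            raise ValueError("only 2-D covers are supported")
        side = round(self.n_bins ** 0.5)
        if side * side != self.n_bins:
            raise ValueError("n_bins must be a perfect square for a 2-D grid")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")

    @property
    def bins_per_axis(self) -> int:
        return round(self.n_bins ** 0.5)


@dataclass
class MapperGraph:
    """Nodes are clusters of input rows; edges join nodes sharing a row."""

    nodes: list[tuple[int, frozenset]]      # (bin id, member row indices)
    edges: set[tuple[int, int]]             # indices into ``nodes``
    row_labels: list = field(default_factory=list)
    coords: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, (bin_id, members) in enumerate(self.nodes):
            g.add_node(idx, bin=bin_id,
                       members=",".join(str(m) for m in sorted(members)))
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# delta matrix
# ---------------------------------------------------------------------------

def delta_matrix(
    cohort: CohortTable,
    stress_group: str,
    naive_group: str = "naive",
    features=BRAIN_FEATURES,
) -> pd.DataFrame:
    """Rows = (area, feature), columns = stressed animals; entries are each
    animal's value minus the naive-group mean for that row.

    Missing cells are filled by linear interpolation along the row order
    within each animal column; rows with no naive observations are dropped.
    """
    groups = cohort.group_of()
    stressed = [a for a in cohort.animals if groups[a] == stress_group]
    naives = [a for a in cohort.animals if groups[a] == naive_group]
    if not stressed or not naives:
        raise ValueError(
            f"groups not found in cohort: {stress_group!r} / {naive_group!r}")
    wide = cohort.wide(sites=cohort.areas, features=features)
    rows = [(a, f) for a in cohort.areas for f in features
            if (a, f) in wide.columns]
    naive_mean = wide.loc[naives, rows].mean(axis=0, skipna=True)
    dropped = naive_mean.index[naive_mean.isna()]
    if len(dropped):
        log.warning("dropping %d rows with no naive observations", len(dropped))
        rows = [r for r in rows if r not in set(dropped)]
        naive_mean = naive_mean[rows]
    delta = wide.loc[stressed, rows].T - naive_mean.to_numpy()[:, None]
    delta = delta.interpolate(axis=0, limit_direction="both")
    delta.index = pd.MultiIndex.from_tuples(rows, names=["area", "feature"])
    return delta


# ---------------------------------------------------------------------------
# filter / embedding
# ---------------------------------------------------------------------------

def embed(data, config: MapperConfig | None = None) -> np.ndarray:
    """Neighborhood-preserving 2-D filter coordinates for each row.

    Spectral embedding of the symmetrized kNN graph of the rows: the two
    nontrivial eigenvectors of the normalized graph Laplacian.  Fully
    deterministic (dense eigendecomposition with a fixed sign convention),
    and local neighborhoods map to nearby filter values.
    """
    config = config or MapperConfig()
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D row matrix")
    n = x.shape[0]
    if n < 10:
        raise ValueError("need >=10 rows to embed")
    if np.allclose(x, x[0]):
        raise ValueError("constant data: no variance to embed")
    # identical rows must get identical filter values: embed unique rows and
    # broadcast the coordinates back
    unique, inverse = np.unique(x, axis=0, return_inverse=True)
    if unique.shape[0] < n:
        sub_config = MapperConfig(
            n_bins=config.n_bins, overlap=config.overlap,
            n_neighbors=min(config.n_neighbors, max(unique.shape[0] - 1, 1)),
            gap_bins=config.gap_bins, seed=config.seed)
        if unique.shape[0] >= 3:
            return _embed_rows(unique, sub_config)[inverse]
    return _embed_rows(x, config)


def _embed_rows(x: np.ndarray, config: MapperConfig) -> np.ndarray:
    n = x.shape[0]
    k = min(config.n_neighbors, n - 1)
    conn = kneighbors_graph(x, n_neighbors=k, mode="connectivity")
    w = np.asarray((conn + conn.T).todense())
    w[w > 0] = 1.0
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(lap)
    coords = vecs[:, 1:3] * d_inv_sqrt[:, None]
    # fix eigenvector sign so the output is reproducible run to run
    for c in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, c]))
        if coords[pivot, c] < 0:
            coords[:, c] = -coords[:, c]
    return coords


# ---------------------------------------------------------------------------
# cover + partial clustering
# ---------------------------------------------------------------------------

def _axis_bins(values: np.ndarray, n: int, overlap: float):
    """Overlapping 1-D intervals: base cells of width R/n stretched so that
    consecutive intervals share ``overlap`` of their length."""
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    if span == 0:
        span = 1.0
    base = span / n
    length = base / (1.0 - overlap) if overlap > 0 else base
    intervals = []
    for i in range(n):
        center = lo + (i + 0.5) * base
        intervals.append((center - length / 2.0, center + length / 2.0))
    return intervals


def _members_of(values: np.ndarray, interval, last: bool) -> np.ndarray:
    lo, hi = interval
    if last:
        return np.where((values >= lo) & (values <= hi))[0]
    return np.where((values >= lo) & (values < hi))[0]


def _gap_cut(link: np.ndarray, n_points: int, gap_bins: int) -> np.ndarray:
    """Classic Mapper heuristic: histogram the merge distances; cut the
    dendrogram at the first empty histogram bin."""
    heights = link[:, 2]
    hist, edges = np.histogram(heights, bins=gap_bins)
    cut = None
    for b in range(len(hist)):
        if hist[b] == 0:
            cut = edges[b]
            break
    if cut is None:
        return np.ones(n_points, dtype=int)
    return hierarchy.fcluster(link, t=cut, criterion="distance")


def build_mapper(coords, data, config: MapperConfig | None = None,
                 row_labels=None) -> MapperGraph:
    """Overlapping 2-D binning of the filter values, single-linkage partial
    clustering of each bin's rows on their original high-dimensional values,
    and edges between nodes sharing any row."""
    config = config or MapperConfig()
    coords = np.asarray(coords, dtype=float)
    x = np.asarray(data, dtype=float)
    if coords.shape[0] == 0:
        return MapperGraph(nodes=[], edges=set(), row_labels=row_labels or [],
                           coords=coords)
    side = config.bins_per_axis
    ax0 = _axis_bins(coords[:, 0], side, config.overlap)
    ax1 = _axis_bins(coords[:, 1], side, config.overlap)

    nodes: list[tuple[int, frozenset]] = []
    for bi, iv0 in enumerate(ax0):
        m0 = _members_of(coords[:, 0], iv0, last=bi == side - 1)
        if m0.size == 0:
            continue
        for bj, iv1 in enumerate(ax1):
            m1 = _members_of(coords[m0, 1], iv1, last=bj == side - 1)
            members = m0[m1]
            if members.size == 0:
                continue
            bin_id = bi * side + bj
            if members.size == 1:
                nodes.append((bin_id, frozenset(members.tolist())))
                continue
            sub = x[members]
            d = pdist(sub)
            if np.all(d == 0):
                nodes.append((bin_id, frozenset(members.tolist())))
                continue
            link = hierarchy.linkage(d, method="single")
            labels = _gap_cut(link, members.size, config.gap_bins)
            for lab in np.unique(labels):
                nodes.append((bin_id,
                              frozenset(members[labels == lab].tolist())))

    edges: set[tuple[int, int]] = set()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i][1] & nodes[j][1]:
                edges.add((i, j))
    return MapperGraph(nodes=nodes, edges=edges,
                       row_labels=list(row_labels) if row_labels is not None
                       else list(range(x.shape[0])),
                       coords=coords)


# ---------------------------------------------------------------------------
# participation coefficient
# ---------------------------------------------------------------------------

def node_communities(graph: MapperGraph, communities: dict) -> list:
    """Community per node: majority community of its member rows' labels,
    ties broken by the community of the lowest row index."""
    def comm_of(label):
        if label in communities:
            return communities[label]
        return communities[_row_area(label)]

    out = []
    for _, members in graph.nodes:
        ordered = sorted(members)
        comms = [comm_of(graph.row_labels[r]) for r in ordered]
        counts = Counter(comms)
        best = max(counts.values())
        tied = {c for c, v in counts.items() if v == best}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            out.append(next(c for c in comms if c in tied))
    return out


def _row_area(label):
    return label[0] if isinstance(label, tuple) else label


def participation_coefficient(
    graph: MapperGraph, communities: dict
) -> tuple[np.ndarray, float]:
    """PC_i = 1 - sum_s (kappa_is / k_i)^2 over communities s.

    Node communities come from majority row labels.  Isolated nodes get
    PC = 0; the graph-level value is the mean over non-isolated nodes.
    """
    if not communities:
        raise ValueError("empty community mapping")
    node_comm = node_communities(graph, communities)
    n = graph.n_nodes
    pc = np.zeros(n)
    degrees = np.zeros(n, dtype=int)
    links: list[Counter] = [Counter() for _ in range(n)]
    for i, j in graph.edges:
        degrees[i] += 1
        degrees[j] += 1
        links[i][node_comm[j]] += 1
        links[j][node_comm[i]] += 1
    for i in range(n):
        if degrees[i] == 0:
            pc[i] = 0.0
            continue
        pc[i] = 1.0 - sum((k / degrees[i]) ** 2 for k in links[i].values())
    non_isolated = degrees > 0
    mean_pc = float(pc[non_isolated].mean()) if non_isolated.any() else 0.0
    return pc, mean_pc


def mapper_pc(delta: pd.DataFrame, communities: dict,
              config: MapperConfig | None = None) -> float:
    """Convenience: delta matrix -> embed -> Mapper -> graph-mean PC."""
    config = config or MapperConfig()
    coords = embed(delta.to_numpy(), config)
    graph = build_mapper(coords, delta.to_numpy(), config,
                         row_labels=list(delta.index))
    _, mean_pc = participation_coefficient(graph, communities)
    return mean_pc


# ---------------------------------------------------------------------------
# phase-randomized null
# ---------------------------------------------------------------------------

def phase_randomize(data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier phase randomization along the row dimension with identical
    random phases for every column: preserves the cross-column (cross-mouse)
    covariance while destroying the regional (row) structure."""
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    f = np.fft.rfft(x, axis=0)
    n_freq = f.shape[0]
    phases = np.zeros(n_freq)
    hi = n_freq - 1 if n % 2 == 0 else n_freq
    phases[1:hi] = rng.uniform(0.0, 2.0 * np.pi, size=max(hi - 1, 0))
    f = f * np.exp(1j * phases)[:, None]
    return np.fft.irfft(f, n=n, axis=0)


def phase_randomized_null(
    delta_a: pd.DataFrame,
    delta_b: pd.DataFrame,
    communities: dict,
    config: MapperConfig | None = None,
    n_null: int = 1000,
    seed: int = 0,
) -> dict:
    """Two-sided surrogate test of the group difference in graph-mean PC.

    Surrogates phase-randomize each group's delta matrix (same phases across
    mice within a group), re-run Mapper + PC, and compare |observed
    difference| against the surrogate-difference distribution.
    """
    if n_null < 100:
        log.warning("n_null=%d is low; p-value resolution is coarse", n_null)
    config = config or MapperConfig()
    rng = np.random.default_rng(seed)
    pc_a = mapper_pc(delta_a, communities, config)
    pc_b = mapper_pc(delta_b, communities, config)
    observed = pc_a - pc_b
    null = np.empty(n_null)
    for t in range(n_null):
        sa = pd.DataFrame(phase_randomize(delta_a.to_numpy(), rng),
                          index=delta_a.index)
        sb = pd.DataFrame(phase_randomize(delta_b.to_numpy(), rng),
                          index=delta_b.index)
        null[t] = mapper_pc(sa, communities, config) - \
            mapper_pc(sb, communities, config)
    p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (n_null + 1)
    rel_change = (pc_b - pc_a) / pc_b if pc_b != 0 else np.nan
    return {"pc_a": pc_a, "pc_b": pc_b, "observed_diff": observed,
            "relative_change": rel_change, "null": null, "p": p}
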