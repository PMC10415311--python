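import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression

from mitonet import mapper, synthetic
from mitonet.mapper import MapperConfig, MapperGraph


class TestConfig:
    def test_non_square_bins_rejected(self):
        with pytest.raises(ValueError):
            MapperConfig(n_bins=60)

    def test_overlap_bounds(self):
        with pytest.raises(ValueError):
            MapperConfig(overlap=1.0)

    def test_default_grid(self):
        assert MapperConfig().bins_per_axis == 8


class TestDeltaMatrix:
    def test_shape_and_zero_column(self, small_cohort):
        delta = mapper.delta_matrix(small_cohort, "CSDS")
        groups = small_cohort.group_of()
        n_csds = (groups == "CSDS").sum()
        assert delta.shape == (102, n_csds)

    def test_naive_mean_animal_gives_zero_column(self):
        config = synthetic.SyntheticConfig(n_per_group=4, missing_rate=0.0,
                                           seed=1)
        cohort = synthetic.generate_cohort(config)
        wide = cohort.wide(sites=cohort.areas)
        groups = cohort.group_of()
        naive = [a for a in wide.index if groups[a] == "naive"]
        clone = wide.loc[naive].mean()
        data = cohort.data.copy()
        extra = []
        for (site, feat), val in clone.items():
            extra.append(("clone", "CSDS", site, "brain", feat, val))
        data = pd.concat(
            [data, pd.DataFrame(extra, columns=data.columns)],
            ignore_index=True)
        from mitonet.core import CohortTable
        cohort2 = CohortTable(data=data, areas=cohort.areas,
                              tissues=cohort.tissues)
        delta = mapper.delta_matrix(cohort2, "CSDS")
        np.testing.assert_allclose(delta["clone"], 0.0, atol=1e-9)

    def test_midpoint_interpolation(self):
        config = synthetic.SyntheticConfig(n_per_group=4, missing_rate=0.0,
                                           seed=2)
        cohort = synthetic.generate_cohort(config)
        animal = [a for a in cohort.animals
                  if cohort.group_of()[a] == "CSDS"][0]
        delta_full = mapper.delta_matrix(cohort, "CSDS")
        # knock out the middle of three consecutive rows for one animal
        row = delta_full.index[5]
        data = cohort.data.copy()
        mask = ((data.animal_id == animal) & (data.site == row[0]) &
                (data.feature == row[1]))
        data.loc[mask, "value"] = np.nan
        from mitonet.core import CohortTable
        cohort2 = CohortTable(data=data, areas=cohort.areas,
                              tissues=cohort.tissues)
        delta = mapper.delta_matrix(cohort2, "CSDS")
        expected = (delta_full.iloc[4][animal] + delta_full.iloc[6][animal]) / 2
        assert delta.iloc[5][animal] == pytest.approx(expected)


class TestEmbed:
    def test_deterministic(self, rng):
        x = rng.standard_normal((30, 6))
        c1 = mapper.embed(x, MapperConfig(seed=4))
        c2 = mapper.embed(x, MapperConfig(seed=4))
        np.testing.assert_array_equal(c1, c2)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mapper.embed(np.ones((20, 5)))

    def test_duplicated_rows_coincident(self, rng):
        base = rng.standard_normal((10, 4))
        x = np.vstack([base, base])
        coords = mapper.embed(x, MapperConfig(n_neighbors=4))
        np.testing.assert_allclose(coords[:10], coords[10:], atol=1e-8)

    def test_two_cluster_separability(self):
        # contract: well-separated clusters stay linearly separable in 2-D
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((12, 6)) + 10.0
            b = rng.standard_normal((12, 6)) - 10.0
            x = np.vstack([a, b])
            coords = mapper.embed(x, MapperConfig(n_neighbors=6))
            y = np.repeat([0, 1], 12)
            clf = LogisticRegression().fit(coords, y)
            if clf.score(coords, y) == 1.0:
                hits += 1
        assert hits >= 95


def _reference_mapper(coords, data, config):
    """Independent brute-force Mapper with the same cover and clusterer."""
    side = config.bins_per_axis
    nodes = []
    for axis_idx in [(i, j) for i in range(side) for j in range(side)]:
        members = []
        for r in range(coords.shape[0]):
            inside = True
            for ax, b in enumerate(axis_idx):
                v = coords[:, ax]
                lo, hi = v.min(), v.max()
                span = (hi - lo) or 1.0
                base = span / side
                length = base / (1 - config.overlap) if config.overlap else base
                center = lo + (b + 0.5) * base
                left, right = center - length / 2, center + length / 2
                val = coords[r, ax]
                if b == side - 1:
                    ok = left <= val <= right
                else:
                    ok = left <= val < right
                if not ok:
                    inside = False
                    break
            if inside:
                members.append(r)
        if not members:
            continue
        members = np.array(members)
        if members.size == 1:
            nodes.append(frozenset(members.tolist()))
            continue
        d = pdist(data[members])
        if np.all(d == 0):
            nodes.append(frozenset(members.tolist()))
            continue
        link = hierarchy.linkage(d, method="single")
        hist, edges = np.histogram(link[:, 2], bins=config.gap_bins)
        cut = None
        for k in range(len(hist)):
            if hist[k] == 0:
                cut = edges[k]
                break
        if cut is None:
            labels = np.ones(members.size, dtype=int)
        else:
            labels = hierarchy.fcluster(link, t=cut, criterion="distance")
        for lab in np.unique(labels):
            nodes.append(frozenset(members[labels == lab].tolist()))
    return sorted(nodes, key=sorted)


class TestBuildMapper:
    def test_zero_overlap_disjoint_cover(self, rng):
        x = rng.standard_normal((40, 5))
        config = MapperConfig(n_bins=16, overlap=0.0)
        coords = mapper.embed(x, config)
        graph = mapper.build_mapper(coords, x, config)
        counts = np.zeros(40, dtype=int)
        for _, members in graph.nodes:
            for m in members:
                counts[m] += 1
        assert (counts == 1).all()
        assert graph.edges == set()

    def test_row_sets_cover_input(self, rng):
        x = rng.standard_normal((50, 4))
        config = MapperConfig(n_bins=16, overlap=0.5)
        coords = mapper.embed(x, config)
        graph = mapper.build_mapper(coords, x, config)
        covered = set()
        for _, members in graph.nodes:
            covered |= set(members)
        assert covered == set(range(50))

    def test_identical_rows_single_cluster_per_bin(self):
        x = np.tile(np.arange(5.0), (20, 1))
        coords = np.zeros((20, 2))  # all land in the same bin stack
        config = MapperConfig(n_bins=4, overlap=0.3)
        graph = mapper.build_mapper(coords, x, config)
        for _, members in graph.nodes:
            assert len(members) == 20

    def test_matches_reference_implementation(self, rng):
        x = np.vstack([rng.standard_normal((10, 4)) + 5,
                       rng.standard_normal((10, 4)) - 5])
        config = MapperConfig(n_bins=9, overlap=0.4, n_neighbors=5)
        coords = mapper.embed(x, config)
        graph = mapper.build_mapper(coords, x, config)
        got = sorted({members for _, members in graph.nodes}, key=sorted)
        expected = _reference_mapper(coords, x, config)
        assert got == sorted(set(expected), key=sorted)


def _toy_graph(memberships, edges):
    nodes = [(i, frozenset(m)) for i, m in enumerate(memberships)]
    return MapperGraph(nodes=nodes, edges=set(edges),
                       row_labels=list(range(1 + max(
                           max(m) for m in memberships))))


class TestParticipationCoefficient:
    def test_all_links_own_community_pc_zero(self):
        graph = _toy_graph([{0}, {1}, {2}], [(0, 1), (0, 2), (1, 2)])
        comm = {0: "a", 1: "a", 2: "a"}
        pc, mean_pc = mapper.participation_coefficient(graph, comm)
        np.testing.assert_allclose(pc, 0.0)
        assert mean_pc == 0.0

    def test_four_links_four_communities(self):
        graph = _toy_graph([{0}, {1}, {2}, {3}, {4}],
                           [(0, 1), (0, 2), (0, 3), (0, 4)])
        comm = {0: "hub", 1: "a", 2: "b", 3: "c", 4: "d"}
        pc, _ = mapper.participation_coefficient(graph, comm)
        assert pc[0] == pytest.approx(0.75)

    def test_bruteforce_oracle_six_nodes(self, rng):
        memberships = [{i} for i in range(6)]
        edges = {(0, 1), (0, 2), (1, 3), (2, 4), (4, 5), (1, 2)}
        comm = {0: "x", 1: "x", 2: "y", 3: "y", 4: "z", 5: "z"}
        graph = _toy_graph(memberships, edges)
        pc, _ = mapper.participation_coefficient(graph, comm)
        # oracle: explicit edge enumeration per node
        for i in range(6):
            neigh = [j for (a, b) in edges for j in ((b,) if a == i else
                                                     (a,) if b == i else ())]
            if not neigh:
                assert pc[i] == 0.0
                continue
            ks = {}
            for j in neigh:
                cj = comm[j]
                ks[cj] = ks.get(cj, 0) + 1
            expected = 1 - sum((v / len(neigh)) ** 2 for v in ks.values())
            assert pc[i] == pytest.approx(expected)

    def test_pc_in_unit_interval_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 12))
            memberships = [{i} for i in range(n)]
            possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
            take = rng.random(len(possible)) < 0.4
            edges = {e for e, t in zip(possible, take) if t}
            comm = {i: int(rng.integers(1, 4)) for i in range(n)}
            graph = _toy_graph(memberships, edges or {(0, 1)})
            pc, mean_pc = mapper.participation_coefficient(graph, comm)
            assert ((pc >= 0) & (pc <= 1.0 + 1e-12)).all()
            assert 0.0 <= mean_pc <= 1.0

    def test_empty_community_mapping_rejected(self):
        graph = _toy_graph([{0}, {1}], [(0, 1)])
        with pytest.raises(ValueError):
            mapper.participation_coefficient(graph, {})


class TestPhaseRandomization:
    def test_covariance_preserved(self, rng):
        x = rng.standard_normal((102, 6)) @ np.diag([3, 1, 2, 1, 0.5, 1.5])
        x[:, 1] += 0.8 * x[:, 0]
        surrogate = mapper.phase_randomize(x, rng)
        c0 = np.cov(x, rowvar=False)
        c1 = np.cov(surrogate, rowvar=False)
        rel = np.linalg.norm(c1 - c0) / np.linalg.norm(c0)
        assert rel < 0.05

    def test_destroys_row_structure(self, rng):
        x = np.zeros((64, 4))
        x[:32] = 5.0  # strong block structure along rows
        x += rng.standard_normal(x.shape) * 0.1
        surrogate = mapper.phase_randomize(x, rng)
        block_diff = abs(surrogate[:32].mean() - surrogate[32:].mean())
        assert block_diff < abs(x[:32].mean() - x[32:].mean())

    def test_directional_pc_contrast(self):
        # integrated deltas (shared response) vs segregated (block-specific)
        comm = {i: i // 34 for i in range(102)}
        rng = np.random.default_rng(0)
        shared = rng.standard_normal(6)
        integrated = np.tile(shared, (102, 1)) + \
            0.2 * rng.standard_normal((102, 6))
        segregated = np.zeros((102, 6))
        for b in range(3):
            segregated[34 * b:34 * (b + 1)] = rng.standard_normal(6) * 4
        segregated += 0.2 * rng.standard_normal((102, 6))
        config = MapperConfig()
        pc_int = mapper.mapper_pc(pd.DataFrame(integrated), comm, config)
        pc_seg = mapper.mapper_pc(pd.DataFrame(segregated), comm, config)
        assert pc_int > pc_seg

    def test_null_result_fields(self, rng):
        a = pd.DataFrame(rng.standard_normal((102, 5)))
        b = pd.DataFrame(rng.standard_normal((102, 6)))
        comm = {i: i % 3 for i in range(102)}
        res = mapper.phase_randomized_null(a, b, comm, MapperConfig(),
                                           n_null=100, seed=3)
        assert 0 < res["p"] <= 1.0
        assert len(res["null"]) == 100
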