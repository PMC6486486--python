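import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import pearsonr

from synaptage import MclParams, SimConfig, arcsinh_normalize, build_graph, mcl_cluster, simulate_dataset
from synaptage.network import mcl_iterate, _normalize_columns

from conftest import one_region_table


def two_triangles_with_bridge():
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")],
        weight=1.0,
    )
    return g


def reference_mcl(graph, inflation=2.2, iterations=100):
    """Independent, loop-based MCL used as an oracle on tiny graphs.

    Works on plain dicts of column vectors rather than a dense matrix and
    reads clusters as connected components of the limit support.
    """
    nodes = sorted(graph.nodes)
    cols = {v: {u: 0.0 for u in nodes} for v in nodes}
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        cols[v][u] = cols[u][v] = w
    for v in nodes:  # self loop = max incident weight
        mx = max(cols[v].values())
        cols[v][v] = mx if mx > 0 else 1.0
    for v in nodes:  # column normalize
        s = sum(cols[v].values())
        cols[v] = {u: x / s for u, x in cols[v].items()}
    for _ in range(iterations):
        # expansion: (M @ M)[u, v] = sum_w M[u, w] M[w, v]
        new = {}
        for v in nodes:
            acc = {u: 0.0 for u in nodes}
            for w, mwv in cols[v].items():
                if mwv == 0:
                    continue
                for u, muw in cols[w].items():
                    acc[u] += muw * mwv
            new[v] = acc
        # inflation + renormalize, with light pruning
        for v in nodes:
            infl = {u: x**inflation for u, x in new[v].items()}
            s = sum(infl.values())
            new[v] = {u: (x / s if x / s >= 1e-9 else 0.0) for u, x in infl.items()}
            s2 = sum(new[v].values())
            new[v] = {u: x / s2 for u, x in new[v].items()}
        if all(
            abs(new[v][u] - cols[v][u]) < 1e-10 for v in nodes for u in nodes
        ):
            cols = new
            break
        cols = new
    # readout: attractors have recurring flow; systems merge when one attractor
    # holds mass in another's column; every node goes to its max-mass attractor
    attractors = [v for v in nodes if cols[v][v] > 1e-9]
    system = nx.Graph()
    system.add_nodes_from(attractors)
    for a in attractors:
        for b in attractors:
            if a != b and (cols[a][b] > 1e-9 or cols[b][a] > 1e-9):
                system.add_edge(a, b)
    roots = {a: min(c) for c in nx.connected_components(system) for a in c}
    groups = {}
    for v in nodes:
        masses = {a: cols[v][a] for a in attractors if cols[v][a] > 0}
        if masses:
            best = max(sorted(masses), key=lambda a: masses[a])
            groups.setdefault(roots[best], []).append(v)
        else:
            groups.setdefault(("lone", v), []).append(v)
    return sorted((sorted(c) for c in groups.values()), key=lambda c: (len(c), c))


class TestBuildGraph:
    def _table(self, rows, proteins):
        arr = np.asarray(rows, dtype=float)
        groups = {
            "young": arr[:, 0:3] if arr.shape[1] >= 9 else arr[:, [0]],
            "mid": arr[:, 3:6] if arr.shape[1] >= 9 else arr[:, [1]],
            "old": arr[:, 6:9] if arr.shape[1] >= 9 else arr[:, [2]],
        }
        return one_region_table(groups, proteins=proteins)

    def test_perfectly_correlated_pair_gets_an_edge(self):
        table = self._table([[1, 2, 3], [2, 4, 6]], ["P1", "P2"])
        g = build_graph(table, r_threshold=0.95)
        assert g.has_edge("P1", "P2")
        assert g["P1"]["P2"]["weight"] == pytest.approx(1.0)

    def test_anticorrelated_pair_excluded_by_default(self):
        table = self._table([[1, 2, 3], [3, 2, 1]], ["P1", "P2"])
        g = build_graph(table, r_threshold=0.95)
        assert not g.has_edge("P1", "P2")
        g_abs = build_graph(table, r_threshold=0.95, use_absolute=True)
        assert g_abs.has_edge("P1", "P2")

    def test_constant_vector_excluded_with_warning(self):
        table = self._table([[1, 2, 3], [5, 5, 5]], ["P1", "P2"])
        with pytest.warns(UserWarning, match="P2"):
            g = build_graph(table, r_threshold=0.9)
        assert "P2" not in g.nodes

    def test_planted_blocks_give_exactly_within_block_edges(self):
        # two blocks of 5 identical profiles + tiny noise: 2 * C(5,2) = 20 edges
        rng = np.random.default_rng(0)
        prof_a = np.array([10, 10, 10, 20, 20, 20, 40, 40, 40], dtype=float)
        prof_b = np.array([40, 40, 40, 20, 20, 20, 10, 10, 10], dtype=float)
        rows = [prof_a * (1 + 0.01 * rng.standard_normal(9)) for _ in range(5)]
        rows += [prof_b * (1 + 0.01 * rng.standard_normal(9)) for _ in range(5)]
        proteins = [f"P{i}" for i in range(10)]
        table = self._table(rows, proteins)
        g = build_graph(table, r_threshold=0.95)
        # oracle: brute-force all-pairs Pearson r
        expected = set()
        for i, j in itertools.combinations(range(10), 2):
            r, _ = pearsonr(rows[i], rows[j])
            if r >= 0.95:
                expected.add((f"P{i}", f"P{j}"))
        assert {tuple(sorted(e)) for e in g.edges} == expected
        assert len(expected) == 20

    def test_threshold_validation(self, normalized_dataset):
        _, table, _ = normalized_dataset
        with pytest.raises(ValueError):
            build_graph(table, r_threshold=0.0)


class TestMclCluster:
    def test_two_triangles_with_bridge_gives_two_triangle_clusters(self):
        cs = mcl_cluster(two_triangles_with_bridge())
        assert [len(c) for c in cs.clusters] == [3, 3]
        assert cs.clusters == [["a", "b", "c"], ["d", "e", "f"]]
        assert cs.converged

    def test_agrees_with_independent_reference_implementation(self):
        rng = np.random.default_rng(5)
        graphs = [two_triangles_with_bridge(), nx.complete_graph(6), nx.karate_club_graph()]
        for seed in (1, 2, 3):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            for _, _, d in g.edges(data=True):
                d["weight"] = float(rng.uniform(0.5, 1.0))
            graphs.append(g)
        for g in graphs:
            g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
            for _, _, d in g.edges(data=True):
                d.setdefault("weight", 1.0)
            ours = sorted(mcl_cluster(g).clusters, key=lambda c: (len(c), c))
            ref = reference_mcl(g)
            assert ours == ref, f"mismatch on {g}"

    def test_edgeless_graph_gives_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(7))
        cs = mcl_cluster(g)
        assert len(cs) == 7
        assert all(len(c) == 1 for c in cs.clusters)

    def test_complete_graph_is_one_cluster(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        cs = mcl_cluster(nx.relabel_nodes(g, str))
        assert len(cs) == 1
        assert len(cs.clusters[0]) == 6

    def test_columns_stay_stochastic_every_iteration(self):
        g = two_triangles_with_bridge()
        nodes = sorted(g.nodes)
        adj = nx.to_numpy_array(g, nodelist=nodes)
        loop = adj.max(axis=1)
        adj[np.diag_indices(len(nodes))] = loop
        m = _normalize_columns(adj)
        for m_next in mcl_iterate(m, MclParams()):
            np.testing.assert_allclose(m_next.sum(axis=0), 1.0, atol=1e-9)

    def test_invariant_to_node_relabelling(self):
        g = two_triangles_with_bridge()
        mapping = {"a": "z9", "b": "m3", "c": "k1", "d": "q7", "e": "b2", "f": "a0"}
        relabelled = nx.relabel_nodes(g, mapping)
        orig = mcl_cluster(g)
        perm = mcl_cluster(relabelled)
        remapped = sorted(sorted(mapping[p] for p in c) for c in orig.clusters)
        assert sorted(sorted(c) for c in perm.clusters) == remapped

    def test_recovers_planted_blocks_in_synthetic_data(self):
        # steady_up and late_down proteins form distinct co-expression blocks
        cfg = SimConfig(n_proteins=30, n_candidates=0, replicate_cv=0.01, seed=21,
                        class_fractions={"steady_up": 0.5, "late_down": 0.5})
        table, truth = simulate_dataset(cfg)
        table = arcsinh_normalize(table)
        g = build_graph(table, region="HC", r_threshold=0.95)
        cs = mcl_cluster(g)
        blocks = {}
        for pid, cls in truth.classes("HC").items():
            blocks.setdefault(cls, set()).add(pid)
        found = {frozenset(c) for c in cs.clusters}
        assert {frozenset(b) for b in blocks.values()} == found

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.Graph())

    def test_param_validation(self):
        with pytest.raises(ValueError):
            MclParams(inflation=1.0)
        with pytest.raises(ValueError):
            MclParams(expansion=1)
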