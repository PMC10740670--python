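import itertools

import networkx as nx
import numpy as np
import pytest

from swimclass.classifier import PredictionRecord
from swimclass.evaluate import confusion_matrix
from swimclass.networks import (EffectSizeMatrix, cohens_d, compare_networks,
                                confusion_to_graph, effectsize_to_graph,
                                louvain_communities, modularity,
                                pairwise_effect_sizes)
from swimclass.trajectory import ClassLabel, ValidationError


def _partitions(nodes):
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in _partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield [[first]] + p


def exhaustive_best_partition(g):
    """Exact maximum-modularity partition by enumerating all set partitions."""
    best_q, best_p = -1.0, None
    for p in _partitions(list(g.nodes)):
        q = modularity(g, [set(c) for c in p])
        if q > best_q:
            best_q, best_p = q, p
    return best_q, [frozenset(c) for c in best_p]


def two_triangles():
    g = nx.Graph()
    for tri in [(0, 1, 2), (3, 4, 5)]:
        for u, v in itertools.combinations(tri, 2):
            g.add_edge(u, v, weight=1.0)
    return g


def block_confusion_graph():
    """7 concentration nodes, within-block rate 0.4, between 0.02."""
    blocks = [["0.5", "1.0"], ["1.5", "2.0", "2.5"], ["3.5", "4.0"]]
    nodes = [n for b in blocks for n in b]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            same = any(a in blk and b in blk for blk in blocks)
            g.add_edge(a, b, weight=0.4 if same else 0.02)
    return g, [frozenset(b) for b in blocks]


class TestLouvainOracle:
    def test_two_disconnected_triangles(self):
        g = two_triangles()
        part = louvain_communities(g, seed=0)
        assert part.modularity_q == pytest.approx(0.5)
        assert part.as_sets() == [frozenset({0, 1, 2}), frozenset({3, 4, 5})]
        oracle_q, _ = exhaustive_best_partition(g)
        assert part.modularity_q == pytest.approx(oracle_q)

    def test_block_confusion_graph_recovered_exactly(self):
        g, blocks = block_confusion_graph()
        part = louvain_communities(g, seed=0)
        assert sorted(part.as_sets(), key=sorted) == sorted(blocks, key=sorted)
        oracle_q, oracle_p = exhaustive_best_partition(g)
        assert part.modularity_q == pytest.approx(oracle_q)

    @pytest.mark.parametrize("n,graph_seed", [(5, 11), (6, 23), (7, 35), (8, 47)])
    def test_matches_exhaustive_optimum_on_small_graphs(self, n, graph_seed):
        rng = np.random.default_rng(graph_seed)
        g = nx.gnp_random_graph(n, 0.5, seed=graph_seed)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        if g.number_of_edges() == 0:
            pytest.skip("degenerate random draw")
        oracle_q, _ = exhaustive_best_partition(g)
        part = louvain_communities(g, seed=0)
        assert part.modularity_q == pytest.approx(oracle_q, abs=1e-12)

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("only")
        part = louvain_communities(g, seed=0)
        assert part.n_communities == 1 and part.modularity_q == 0.0


class TestModularity:
    def test_trivial_partition_is_zero(self):
        for g in (two_triangles(), block_confusion_graph()[0]):
            assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_true_split_of_triangles(self):
        assert modularity(two_triangles(),
                          {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}) == pytest.approx(0.5)

    def test_zero_weight_graph_defined_as_zero(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        assert modularity(g, {"a": 0, "b": 1}) == 0.0


class TestConfusionToGraph:
    A, B = ClassLabel.control(), ClassLabel.drug("ethanol", 1.0)

    def _cm(self, counts, classes):
        recs = []
        for i, t in enumerate(classes):
            for j, p in enumerate(classes):
                recs += [PredictionRecord(("f", 0), t, p, np.ones(2) / 2)] * counts[i][j]
        return confusion_matrix(recs, classes, classes)

    def test_diagonal_matrix_edgeless(self):
        g = confusion_to_graph(self._cm([[5, 0], [0, 5]], [self.A, self.B]))
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 2

    def test_uniform_two_class_single_edge_half(self):
        g = confusion_to_graph(self._cm([[5, 5], [5, 5]], [self.A, self.B]))
        assert g.number_of_edges() == 1
        assert g["control"]["ethanol_1"]["weight"] == pytest.approx(0.5)

    def test_symmetrization_averages_rates(self):
        g = confusion_to_graph(self._cm([[8, 2], [6, 4]], [self.A, self.B]))
        assert g["control"]["ethanol_1"]["weight"] == pytest.approx((0.2 + 0.6) / 2)

    def test_empty_row_rejected(self):
        cm = self._cm([[5, 5], [5, 5]], [self.A, self.B])
        cm.counts[1] = 0
        with pytest.raises(ValidationError):
            confusion_to_graph(cm)


class TestCohensD:
    def test_identical_samples_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        # pooled SD of {1,2,3} and {4,5,6} is 1, mean difference 3
        assert cohens_d([1, 2, 3], [4, 5, 6]) == pytest.approx(3.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 40)
        assert cohens_d(a, b) == cohens_d(b, a)

    def test_constant_samples(self):
        assert cohens_d([2, 2, 2], [2, 2]) == 0.0
        assert cohens_d([2, 2, 2], [3, 3]) == float("inf")

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d([1], [2, 3])


class TestEffectSizeGraph:
    def test_all_dissimilar_edgeless(self):
        m = EffectSizeMatrix(classes=["a", "b"], d=np.array([[0, 2.0], [2.0, 0]]))
        assert effectsize_to_graph(m, 0.5).number_of_edges() == 0

    def test_zero_effect_gives_threshold_weight(self):
        m = EffectSizeMatrix(classes=["a", "b"], d=np.zeros((2, 2)))
        g = effectsize_to_graph(m, 0.5)
        assert g["a"]["b"]["weight"] == pytest.approx(0.5)

    def test_hand_thresholding_three_classes(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.45], [0.9, 0.45, 0]])
        g = effectsize_to_graph(EffectSizeMatrix(["a", "b", "c"], d), 0.5)
        assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("bc")}
        assert g["b"]["c"]["weight"] == pytest.approx(0.05)

    def test_pairwise_effect_sizes_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        m = pairwise_effect_sizes({"a": rng.normal(0, 1, 50),
                                   "b": rng.normal(2, 1, 50),
                                   "c": rng.normal(0, 1, 50)})
        assert np.allclose(m.d, m.d.T) and np.all(np.diag(m.d) == 0)
        assert m.d[0, 1] > 0.5 > m.d[0, 2]


class TestCompareNetworks:
    def test_identical_graphs_delta_zero(self):
        g = two_triangles()
        rep = compare_networks(g, g.copy(), seed=0)
        assert rep["delta_q"] == 0.0

    def test_block_graph_beats_uniform_complete(self):
        g_block, _ = block_confusion_graph()
        g_uniform = nx.complete_graph(list(g_block.nodes))
        for u, v in g_uniform.edges:
            g_uniform[u][v]["weight"] = 0.2
        rep = compare_networks(g_block, g_uniform, seed=0)
        assert rep["q_confusion"] > rep["q_speed"]
        assert rep["q_speed"] == pytest.approx(0.0, abs=1e-12)

    def test_consistent_with_standalone_louvain(self):
        g, _ = block_confusion_graph()
        rep = compare_networks(g, g.copy(), seed=4)
        standalone = louvain_communities(g, seed=4)
        assert rep["partition_confusion"].community_of_node == \
            standalone.community_of_node

    def test_node_mismatch_rejected(self):
        g1, g2 = two_triangles(), nx.Graph()
        g2.add_nodes_from([0, 1])
        with pytest.raises(ValidationError):
            compare_networks(g1, g2)
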