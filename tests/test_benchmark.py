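import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crmnet import netgen
from crmnet.benchmark import (
    clrm_transform,
    infer_pearson_network,
    mcc,
    mcc_from_confusion,
    to_undirected_truth,
    topology_metrics,
)
from brute_topology import brute_metrics


class TestClrm:
    def test_ratio_mode_example(self):
        out = clrm_transform(np.array([2, 8, 0]))
        assert out == pytest.approx([0.5, 2.0, 0.0])

    def test_equal_composition(self):
        assert clrm_transform(np.array([4, 4])) == pytest.approx([1.0, 1.0])
        assert clrm_transform(np.array([4, 4]), log=True) == pytest.approx([0.0, 0.0])

    def test_zeros_pass_through_in_log_mode(self):
        out = clrm_transform(np.array([2, 8, 0]), log=True)
        assert out[2] == 0.0
        assert out[0] == pytest.approx(np.log(0.5))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            clrm_transform(np.zeros(3))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=30))
    def test_unit_geometric_mean_over_nonzero_support(self, counts):
        y = np.array(counts)
        if not y.any():
            return
        out = clrm_transform(y)
        nz = out[y != 0]
        assert np.prod(nz) == pytest.approx(1.0, rel=1e-6)


class TestPearsonInference:
    def test_perfectly_correlated_taxa_are_linked(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=40)
        Y = np.vstack([base, base, rng.integers(10, 1000, size=40)])
        inet = infer_pearson_network(Y, n_perm=200, alpha=0.05, seed=1)
        assert inet.adjacency[0, 1]
        assert inet.r[0, 1] == pytest.approx(1.0)

    def test_type_one_error_controlled_on_independent_noise(self):
        # S=10 independent taxa: the BH-corrected false-edge rate over
        # replicates must stay near or below alpha
        rates = []
        rng = np.random.default_rng(7)
        for _ in range(60):
            Y = rng.integers(1, 2000, size=(10, 100))
            inet = infer_pearson_network(Y, n_perm=200, alpha=0.05, seed=rng)
            iu = np.triu_indices(10, k=1)
            rates.append(inet.adjacency[iu].mean())
        assert np.mean(rates) <= 0.05 + 0.02

    def test_zero_variance_taxon_gains_no_edges(self):
        # an absent taxon stays zero after the transform: no variance,
        # no correlation, p forced to 1
        rng = np.random.default_rng(2)
        Y = rng.integers(10, 100, size=(4, 30))
        Y[0, :] = 0
        inet = infer_pearson_network(Y, n_perm=100, seed=3)
        assert not inet.adjacency[0].any()
        assert np.all(inet.p[0] == 1.0)
        assert np.all(inet.r[0] == 0.0)

    def test_degenerate_null_rejected(self):
        Y = np.random.default_rng(0).integers(1, 10, size=(3, 10))
        with pytest.raises(ValueError):
            infer_pearson_network(Y, n_perm=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            infer_pearson_network(np.ones((3, 2), dtype=int), n_perm=10)


class TestTruthConversion:
    def test_single_direction_collapses(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = 1
        und = to_undirected_truth(netgen.InteractionNetwork(A=A))
        assert und[0, 1] == und[1, 0] == 1
        assert und.sum() == 2

    def test_mutual_negative_is_single_edge(self, w1_network):
        und = to_undirected_truth(w1_network)
        assert und[1, 2] == und[2, 1] == 1
        assert und[0, 1] == 1

    def test_env_is_stripped(self, w1_augmented):
        und = to_undirected_truth(w1_augmented)
        assert und.shape == (3, 3)

    def test_empty_network(self):
        und = to_undirected_truth(netgen.InteractionNetwork(A=np.zeros((4, 4), int)))
        assert not und.any()


class TestMCC:
    def test_perfect_and_inverted_classifiers(self):
        truth = np.zeros((5, 5), dtype=int)
        truth[0, 1] = truth[1, 0] = 1
        assert mcc(truth, truth) == 1.0
        comp = 1 - truth
        np.fill_diagonal(comp, 0)
        assert mcc(comp, truth) == -1.0

    def test_printed_confusion_example(self):
        assert mcc_from_confusion(4, 90, 3, 3) == pytest.approx(351 / 651)

    def test_zero_denominator_convention(self):
        empty = np.zeros((4, 4), dtype=int)
        assert mcc(empty, empty) == 0.0

    def test_agrees_with_sklearn_on_random_graphs(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 10
            t = rng.random((n, n)) < 0.2
            p = rng.random((n, n)) < 0.2
            t, p = (t | t.T).astype(int), (p | p.T).astype(int)
            np.fill_diagonal(t, 0)
            np.fill_diagonal(p, 0)
            iu = np.triu_indices(n, k=1)
            expected = matthews_corrcoef(t[iu], p[iu])
            assert mcc(p, t) == pytest.approx(expected, abs=1e-12)

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcc(np.zeros((3, 3)), np.zeros((4, 4)))


def path_graph():
    a = np.zeros((3, 3), dtype=int)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return a


class TestTopologyMetrics:
    def test_path_graph(self):
        rep = topology_metrics(path_graph())
        assert rep.diameter == 2
        assert rep.radius == 1
        assert rep.mean_clustering == 0.0
        assert rep.mean_distance == pytest.approx(4 / 3)
        assert rep.betweenness.tolist() == [0.0, 1.0, 0.0]

    def test_triangle(self):
        a = 1 - np.eye(3, dtype=int)
        rep = topology_metrics(a)
        assert rep.diameter == 1 and rep.radius == 1
        assert rep.mean_distance == 1.0
        assert rep.mean_clustering == 1.0
        assert not rep.betweenness.any()

    def test_disconnected_conventions(self):
        # one edge plus an isolated node: D from the largest component,
        # radius and mean distance undefined
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = a[1, 0] = 1
        rep = topology_metrics(a)
        assert rep.diameter == 1
        assert rep.radius is None
        assert rep.mean_distance is None
        assert rep.n_components == 2

    def test_two_proper_components_have_defined_radius(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        rep = topology_metrics(a)
        assert rep.radius == 1
        assert rep.mean_distance is None

    def test_empty_graph(self):
        rep = topology_metrics(np.zeros((0, 0)))
        assert rep.diameter is None and rep.radius is None

    def test_degree_histogram(self):
        rep = topology_metrics(path_graph())
        assert rep.degree_histogram == [0, 2, 1]

    def test_matches_brute_force_oracle_on_small_graphs(self):
        # exhaustive on 4 nodes, randomised spot checks on 5-7 nodes
        cases = []
        pairs4 = list(itertools.combinations(range(4), 2))
        for bits in range(2 ** len(pairs4)):
            a = np.zeros((4, 4), dtype=int)
            for b, (i, j) in enumerate(pairs4):
                if bits >> b & 1:
                    a[i, j] = a[j, i] = 1
            cases.append(a)
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(5, 8))
            a = (rng.random((n, n)) < 0.35).astype(int)
            a = ((a + a.T) > 0).astype(int)
            np.fill_diagonal(a, 0)
            cases.append(a)
        for a in cases:
            rep = topology_metrics(a)
            ref = brute_metrics(a)
            assert rep.diameter == ref["diameter"]
            assert rep.radius == ref["radius"]
            if ref["mean_distance"] is None:
                assert rep.mean_distance is None
            else:
                assert rep.mean_distance == pytest.approx(ref["mean_distance"])
            assert rep.mean_clustering == pytest.approx(ref["clustering"])
            assert rep.betweenness == pytest.approx(ref["betweenness"])
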