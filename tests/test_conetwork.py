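import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plumedpr import conetwork, diversity


def planted_counts(seed, n_taxa=40, n_samples=400, rho=0.9, depth=10000):
    """Log-normal basis abundances with one correlated pair, multinomial reads."""
    rng = np.random.default_rng(seed)
    cov = np.eye(n_taxa)
    cov[0, 1] = cov[1, 0] = rho
    logs = rng.multivariate_normal(np.zeros(n_taxa), cov, size=n_samples)
    basis = np.exp(logs)
    fracs = basis / basis.sum(1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, f) for f in fracs])
    return pd.DataFrame(counts, columns=[f"t{i}" for i in range(n_taxa)])


def sym(mat, ids):
    return pd.DataFrame(mat, index=ids, columns=ids)


class TestSparcc:
    def test_too_few_taxa_rejected(self):
        counts = pd.DataFrame(np.ones((10, 3)))
        with pytest.raises(ValueError):
            conetwork.sparcc(counts, seed=0)

    def test_planted_pair_recovered(self):
        r = conetwork.sparcc(planted_counts(42, n_samples=200), seed=0)
        assert r.loc["t0", "t1"] == pytest.approx(0.9, abs=0.15)

    def test_independent_design_below_edge_threshold(self):
        rng = np.random.default_rng(5)
        logs = rng.normal(0, 1, (150, 30))
        basis = np.exp(logs)
        fracs = basis / basis.sum(1, keepdims=True)
        counts = np.vstack([rng.multinomial(8000, f) for f in fracs])
        r = conetwork.sparcc(pd.DataFrame(counts), seed=1).to_numpy()
        np.fill_diagonal(r, 0)
        assert np.abs(r).max() < 0.75

    def test_output_shape_and_bounds(self):
        r = conetwork.sparcc(planted_counts(0, n_taxa=6, n_samples=30),
                             seed=0)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r.to_numpy()) <= 1.0).all()


class TestBootstrapPvalues:
    def test_strong_pair_attains_minimum_p(self):
        # no bootstrap exceedance for a strongly correlated pair:
        # p = 1/(n_boot+1) = 1/101 < .01 at 100 bootstraps
        counts = planted_counts(7, n_taxa=8, n_samples=120, rho=0.95)
        r = conetwork.sparcc(counts, n_inner=5, seed=0)
        p = conetwork.bootstrap_pvalues(counts, r, n_boot=100, seed=1,
                                        n_inner=5)
        assert p.loc["t0", "t1"] == pytest.approx(1.0 / 101.0)
        assert p.loc["t0", "t1"] < 0.01

    def test_super_uniform_under_permutation_null(self):
        # independent taxa: P(p <= a) should not exceed a by much
        pooled = []
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            logs = rng.normal(0, 1, (25, 20))
            basis = np.exp(logs)
            fracs = basis / basis.sum(1, keepdims=True)
            counts = pd.DataFrame(
                np.vstack([rng.multinomial(2000, f) for f in fracs]))
            r = conetwork.sparcc(counts, n_inner=3, seed=seed)
            p = conetwork.bootstrap_pvalues(counts, r, n_boot=50,
                                            seed=seed, n_inner=3)
            arr = p.to_numpy()
            iu = np.triu_indices(arr.shape[0], k=1)
            pooled.append(arr[iu])
        pooled = np.concatenate(pooled)
        assert (pooled <= 0.10).mean() <= 0.15
        assert (pooled <= 0.02).mean() <= 0.05


class TestMetaNetwork:
    def test_threshold_rule(self):
        ids = ["a", "b", "c"]
        r = sym(np.array([[1.0, 0.80, -0.76],
                          [0.80, 1.0, 0.10],
                          [-0.76, 0.10, 1.0]]), ids)
        p = sym(np.array([[0.001, 0.005, 0.005],
                          [0.005, 0.001, 0.500],
                          [0.005, 0.500, 0.001]]), ids)
        g = conetwork.build_metanetwork(r, p)
        assert g.has_edge("a", "b") and g["a"]["b"]["sign"] == "+"
        assert g.has_edge("a", "c") and g["a"]["c"]["sign"] == "-"
        assert not g.has_edge("b", "c")

    def test_high_p_blocks_edge(self):
        ids = ["a", "b"]
        r = sym(np.array([[1.0, 0.80], [0.80, 1.0]]), ids)
        p = sym(np.array([[0.001, 0.02], [0.02, 0.001]]), ids)
        assert conetwork.build_metanetwork(r, p).number_of_edges() == 0

    def test_asymmetric_input_rejected(self):
        ids = ["a", "b"]
        r = pd.DataFrame([[1.0, 0.8], [0.2, 1.0]], index=ids, columns=ids)
        p = sym(np.full((2, 2), 0.001), ids)
        with pytest.raises(ValueError):
            conetwork.build_metanetwork(r, p)


def toy_meta():
    g = nx.Graph()
    g.add_edge("A", "B", r=0.8, p=0.001, sign="+")
    g.add_edge("A", "C", r=-0.8, p=0.001, sign="-")
    return g


class TestSubnetworks:
    def test_all_taxa_present_reproduces_meta(self):
        g = toy_meta()
        sub = conetwork.sample_subnetwork(
            g, pd.Series({"A": 0.5, "B": 0.3, "C": 0.2}))
        assert set(sub.nodes) == set(g.nodes)
        assert sub.number_of_edges() == g.number_of_edges()

    def test_partial_sample(self):
        sub = conetwork.sample_subnetwork(
            toy_meta(), pd.Series({"A": 0.5, "B": 0.3, "C": 0.0}))
        assert set(sub.nodes) == {"A", "B"}
        assert sub.number_of_edges() == 1

    def test_monotone_under_node_addition(self):
        g = toy_meta()
        small = conetwork.sample_subnetwork(g, pd.Series({"A": 1.0}))
        large = conetwork.sample_subnetwork(
            g, pd.Series({"A": 1.0, "B": 1.0, "C": 1.0}))
        assert small.number_of_nodes() <= large.number_of_nodes()
        assert small.number_of_edges() <= large.number_of_edges()


class TestTopology:
    def test_triangle(self):
        g = nx.complete_graph(3)
        m = conetwork.topology_metrics(g)
        assert (m["size"], m["connectivity"], m["mean_degree"],
                m["clustering"]) == (3, 3, 2.0, 1.0)

    def test_path(self):
        g = nx.path_graph(3)
        m = conetwork.topology_metrics(g)
        assert m["mean_degree"] == pytest.approx(4 / 3)
        assert m["clustering"] == 0.0

    def test_two_disjoint_triangles_modularity(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        m = conetwork.topology_metrics(g)
        assert m["modularity"] == pytest.approx(0.5)

    def test_empty_graph_all_zero(self):
        m = conetwork.topology_metrics(nx.Graph())
        assert m == {"size": 0, "connectivity": 0, "mean_degree": 0.0,
                     "clustering": 0.0, "modularity": 0.0}


class TestCohesion:
    def test_hand_worked_example(self):
        pos, neg, ratio = conetwork.cohesion(
            toy_meta(), pd.Series({"A": 0.5, "B": 0.3, "C": 0.2}))
        assert pos == pytest.approx(0.64)
        assert neg == pytest.approx(-0.56)
        assert ratio == pytest.approx(0.875)

    def test_all_positive_network_ratio_zero(self):
        g = nx.Graph()
        g.add_edge("A", "B", r=0.9, p=0.001, sign="+")
        pos, neg, ratio = conetwork.cohesion(
            g, pd.Series({"A": 0.5, "B": 0.5}))
        assert neg == 0.0 and ratio == 0.0

    def test_absent_taxa_contribute_nothing(self):
        pos, neg, ratio = conetwork.cohesion(
            toy_meta(), pd.Series({"A": 0.0, "B": 0.0, "C": 0.0}))
        assert pos == 0.0 and neg == 0.0

    def test_linear_in_abundance(self):
        a = pd.Series({"A": 0.5, "B": 0.3, "C": 0.2})
        pos1, neg1, _ = conetwork.cohesion(toy_meta(), a)
        pos2, neg2, _ = conetwork.cohesion(toy_meta(), a / 2)
        assert pos2 == pytest.approx(pos1 / 2)
        assert neg2 == pytest.approx(neg1 / 2)


class TestComplementarity:
    def test_hand_subtree_lengths(self, toy_tree):
        assert conetwork.complementarity(["A", "B"], toy_tree) == 3
        assert conetwork.complementarity(["A", "C"], toy_tree) == 5
        assert conetwork.complementarity(["A", "B", "C"], toy_tree) == 7

    def test_fewer_than_two_tips_is_zero(self, toy_tree):
        assert conetwork.complementarity(["A"], toy_tree) == 0.0
        assert conetwork.complementarity([], toy_tree) == 0.0

    def test_monotone_under_tip_addition(self, fixture_dataset):
        tree = fixture_dataset["tree"]
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(0)
        subset = list(rng.choice(tips, 5, replace=False))
        prev = 0.0
        for k in range(2, 6):
            cur = conetwork.complementarity(subset[:k], tree)
            assert cur >= prev - 1e-12
            prev = cur

    def test_unknown_tip_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            conetwork.complementarity(["A", "nope"], toy_tree)
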