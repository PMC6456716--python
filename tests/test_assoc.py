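import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from epiwalk.assoc import (
    AssociationNetwork,
    build_correlation_network,
    build_disease_gene_network,
    build_disease_network,
    mesh_similarity,
    pearson_pvalue,
)


class TestPearsonPvalue:
    def test_perfect_correlation(self):
        x = np.arange(38, dtype=float)
        r, p = pearson_pvalue(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_fisher_z_reference_value(self):
        """r = 0.5 at n = 38: p = 2(1 - Phi(atanh(0.5) sqrt(35)))."""
        # construct a pair with r exactly-ish 0.5 via the formula instead:
        z = np.arctanh(0.5) * np.sqrt(35)
        expected = 2 * norm.sf(z)
        assert expected == pytest.approx(0.001154, abs=2e-6)
        # and check the implementation reproduces it through its own path
        rng = np.random.default_rng(0)
        x = rng.normal(size=38)
        y = 0.5 * (x - x.mean()) / x.std() + np.sqrt(0.75) * rng.normal(size=38)
        r, p = pearson_pvalue(x, y)
        z_obs = np.arctanh(abs(r)) * np.sqrt(35)
        assert p == pytest.approx(2 * norm.sf(z_obs), rel=1e-12)

    def test_null_pvalues_uniform(self):
        """Under independence the Fisher-z p-values are ~uniform."""
        rng = np.random.default_rng(42)
        pvals = [
            pearson_pvalue(rng.normal(size=38), rng.normal(size=38))[1]
            for _ in range(1000)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_pvalue(np.ones(10), np.arange(10.0))

    def test_t_variant_close_to_fisher_z(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 38))
        _, p_z = pearson_pvalue(x, y, method="fisher_z")
        _, p_t = pearson_pvalue(x, y, method="t")
        assert p_z == pytest.approx(p_t, rel=0.2)


def _profile(rows, n_cond=38, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(rows, n_cond)), index=[f"r{i}" for i in range(rows)]
    )


class TestBuildCorrelationNetwork:
    def test_identical_profiles_all_kept(self):
        base = np.random.default_rng(3).normal(size=38)
        prof = pd.DataFrame(
            np.tile(base, (5, 1)) + 1e-9 * np.random.default_rng(4).normal(size=(5, 38)),
            index=[f"s{i}" for i in range(5)],
        )
        net = build_correlation_network(prof, layer_pair="SS", pct=100.0)
        assert net.n_edges == 10  # all C(5,2) pairs
        assert np.allclose(net.edges["weight"], 1.0, atol=1e-6)

    def test_planted_blocks_exact_recovery(self):
        """6 rows, two independent correlated triples: exactly the 6
        within-block pairs survive; brute-force check over all 15 pairs."""
        rng = np.random.default_rng(5)
        f1, f2 = rng.normal(size=(2, 38))
        rows = [f1 + 0.05 * rng.normal(size=38) for _ in range(3)]
        rows += [f2 + 0.05 * rng.normal(size=38) for _ in range(3)]
        prof = pd.DataFrame(rows, index=[f"s{i}" for i in range(6)])
        net = build_correlation_network(prof, layer_pair="SS", pct=45.0)
        got = {tuple(sorted(p)) for p in zip(net.edges["node_a"], net.edges["node_b"])}
        expected = {("s0", "s1"), ("s0", "s2"), ("s1", "s2"),
                    ("s3", "s4"), ("s3", "s5"), ("s4", "s5")}
        assert got == expected

    def test_familywise_error_control(self):
        """On pure noise, the Bonferroni gate keeps a pair in at most
        ~alpha of simulations."""
        n_hits = 0
        for seed in range(200):
            net = build_correlation_network(
                _profile(6, seed=seed), layer_pair="SS", pct=100.0
            )
            n_hits += net.n_edges > 0
        assert n_hits / 200 <= 0.05 + 0.03

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=38)
        prof = pd.DataFrame(
            [f + 0.3 * rng.normal(size=38) for _ in range(8)],
            index=[f"s{i}" for i in range(8)],
        )
        net1 = build_correlation_network(prof, layer_pair="SS", pct=60.0)
        net2 = build_correlation_network(prof.iloc[::-1], layer_pair="SS", pct=60.0)
        assert net1.n_edges > 0
        key = lambda n: sorted(
            zip(n.edges["node_a"], n.edges["node_b"], np.round(n.edges["weight"], 12))
        )
        assert key(net1) == key(net2)

    def test_cross_layer_shape_and_weights(self):
        a = _profile(4, seed=8)
        rng = np.random.default_rng(9)
        b = pd.DataFrame(
            a.to_numpy() + 0.1 * rng.normal(size=(4, 38)),
            index=[f"g{i}" for i in range(4)],
        )
        net = build_correlation_network(a, b, layer_pair="SG", pct=100.0)
        assert set(net.edges["node_a"]) <= set(a.index)
        assert set(net.edges["node_b"]) <= set(b.index)
        assert (net.edges["weight"] >= 0).all()
        # |pcc| is the weight, sign kept separately
        assert np.allclose(net.edges["weight"], net.edges["pcc"].abs())

    def test_constant_rows_skipped_with_warning(self):
        prof = _profile(5, seed=10)
        prof.iloc[0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            net = build_correlation_network(prof, layer_pair="SS", pct=100.0)
        assert "r0" not in set(net.edges["node_a"]) | set(net.edges["node_b"])


class TestMeshSimilarity:
    def test_examples(self):
        assert mesh_similarity({"A", "B"}, {"A", "B"}) == 1.0
        assert mesh_similarity({"A"}, {"B"}) == 0.0
        assert mesh_similarity({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mesh_similarity(set(), {"A"})

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        vocab = [f"T{i}" for i in range(20)]
        for _ in range(50):
            si = set(rng.choice(vocab, size=rng.integers(1, 10), replace=False))
            sj = set(rng.choice(vocab, size=rng.integers(1, 10), replace=False))
            v = mesh_similarity(si, sj)
            assert 0.0 <= v <= 1.0
            assert v == mesh_similarity(sj, si)
            assert mesh_similarity(si, si) == 1.0 >= v


class TestDiseaseNetwork:
    def test_hand_computed_weights(self):
        terms = {"d1": {"A", "B"}, "d2": {"B", "C"}, "d3": {"C", "D", "E"}}
        net = build_disease_network(terms)
        w = {
            tuple(sorted((a, b))): wt
            for a, b, wt in zip(net.edges["node_a"], net.edges["node_b"], net.edges["weight"])
        }
        assert w[("d1", "d2")] == pytest.approx(1 / 3)
        assert w[("d2", "d3")] == pytest.approx(1 / 4)
        assert ("d1", "d3") not in w  # zero similarity not stored

    def test_identical_term_sets(self):
        terms = {f"d{i}": {"X", "Y"} for i in range(4)}
        net = build_disease_network(terms)
        assert net.n_edges == 6
        assert np.allclose(net.edges["weight"], 1.0)

    def test_termless_disease_excluded(self):
        with pytest.warns(UserWarning, match="no MeSH"):
            net = build_disease_network({"d1": {"A"}, "d2": {"A"}, "d3": set()})
        assert "d3" not in net.nodes_a


class TestDiseaseGeneNetwork:
    def test_duplicates_collapse(self):
        pairs = pd.DataFrame({"disease": ["d1", "d1"], "gene": ["g1", "g1"]})
        assert build_disease_gene_network(pairs).n_edges == 1

    def test_five_pair_toy(self):
        pairs = pd.DataFrame(
            {"disease": ["d1", "d1", "d2", "d2", "d3"],
             "gene": ["g1", "g2", "g2", "g3", "g1"]}
        )
        net = build_disease_gene_network(pairs)
        assert net.n_edges == 5
        assert set(net.nodes_a) == {"d1", "d2", "d3"}
        assert set(net.nodes_b) == {"g1", "g2", "g3"}
        assert (net.edges["weight"] == 1.0).all()

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            net = build_disease_gene_network(pd.DataFrame(columns=["disease", "gene"]))
        assert net.n_edges == 0


class TestAssociationNetworkInvariants:
    def test_within_layer_adjacency_symmetric(self):
        edges = pd.DataFrame(
            {"node_a": ["b", "a"], "node_b": ["a", "c"], "weight": [0.5, 0.25]}
        )
        net = AssociationNetwork("SS", edges)
        idx = {n: i for i, n in enumerate(net.nodes_a)}
        adj = net.to_adjacency(idx).toarray()
        np.testing.assert_allclose(adj, adj.T)

    def test_self_loop_rejected(self):
        edges = pd.DataFrame({"node_a": ["a"], "node_b": ["a"], "weight": [1.0]})
        with pytest.raises(ValueError, match="self-loop"):
            AssociationNetwork("GG", edges)

    def test_unknown_endpoint_rejected(self):
        edges = pd.DataFrame({"node_a": ["a"], "node_b": ["b"], "weight": [1.0]})
        with pytest.raises(ValueError, match="universe"):
            AssociationNetwork("SS", edges, nodes_a=("a",))
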