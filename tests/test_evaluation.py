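import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from conftest import random_bipartite
from epiwalk.assoc import AssociationNetwork
from epiwalk.evaluation import (
    CVFoldPlan,
    cross_validate,
    host_gene_diagnostic,
    make_folds,
    roc_auc,
)
from epiwalk.profiles import ExpressionProfile, MethylationProfile, SiteRecord


def mannwhitney_auc(scores, labels):
    """Brute-force all-pairs AUC: wins + half-ties over pos x neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMakeFolds:
    def test_balanced_partition(self):
        net = random_bipartite(n_edges=100, seed=0)
        plan = make_folds(net, k=10, rng_seed=1)
        assert sorted(len(f) for f in plan.folds) == [10] * 10

    def test_uneven_sizes_differ_by_one(self):
        net = random_bipartite(n_edges=101, seed=1)
        plan = make_folds(net, k=10, rng_seed=1)
        sizes = sorted(len(f) for f in plan.folds)
        assert sizes == [10] * 9 + [11]

    def test_deterministic(self):
        net = random_bipartite(n_edges=60, seed=2)
        assert make_folds(net, 6, rng_seed=9) == make_folds(net, 6, rng_seed=9)

    def test_k_too_small_rejected(self):
        net = random_bipartite(n_edges=30, seed=3)
        with pytest.raises(ValueError):
            make_folds(net, k=1, rng_seed=0)

    def test_partition_enforced(self):
        with pytest.raises(ValueError, match="partition"):
            CVFoldPlan(folds=((0, 1), (1, 2)), rng_seed=0, n_edges=4)

    def test_fold_removal_reversible(self):
        net = random_bipartite(n_edges=50, seed=4)
        plan = make_folds(net, 5, rng_seed=0)
        for fold in plan.folds:
            mask = np.zeros(net.n_edges, dtype=bool)
            mask[list(fold)] = True
            restored = pd.concat([net.edges[~mask], net.edges[mask]])
            restored = restored.sort_index()
            pd.testing.assert_frame_equal(restored, net.edges)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        res = roc_auc([0.9, 0.8, 0.1], [1, 1, 0])
        assert res.auc == 1.0
        assert roc_auc([0.9, 0.8, 0.1], [0, 0, 1]).auc == 0.0

    def test_all_tied_is_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_monotone(self):
        rng = np.random.default_rng(0)
        res = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_mannwhitney_oracle(self, seed):
        """Trapezoidal midrank AUC equals the all-pairs count, with ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = roc_auc(scores, labels).auc
        assert got == pytest.approx(mannwhitney_auc(scores, labels), abs=1e-12)


class TestCrossValidate:
    def test_random_method_near_half(self, small_networks):
        plan = make_folds(small_networks["networks"]["dg"], 10, rng_seed=2)
        res = cross_validate(
            small_networks["networks"], plan, method="random", rng_seed=2
        )
        assert 0.45 <= res.auc <= 0.55

    def test_rwr_beats_baseline_beats_random(self, small_networks):
        plan = make_folds(small_networks["networks"]["dg"], 5, rng_seed=3)
        aucs = {
            m: cross_validate(small_networks["networks"], plan, method=m, rng_seed=3).auc
            for m in ("rwr", "baseline", "random")
        }
        assert aucs["rwr"] > aucs["baseline"] > aucs["random"]

    def test_unknown_method_rejected(self, small_networks):
        plan = make_folds(small_networks["networks"]["dg"], 5, rng_seed=0)
        with pytest.raises(ValueError):
            cross_validate(small_networks["networks"], plan, method="magic")

    def test_per_disease_aucs_bounded(self, small_networks):
        plan = make_folds(small_networks["networks"]["dg"], 5, rng_seed=4)
        res = cross_validate(
            small_networks["networks"], plan, method="rwr", rng_seed=4
        )
        assert res.per_disease_auc
        for auc in res.per_disease_auc.values():
            assert 0.0 <= auc <= 1.0


def _meth_expr(seed=0, n_sites=30, n_genes=20, n_cond=15, copy_host=False):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    expr_vals = rng.normal(size=(n_genes, n_cond))
    hosts = rng.integers(0, n_genes, size=n_sites)
    if copy_host:
        m_vals = expr_vals[hosts]
    else:
        m_vals = rng.normal(size=(n_sites, n_cond))
    sites = [
        SiteRecord(f"s{i}", "chr1", 0, 101, "+", genes[hosts[i]], 20)
        for i in range(n_sites)
    ]
    cond = [f"c{i}" for i in range(n_cond)]
    return (
        MethylationProfile(sites, cond, m_vals),
        ExpressionProfile(genes, cond, expr_vals),
    )


class TestHostGeneDiagnostic:
    def test_copied_profiles_have_self_corr_one(self):
        meth, expr = _meth_expr(copy_host=True)
        self_corr, null = host_gene_diagnostic(meth, expr, n_perm=50, rng_seed=0)
        np.testing.assert_allclose(self_corr, 1.0, atol=1e-9)
        assert abs(null.mean()) < 0.15

    def test_independent_profiles_match_null(self):
        """With methylation independent of expression, the self-gene
        correlations are indistinguishable from random-gene pairings."""
        meth, expr = _meth_expr(seed=3, n_sites=200, n_cond=38)
        self_corr, null = host_gene_diagnostic(meth, expr, n_perm=200, rng_seed=1)
        assert kstest(self_corr, null.ravel()).pvalue > 0.01

    def test_zero_permutations(self):
        meth, expr = _meth_expr(seed=4)
        self_corr, null = host_gene_diagnostic(meth, expr, n_perm=0, rng_seed=0)
        assert null.shape == (len(self_corr), 0)
        assert len(self_corr) == 30

    def test_missing_host_gene_skipped(self):
        meth, expr = _meth_expr(seed=5)
        meth.sites[0] = SiteRecord("s0", "chr1", 0, 101, "+", "absent", 20)
        self_corr, _ = host_gene_diagnostic(meth, expr, n_perm=0, rng_seed=0)
        assert len(self_corr) == 29
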