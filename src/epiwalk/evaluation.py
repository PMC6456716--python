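"""Cross-validated evaluation of disease-gene link recovery.

Ground truth at the site level does not exist, so the pipeline is
scored on what can be held out: known disease-gene associations.  In
each of k folds, 10% of the DG edges are removed, the transition
matrix rebuilt from the remaining 90%, and each affected disease's
held-out genes scored against that disease's never-associated genes.
The walk scores a (disease, gene) pair by the gene node's stationary
probability; the hypergeometric baseline by co-site gene overlap; the
random control by i.i.d. uniform scores.  ROC/AUC is reported pooled
over all scored pairs and per disease.

Also here: the host-gene correlation diagnostic — whether a site's
methylation profile is any more correlated with its own host gene's
expression than with a random gene's (in the motivating data it is
not, which is why the site layer carries information beyond
expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve, auc as _trapezoid_auc

from .assoc import AssociationNetwork
from .baseline import CositeGeneBaseline
from .hetnet import NodeRegistry, assemble_W
from .profiles import ExpressionProfile, MethylationProfile
from .rwr import RWRConfig, rwr_iterate

__all__ = [
    "CVFoldPlan",
    "RocResult",
    "make_folds",
    "roc_auc",
    "cross_validate",
    "host_gene_diagnostic",
]


@dataclass(frozen=True)
class CVFoldPlan:
    """Disjoint folds over DG edge indices, seed-reproducible."""

    folds: tuple[tuple[int, ...], ...]
    rng_seed: int
    n_edges: int

    def __post_init__(self) -> None:
        flat = [i for f in self.folds for i in f]
        if sorted(flat) != list(range(self.n_edges)):
            raise ValueError("folds must partition the edge set")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    per_disease_auc: dict[str, float] = field(default_factory=dict)
    scope: str = "overall"
    n_pairs: int = 0

    @property
    def mean_disease_auc(self) -> float:
        return float(np.mean(list(self.per_disease_auc.values())))

    @property
    def median_disease_auc(self) -> float:
        return float(np.median(list(self.per_disease_auc.values())))


def make_folds(dg: AssociationNetwork, k: int = 10, rng_seed: int = 0) -> CVFoldPlan:
    """Random balanced partition of the DG edges into k folds."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    n = dg.n_edges
    if n < k:
        raise ValueError(f"{n} edges cannot fill {k} folds")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    folds = tuple(tuple(int(i) for i in part) for part in np.array_split(perm, k))
    return CVFoldPlan(folds, rng_seed, n)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and trapezoidal AUC with midrank tie handling
    (equivalent to the normalized Mann-Whitney U statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def cross_validate(
    networks: dict[str, AssociationNetwork],
    plan: CVFoldPlan,
    method: str = "rwr",
    registry: NodeRegistry | None = None,
    config: RWRConfig | None = None,
    rng_seed: int = 0,
    negatives: str = "unassociated",
    column_policy: str = "redistribute",
) -> RocResult:
    """k-fold link-recovery evaluation of one scoring method.

    ``networks`` holds the five association networks under keys
    ``dd, gg, ss, dg, sg``; ``plan`` partitions the DG edges.  Per
    fold, the held-out edges are positives; negatives are, per test
    disease, its never-associated genes (``negatives='all'`` uses every
    non-positive gene including training ones).  Per-disease AUCs pool
    that disease's scores across folds and require at least one
    positive and one negative.
    """
    if method not in ("rwr", "baseline", "random"):
        raise ValueError(f"unknown method {method!r}")
    dg = networks["dg"]
    reg = registry or _registry_from(networks)
    gene_universe = reg.genes
    edges = dg.edges
    all_assoc: dict[str, set[str]] = {}
    for d, g in zip(edges["node_a"], edges["node_b"]):
        all_assoc.setdefault(d, set()).add(g)
    rng = np.random.default_rng(rng_seed)

    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    by_disease: dict[str, tuple[list[float], list[int]]] = {}

    for fold in plan.folds:
        test_mask = np.zeros(dg.n_edges, dtype=bool)
        test_mask[list(fold)] = True
        train_edges = edges[~test_mask]
        test_edges = edges[test_mask]
        dg_train = AssociationNetwork(
            "DG", train_edges.copy(), dg.nodes_a, dg.nodes_b
        )
        test_by_disease: dict[str, set[str]] = {}
        for d, g in zip(test_edges["node_a"], test_edges["node_b"]):
            test_by_disease.setdefault(d, set()).add(g)

        scorer = _make_scorer(
            method, networks, dg_train, reg, config, column_policy, rng
        )
        train_by_disease: dict[str, set[str]] = {}
        for d, g in zip(train_edges["node_a"], train_edges["node_b"]):
            train_by_disease.setdefault(d, set()).add(g)

        for disease, positives in sorted(test_by_disease.items()):
            if negatives == "unassociated":
                neg = [g for g in gene_universe if g not in all_assoc[disease]]
            else:
                neg = [g for g in gene_universe if g not in positives]
            if not neg or not positives:
                continue
            gene_scores = scorer(disease, train_by_disease.get(disease, set()))
            sc = [gene_scores[g] for g in sorted(positives)] + [
                gene_scores[g] for g in neg
            ]
            lb = [1] * len(positives) + [0] * len(neg)
            pooled_scores.extend(sc)
            pooled_labels.extend(lb)
            d_sc, d_lb = by_disease.setdefault(disease, ([], []))
            d_sc.extend(sc)
            d_lb.extend(lb)

    result = roc_auc(pooled_scores, pooled_labels)
    result.scope = "overall"
    result.n_pairs = len(pooled_scores)
    for disease, (sc, lb) in sorted(by_disease.items()):
        if 0 < sum(lb) < len(lb):
            result.per_disease_auc[disease] = roc_auc(sc, lb).auc
    return result


def _registry_from(networks: dict[str, AssociationNetwork]) -> NodeRegistry:
    from .hetnet import build_registry

    return build_registry(
        networks["dd"], networks["gg"], networks["ss"], networks["dg"], networks["sg"]
    )


def _make_scorer(method, networks, dg_train, reg, config, column_policy, rng):
    """Returns scorer(disease, train_genes) -> {gene: score}."""
    if method == "rwr":
        het = assemble_W(
            networks["dd"],
            networks["gg"],
            networks["ss"],
            dg_train,
            networks["sg"],
            registry=reg,
            column_policy=column_policy,
        )
        gslice = reg.layer_slice("G")

        def score_rwr(disease, train_genes):
            res = rwr_iterate(het, disease, config)
            probs = res.probabilities[gslice]
            return dict(zip(reg.genes, probs.tolist()))

        return score_rwr
    if method == "baseline":
        base = CositeGeneBaseline(networks["sg"], reg.genes)

        def score_baseline(disease, train_genes):
            return base.scores(train_genes)

        return score_baseline

    def score_random(disease, train_genes):
        return dict(zip(reg.genes, rng.uniform(size=len(reg.genes)).tolist()))

    return score_random


def host_gene_diagnostic(
    meth: MethylationProfile,
    expr: ExpressionProfile,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Self vs random host-gene correlation of site methylation.

    Returns ``(self_corr, null_corrs)``: per retained site, the Pearson
    correlation of its M-value profile with its host gene's expression,
    and a (sites x n_perm) null matrix where each permutation pairs
    every site with a uniformly random gene instead.  Sites whose host
    gene is missing from the expression profile are skipped.
    """
    frame = expr.to_frame()
    cond = list(meth.condition_ids)
    if list(frame.columns) != cond:
        frame = frame[cond]
    keep = [i for i, s in enumerate(meth.sites) if s.host_gene in frame.index]
    m = _standardize(meth.m_values[keep])
    g = _standardize(frame.to_numpy(dtype=float))
    gene_index = {gid: i for i, gid in enumerate(frame.index)}
    host_rows = np.array([gene_index[meth.sites[i].host_gene] for i in keep])
    n_cond = len(cond)
    self_corr = (m * g[host_rows]).sum(axis=1) / n_cond
    rng = np.random.default_rng(rng_seed)
    null = np.empty((len(keep), n_perm))
    for p in range(n_perm):
        rand_rows = rng.integers(0, g.shape[0], size=len(keep))
        null[:, p] = (m * g[rand_rows]).sum(axis=1) / n_cond
    return self_corr, null


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd
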