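"""Hypergeometric-overlap baseline predictor.

A naive alternative to network propagation: a site is associated with a
disease when the two are simultaneously linked to significantly many
common genes.  With m genes in total, n linked to the disease, x linked
to the site, and y linked to both, the upper-tail probability

    P(Y >= y) = 1 - sum_{i=0}^{y-1} C(x, i) C(m-x, n-i) / C(m, n)

under the hypergeometric distribution scores the overlap.  Only the
disease-gene and site-gene bipartite links are used — none of the
within-layer similarity structure — which is what makes it a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .assoc import AssociationNetwork

__all__ = [
    "HypergeomInput",
    "hypergeom_pvalue",
    "baseline_predict",
    "CositeGeneBaseline",
]


@dataclass(frozen=True)
class HypergeomInput:
    """Overlap counts: m total genes, n disease genes, x site genes,
    y genes linked to both."""

    m: int
    n: int
    x: int
    y: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.y <= min(self.n, self.x)
            and self.n <= self.m
            and self.x <= self.m
            and min(self.n, self.x) >= 0
        )
        if not ok:
            raise ValueError(
                f"invalid hypergeometric input m={self.m} n={self.n} x={self.x} y={self.y}"
            )
        # y cannot undercut the pigeonhole minimum overlap
        if self.y < self.n + self.x - self.m:
            raise ValueError("y below the minimum possible overlap n + x - m")


def hypergeom_pvalue(inp: HypergeomInput) -> float:
    """Upper tail P(Y >= y) of the hypergeometric overlap; 1 when y = 0."""
    if inp.y == 0:
        return 1.0
    # survival function is P(Y > y-1) = P(Y >= y)
    return float(hypergeom.sf(inp.y - 1, inp.m, inp.x, inp.n))


def baseline_predict(
    dg: AssociationNetwork,
    sg: AssociationNetwork,
    disease: str,
    gene_universe: tuple[str, ...] = (),
) -> list[tuple[str, float]]:
    """Rank every site for one disease by hypergeometric overlap p-value.

    ``gene_universe`` defaults to the union of the gene sides of the
    two networks.  Sites are ordered by ascending p-value, ties broken
    by site id; a disease with no genes gets p = 1 everywhere.
    """
    if disease not in set(dg.nodes_a):
        raise KeyError(f"unknown disease {disease!r}")
    genes = set(gene_universe) if gene_universe else set(dg.nodes_b) | set(sg.nodes_b)
    m = len(genes)
    d_genes = set(dg.edges.loc[dg.edges["node_a"] == disease, "node_b"]) & genes
    site_genes: dict[str, set[str]] = {s: set() for s in sg.nodes_a}
    for s, g in zip(sg.edges["node_a"], sg.edges["node_b"]):
        if g in genes:
            site_genes[s].add(g)
    n = len(d_genes)
    out = []
    for site in sg.nodes_a:
        x = len(site_genes[site])
        y = len(site_genes[site] & d_genes)
        p = hypergeom_pvalue(HypergeomInput(m, n, x, y)) if n else 1.0
        out.append((site, p))
    return sorted(out, key=lambda kv: (kv[1], kv[0]))


class CositeGeneBaseline:
    """Gene-level adaptation of the hypergeometric baseline for link
    prediction on disease-gene pairs.

    The disease-site baseline has no direct score for a (disease, gene)
    pair, so the same idea is applied one hop away: gene g is scored by
    the hypergeometric overlap between the disease's (training) gene
    set and the genes co-linked with g through shared m6A sites.  Only
    the DG and SG links enter, as in the site-level baseline.  Scores
    are ``1 - p`` so larger means stronger evidence.
    """

    def __init__(self, sg: AssociationNetwork, gene_universe: tuple[str, ...]):
        from scipy import sparse

        self.genes = list(gene_universe)
        self.g_index = {g: i for i, g in enumerate(self.genes)}
        m = len(self.genes)
        s_index = {s: i for i, s in enumerate(sg.nodes_a)}
        rows = [self.g_index[g] for g in sg.edges["node_b"] if g in self.g_index]
        cols = [
            s_index[s]
            for s, g in zip(sg.edges["node_a"], sg.edges["node_b"])
            if g in self.g_index
        ]
        inc = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, len(s_index))
        ).tocsr()
        co = (inc @ inc.T).toarray() > 0  # genes sharing at least one site
        np.fill_diagonal(co, False)
        self.co = co
        self.x = co.sum(axis=1)

    def scores(self, train_genes: set[str]) -> dict[str, float]:
        """Per-gene score (1 - hypergeometric p) against one disease's
        training gene set."""
        m = len(self.genes)
        d_genes = np.zeros(m, dtype=bool)
        for g in train_genes:
            if g in self.g_index:
                d_genes[self.g_index[g]] = True
        n = int(d_genes.sum())
        if n == 0:
            return {g: 0.0 for g in self.genes}
        y = (self.co & d_genes[None, :]).sum(axis=1)
        p = np.where(y > 0, hypergeom.sf(y - 1, m, self.x, n), 1.0)
        return {g: float(1.0 - p[i]) for g, i in self.g_index.items()}
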