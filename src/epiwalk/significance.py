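"""Empirical significance by degree-preserving network randomization,
and the hyper/hypo methylation direction call.

The null model rewires each association sub-network by repeated edge
exchange: two edges a-b and c-d are replaced by a-d and c-b, but only
when neither new edge already exists and no self-loop arises, so every
node keeps its exact degree (and, for bipartite networks, its layer).
The heterogeneous network is reassembled from the rewired sub-networks
and the walk re-run; the observed probability of a (disease, site)
association is then compared against its own null sample with the
standard add-one empirical p-value, which can never be exactly zero
from a finite number of random networks.

Direction: a predicted site is called hyper-methylated under disease
when its methylation profile is positively correlated with the genes
over-expressed in that disease (or anti-correlated with the
under-expressed ones); the median of the sign-adjusted correlations
over all disease genes decides, with an exact zero reported as NA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssociationNetwork
from .hetnet import HetNet, NodeRegistry, assemble_W
from .profiles import ExpressionProfile
from .rwr import RWRConfig, rwr_iterate

__all__ = [
    "edge_swap_randomize",
    "empirical_pvalue",
    "direction_of_association",
    "permutation_null_scores",
    "DirectedPrediction",
]


@dataclass
class DirectedPrediction:
    """One scored (disease, site) call with significance and direction."""

    site_id: str
    disease_id: str
    probability: float
    empirical_p: float
    direction: str | None  # 'hyper', 'hypo', or None (undetermined)
    median_corr: float | None


def edge_swap_randomize(
    net: AssociationNetwork, rng_seed: int, swaps_per_edge: int = 10
) -> AssociationNetwork:
    """Degree-preserving rewiring by repeated edge exchange.

    Attempts ``swaps_per_edge * n_edges`` exchanges.  Each edge carries
    its weight with its first endpoint through the swap (topology is
    randomized; the weight multiset per node-a side is preserved).
    Networks too rigid to admit any swap are returned unchanged with a
    warning.
    """
    if net.n_edges < 2:
        warnings.warn("fewer than 2 edges: returning unchanged copy", stacklevel=2)
        return AssociationNetwork(
            net.layer_pair, net.edges.copy(), net.nodes_a, net.nodes_b
        )
    rng = np.random.default_rng(rng_seed)
    a = list(net.edges["node_a"])
    b = list(net.edges["node_b"])
    n = len(a)
    within = net.is_within

    def key(x: str, y: str):
        return (x, y) if not within else (min(x, y), max(x, y))

    existing = {key(x, y) for x, y in zip(a, b)}
    n_success = 0
    for _ in range(swaps_per_edge * n):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        ai, bi, aj, bj = a[i], b[i], a[j], b[j]
        if within and rng.integers(0, 2):
            # undirected edges have no intrinsic orientation; flip one
            aj, bj = bj, aj
        # proposed: ai-bj and aj-bi
        if ai == bj or aj == bi:
            continue
        k1, k2 = key(ai, bj), key(aj, bi)
        if k1 == k2 or k1 in existing or k2 in existing:
            continue
        existing.discard(key(ai, bi))
        existing.discard(key(aj, bj))
        existing.add(k1)
        existing.add(k2)
        b[i], b[j] = bj, bi
        if within:
            a[j] = aj
        n_success += 1
    if n_success == 0:
        warnings.warn("network too rigid to swap: returning unchanged copy", stacklevel=2)
    edges = net.edges.copy()
    edges["node_a"] = a
    edges["node_b"] = b
    return AssociationNetwork(net.layer_pair, edges, net.nodes_a, net.nodes_b)


def empirical_pvalue(observed: float, null_scores) -> float:
    """Add-one empirical p: (1 + #{null >= observed}) / (K + 1), in (0, 1]."""
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    return float((1 + int((null >= observed).sum())) / (null.size + 1))


def permutation_null_scores(
    networks: dict[str, AssociationNetwork],
    disease: str,
    registry: NodeRegistry,
    n_networks: int = 100,
    rng_seed: int = 0,
    swaps_per_edge: int = 10,
    config: RWRConfig | None = None,
    column_policy: str = "redistribute",
) -> np.ndarray:
    """Site-probability null sample from ``n_networks`` rewired networks.

    Each of the five sub-networks is rewired independently (preserving
    its own topology characteristics), W reassembled on the same node
    registry, and the walk re-run from ``disease``.  Returns a
    (n_sites x n_networks) matrix of site probabilities, rows ordered
    as ``registry.sites``.  Fully seeded and reproducible.
    """
    seeds = np.random.SeedSequence(rng_seed).spawn(n_networks)
    out = np.empty((len(registry.sites), n_networks))
    for k, ss_seed in enumerate(seeds):
        child = np.random.default_rng(ss_seed)
        rand_nets = {
            name: edge_swap_randomize(
                net, int(child.integers(2**31)), swaps_per_edge
            )
            for name, net in networks.items()
        }
        het = assemble_W(
            rand_nets["dd"],
            rand_nets["gg"],
            rand_nets["ss"],
            rand_nets["dg"],
            rand_nets["sg"],
            registry=registry,
            column_policy=column_policy,
        )
        res = rwr_iterate(het, disease, config)
        out[:, k] = res.probabilities[registry.layer_slice("S")]
    return out


def site_empirical_pvalues(
    observed: np.ndarray, null: np.ndarray, pooled: bool = False
) -> np.ndarray:
    """Per-site empirical p-values against the permutation null.

    Default compares each site to its own null sample (row of
    ``null``); ``pooled=True`` compares against the pooled sample of
    all sites.
    """
    observed = np.asarray(observed, dtype=float)
    if pooled:
        flat = null.ravel()
        return np.array([empirical_pvalue(o, flat) for o in observed])
    if null.shape[0] != observed.size:
        raise ValueError("null rows must match observed sites")
    return np.array(
        [empirical_pvalue(o, null[i]) for i, o in enumerate(observed)]
    )


def direction_of_association(
    site_profile,
    disease_genes,
    expr: ExpressionProfile,
    disease_gene_sign: dict[str, str] | None = None,
) -> tuple[str | None, float | None]:
    """Hyper/hypo call from the median signed correlation to disease genes.

    Correlations with genes labelled ``under`` (under-expressed in the
    disease) are sign-flipped before taking the median; positive median
    means hyper-methylation, negative hypo, exact zero NA.  Genes absent
    from the expression profile are ignored; no overlap gives NA.
    """
    site = np.asarray(site_profile, dtype=float)
    frame = expr.to_frame()
    signs = disease_gene_sign or {}
    corrs = []
    for gene in disease_genes:
        if gene not in frame.index:
            continue
        gvec = frame.loc[gene].to_numpy()
        if np.std(gvec) == 0 or np.std(site) == 0:
            continue
        c = float(np.corrcoef(site, gvec)[0, 1])
        if signs.get(gene, "over") == "under":
            c = -c
        corrs.append(c)
    if not corrs:
        return None, None
    med = float(np.median(corrs))
    if med > 0:
        return "hyper", med
    if med < 0:
        return "hypo", med
    return None, med
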