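"""Association sub-networks between and within the three node layers.

Five networks feed the heterogeneous walk:

* within-layer co-methylation (site-site, ``SS``), co-expression
  (gene-gene, ``GG``) and cross-layer methylation-expression coupling
  (site-gene, ``SG``) networks, each built from Pearson correlation
  across experimental conditions with a Fisher-z asymptotic test,
  Bonferroni control, and a top/bottom percentile cut on the
  correlation values themselves;
* disease-disease similarity (``DD``) from Jaccard overlap of MeSH
  term sets;
* the curated disease-gene bipartite network (``DG``).

Correlation sign is not distinguished in edge weights (|Pcc|), because
methylation may either enhance or repress expression; the signed
coefficient is kept alongside for the hyper/hypo direction call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm, t as t_dist

__all__ = [
    "AssociationNetwork",
    "pearson_pvalue",
    "build_correlation_network",
    "mesh_similarity",
    "build_disease_network",
    "build_disease_gene_network",
]

WITHIN_LAYER = {"DD", "GG", "SS"}
CROSS_LAYER = {"DG", "SG"}


@dataclass
class AssociationNetwork:
    """Typed weighted edge list between (or within) node layers.

    Within-layer networks (``DD``/``GG``/``SS``) are undirected: each
    edge is stored once with ``node_a < node_b``.  Cross-layer networks
    (``DG``/``SG``) have ``node_a`` in the first layer and ``node_b``
    in the second.  ``edges`` may carry extra columns (e.g. the signed
    Pearson coefficient ``pcc``); ``weight`` must be non-negative.
    """

    layer_pair: str
    edges: pd.DataFrame
    nodes_a: tuple[str, ...] = ()
    nodes_b: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.layer_pair not in WITHIN_LAYER | CROSS_LAYER:
            raise ValueError(f"unknown layer pair {self.layer_pair!r}")
        required = {"node_a", "node_b", "weight"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")
        self.edges = self.edges.reset_index(drop=True)
        if len(self.edges):
            if (self.edges["weight"].to_numpy() < 0).any():
                raise ValueError("negative edge weight")
            if self.is_within:
                if (self.edges["node_a"] == self.edges["node_b"]).any():
                    raise ValueError("self-loop in within-layer network")
                # canonical orientation so each undirected edge is stored once
                a = self.edges["node_a"].to_numpy()
                b = self.edges["node_b"].to_numpy()
                flip = a > b
                self.edges.loc[flip, ["node_a", "node_b"]] = np.column_stack(
                    [b[flip], a[flip]]
                )
        if not self.nodes_a:
            self.nodes_a = tuple(sorted(set(self.edges["node_a"])))
            if self.is_within:
                self.nodes_a = tuple(
                    sorted(set(self.edges["node_a"]) | set(self.edges["node_b"]))
                )
        if not self.nodes_b:
            self.nodes_b = (
                self.nodes_a
                if self.is_within
                else tuple(sorted(set(self.edges["node_b"])))
            )
        known_a, known_b = set(self.nodes_a), set(self.nodes_b)
        bad = set(self.edges["node_a"]) - known_a
        bad |= set(self.edges["node_b"]) - known_b
        if self.is_within:
            bad = (set(self.edges["node_a"]) | set(self.edges["node_b"])) - known_a
        if bad:
            raise ValueError(f"edge endpoints outside node universe: {sorted(bad)[:5]}")

    @property
    def is_within(self) -> bool:
        return self.layer_pair in WITHIN_LAYER

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        """Per-node edge count (both endpoints for within-layer networks)."""
        deg: dict[str, int] = {n: 0 for n in self.nodes_a}
        if not self.is_within:
            deg.update({n: 0 for n in self.nodes_b})
        for a, b in zip(self.edges["node_a"], self.edges["node_b"]):
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_adjacency(
        self, index_a: dict[str, int], index_b: dict[str, int] | None = None
    ) -> sparse.csr_matrix:
        """Weighted adjacency, rows indexed by ``index_a`` and columns by
        ``index_b`` (within-layer: symmetric, both sides ``index_a``)."""
        if self.is_within:
            index_b = index_a
        elif index_b is None:
            raise ValueError("cross-layer adjacency needs both indexes")
        rows = [index_a[a] for a in self.edges["node_a"]]
        cols = [index_b[b] for b in self.edges["node_b"]]
        w = self.edges["weight"].to_numpy(dtype=float)
        shape = (len(index_a), len(index_b))
        mat = sparse.coo_matrix((w, (rows, cols)), shape=shape)
        if self.is_within:
            mat = mat + mat.T
        return mat.tocsr()


def pearson_pvalue(x, y, method: str = "fisher_z") -> tuple[float, float]:
    """Pearson correlation with its two-sided asymptotic p-value.

    ``method='fisher_z'`` (default) uses the Fisher z-transform:
    z = atanh(r) * sqrt(n - 3), p = 2 * (1 - Phi(|z|)).  ``method='t'``
    uses the exact-under-normality t reference with n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("length mismatch")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    p = _corr_pvalues(np.array([r]), n, method)[0]
    return r, float(p)


def _corr_pvalues(r: np.ndarray, n: int, method: str) -> np.ndarray:
    r_cl = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    if method == "fisher_z":
        z = np.abs(np.arctanh(r_cl)) * np.sqrt(n - 3)
        return 2.0 * norm.sf(z)
    if method == "t":
        tval = np.abs(r_cl) * np.sqrt((n - 2) / (1 - r_cl**2))
        return 2.0 * t_dist.sf(tval, df=n - 2)
    raise ValueError(f"unknown method {method!r}")


def build_correlation_network(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame | None = None,
    layer_pair: str = "SS",
    alpha: float = 0.05,
    pct: float = 10.0,
    method: str = "fisher_z",
) -> AssociationNetwork:
    """Correlation network with Bonferroni and percentile thresholds.

    Tests all unordered row pairs of ``profile_a`` (within-layer) or all
    cross pairs against ``profile_b``.  A pair is kept when its
    Bonferroni-adjusted p-value (divisor = number of pairs actually
    tested; constant rows are skipped with a warning) is below ``alpha``
    AND its correlation ranks in the top or bottom ``pct`` percentile of
    all tested correlations.  Edge weight is |Pcc|; the signed Pcc is
    carried in the ``pcc`` column.
    """
    a = profile_a.to_numpy(dtype=float)
    ids_a = list(profile_a.index)
    within = profile_b is None
    if within:
        b, ids_b = a, ids_a
    else:
        if list(profile_a.columns) != list(profile_b.columns):
            raise ValueError("profiles disagree on condition columns")
        b = profile_b.to_numpy(dtype=float)
        ids_b = list(profile_b.index)
    n_cond = a.shape[1]
    if n_cond < 4:
        raise ValueError("need at least 4 conditions")

    ok_a = a.std(axis=1) > 0
    ok_b = b.std(axis=1) > 0
    n_const = int((~ok_a).sum()) + (0 if within else int((~ok_b).sum()))
    if n_const:
        warnings.warn(f"skipping {n_const} constant profile(s)", stacklevel=2)

    za = _standardize_rows(a)
    zb = za if within else _standardize_rows(b)
    corr = (za @ zb.T) / n_cond

    if within:
        iu, ju = np.triu_indices(len(ids_a), k=1)
        mask = ok_a[iu] & ok_a[ju]
        iu, ju = iu[mask], ju[mask]
    else:
        iu, ju = np.meshgrid(
            np.flatnonzero(ok_a), np.flatnonzero(ok_b), indexing="ij"
        )
        iu, ju = iu.ravel(), ju.ravel()
    pccs = corr[iu, ju]
    n_pairs = pccs.size
    if n_pairs == 0:
        warnings.warn("no testable pairs", stacklevel=2)
        return AssociationNetwork(
            layer_pair,
            pd.DataFrame(columns=["node_a", "node_b", "weight", "pcc"]),
            tuple(ids_a),
            tuple(ids_a if within else ids_b),
        )

    p_raw = _corr_pvalues(pccs, n_cond, method)
    p_adj = np.minimum(1.0, p_raw * n_pairs)
    hi = np.percentile(pccs, 100.0 - pct)
    lo = np.percentile(pccs, pct)
    kept = (p_adj < alpha) & ((pccs >= hi) | (pccs <= lo))
    if not kept.any():
        warnings.warn("no pair passed the thresholds: empty network", stacklevel=2)
    edges = pd.DataFrame(
        {
            "node_a": [ids_a[i] for i in iu[kept]],
            "node_b": [ids_b[j] for j in ju[kept]],
            "weight": np.abs(pccs[kept]),
            "pcc": pccs[kept],
        }
    )
    return AssociationNetwork(
        layer_pair, edges, tuple(ids_a), tuple(ids_a if within else ids_b)
    )


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def mesh_similarity(terms_i: set[str], terms_j: set[str]) -> float:
    """Jaccard similarity of two MeSH term sets: |i n j| / |i u j|."""
    if not terms_i or not terms_j:
        raise ValueError("empty term set")
    si, sj = set(terms_i), set(terms_j)
    return len(si & sj) / len(si | sj)


def build_disease_network(disease_terms: dict[str, set[str]]) -> AssociationNetwork:
    """Complete disease-disease similarity graph from MeSH term sets.

    All pairwise similarities are kept (no cut-off); zero-similarity
    pairs are simply not stored, which is equivalent under column
    normalization.  Diseases without terms are excluded with a warning.
    """
    termless = sorted(d for d, ts in disease_terms.items() if not ts)
    if termless:
        warnings.warn(f"excluding {len(termless)} disease(s) with no MeSH terms", stacklevel=2)
    diseases = sorted(d for d, ts in disease_terms.items() if ts)
    if len(diseases) < 2:
        raise ValueError("need at least 2 diseases with terms")
    rows = []
    for i, di in enumerate(diseases):
        for dj in diseases[i + 1 :]:
            w = mesh_similarity(disease_terms[di], disease_terms[dj])
            if w > 0:
                rows.append((di, dj, w))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    return AssociationNetwork("DD", edges, tuple(diseases))


def build_disease_gene_network(
    pairs: pd.DataFrame,
    diseases: tuple[str, ...] = (),
    genes: tuple[str, ...] = (),
) -> AssociationNetwork:
    """Unweighted disease-gene bipartite network from an id-pair table.

    ``pairs`` needs columns ``disease`` and ``gene``; duplicates
    collapse to a single edge of weight 1.
    """
    if not {"disease", "gene"}.issubset(pairs.columns):
        raise ValueError("pairs table needs 'disease' and 'gene' columns")
    if pairs.empty:
        warnings.warn("empty disease-gene table", stacklevel=2)
    dedup = pairs[["disease", "gene"]].drop_duplicates()
    edges = pd.DataFrame(
        {
            "node_a": dedup["disease"].to_numpy(),
            "node_b": dedup["gene"].to_numpy(),
            "weight": 1.0,
        }
    )
    return AssociationNetwork("DG", edges, diseases, genes)
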