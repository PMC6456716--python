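"""Assembly of the column-normalized multi-layer transition matrix.

Nodes are ordered disease block, then gene block, then site block.  The
transition matrix W is built from the five association networks, each
sub-block column-normalized independently and scaled by its layer
weight: disease columns split 1/2 : 1/2 between disease-disease and
disease-gene transitions, gene columns 1/3 : 1/3 : 1/3 between the
three gene-adjacent networks, and site columns 1/2 : 1/2 between
site-gene and site-site transitions.  The disease-site block is a
structural zero (no direct association is known a priori — inferring it
is the point of the walk).

When a node has no edges in one of its blocks, the default
``redistribute`` column policy reassigns that block's weight to the
node's remaining blocks so its column still sums to 1 and no walker
mass leaks; ``leak`` keeps the nominal weights (sub-stochastic
columns).  Fully isolated nodes keep a zero column either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .assoc import AssociationNetwork

__all__ = ["NodeRegistry", "HetNet", "column_normalize", "assemble_W"]

LAYER_WEIGHTS = {"D": 0.5, "G": 1.0 / 3.0, "S": 0.5}  # per-block weight by column layer


@dataclass(frozen=True)
class NodeRegistry:
    """Stable ordering of disease, gene, and site nodes.

    Global indices run over diseases first, then genes, then sites.
    """

    diseases: tuple[str, ...]
    genes: tuple[str, ...]
    sites: tuple[str, ...]
    index: dict[str, tuple[str, int]] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.index:
            idx: dict[str, tuple[str, int]] = {}
            for layer, names in (("D", self.diseases), ("G", self.genes), ("S", self.sites)):
                for pos, name in enumerate(names):
                    if name in idx:
                        raise ValueError(f"duplicate node id across layers: {name!r}")
                    idx[name] = (layer, pos)
            object.__setattr__(self, "index", idx)

    @property
    def n_nodes(self) -> int:
        return len(self.diseases) + len(self.genes) + len(self.sites)

    def offset(self, layer: str) -> int:
        if layer == "D":
            return 0
        if layer == "G":
            return len(self.diseases)
        if layer == "S":
            return len(self.diseases) + len(self.genes)
        raise ValueError(f"unknown layer {layer!r}")

    def global_index(self, node_id: str) -> int:
        try:
            layer, pos = self.index[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None
        return self.offset(layer) + pos

    def layer_slice(self, layer: str) -> slice:
        off = self.offset(layer)
        size = {"D": len(self.diseases), "G": len(self.genes), "S": len(self.sites)}[layer]
        return slice(off, off + size)

    def layer_index(self, layer: str) -> dict[str, int]:
        names = {"D": self.diseases, "G": self.genes, "S": self.sites}[layer]
        return {n: i for i, n in enumerate(names)}


@dataclass
class HetNet:
    """Node registry plus the sparse column-stochastic transition matrix."""

    registry: NodeRegistry
    W: sparse.csc_matrix
    column_policy: str = "redistribute"
    block_weights: dict[str, float] = field(
        default_factory=lambda: dict(LAYER_WEIGHTS)
    )

    def __post_init__(self) -> None:
        n = self.registry.n_nodes
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} != ({n}, {n})")

    def seed_vector(self, node_id: str) -> np.ndarray:
        p0 = np.zeros(self.registry.n_nodes)
        p0[self.registry.global_index(node_id)] = 1.0
        return p0

    def save(self, out_dir: str | Path) -> None:
        """Write registry, sparse triplets, and a JSON config sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for layer, names in (
            ("D", self.registry.diseases),
            ("G", self.registry.genes),
            ("S", self.registry.sites),
        ):
            rows.extend({"node_id": n, "layer": layer} for n in names)
        pd.DataFrame(rows).to_csv(out / "nodes.tsv", sep="\t", index=False)
        coo = self.W.tocoo()
        pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(
            out / "transition.tsv", sep="\t", index=False
        )
        (out / "hetnet.json").write_text(
            json.dumps(
                {"column_policy": self.column_policy, "block_weights": self.block_weights},
                indent=2,
            )
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "HetNet":
        src = Path(in_dir)
        nodes = pd.read_csv(src / "nodes.tsv", sep="\t")
        reg = NodeRegistry(
            diseases=tuple(nodes.loc[nodes["layer"] == "D", "node_id"]),
            genes=tuple(nodes.loc[nodes["layer"] == "G", "node_id"]),
            sites=tuple(nodes.loc[nodes["layer"] == "S", "node_id"]),
        )
        trip = pd.read_csv(src / "transition.tsv", sep="\t")
        n = reg.n_nodes
        W = sparse.coo_matrix(
            (trip["value"], (trip["row"], trip["col"])), shape=(n, n)
        ).tocsc()
        cfg = json.loads((src / "hetnet.json").read_text())
        return cls(reg, W, cfg["column_policy"], cfg["block_weights"])


def column_normalize(block: sparse.spmatrix | np.ndarray) -> sparse.csc_matrix:
    """Scale each nonzero column to sum 1; zero columns stay zero."""
    mat = sparse.csc_matrix(block, dtype=float)
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("negative entry in adjacency block")
    sums = np.asarray(mat.sum(axis=0)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return (mat @ sparse.diags(inv)).tocsc()


def build_registry(
    dd: AssociationNetwork,
    gg: AssociationNetwork,
    ss: AssociationNetwork,
    dg: AssociationNetwork,
    sg: AssociationNetwork,
) -> NodeRegistry:
    """Registry over the union of node universes, sorted for determinism."""
    diseases = sorted(set(dd.nodes_a) | set(dg.nodes_a))
    genes = sorted(set(gg.nodes_a) | set(dg.nodes_b) | set(sg.nodes_b))
    sites = sorted(set(ss.nodes_a) | set(sg.nodes_a))
    return NodeRegistry(tuple(diseases), tuple(genes), tuple(sites))


def assemble_W(
    dd: AssociationNetwork,
    gg: AssociationNetwork,
    ss: AssociationNetwork,
    dg: AssociationNetwork,
    sg: AssociationNetwork,
    registry: NodeRegistry | None = None,
    column_policy: str = "redistribute",
) -> HetNet:
    """Build the block transition matrix from the five association networks."""
    if column_policy not in ("redistribute", "leak"):
        raise ValueError(f"unknown column_policy {column_policy!r}")
    expected = {"DD": dd, "GG": gg, "SS": ss, "DG": dg, "SG": sg}
    for name, net in expected.items():
        if net.layer_pair != name:
            raise ValueError(f"network {name} has layer_pair {net.layer_pair!r}")
    reg = registry or build_registry(dd, gg, ss, dg, sg)
    d_idx, g_idx, s_idx = reg.layer_index("D"), reg.layer_index("G"), reg.layer_index("S")

    A_dd = dd.to_adjacency(d_idx)
    A_gg = gg.to_adjacency(g_idx)
    A_ss = ss.to_adjacency(s_idx)
    A_dg = dg.to_adjacency(d_idx, g_idx)  # diseases x genes
    A_sg = sg.to_adjacency(s_idx, g_idx)  # sites x genes

    # per column layer: row-block adjacencies (rows x columns-of-that-layer)
    d_blocks = {"D": A_dd, "G": A_dg.T}          # disease columns
    g_blocks = {"D": A_dg, "G": A_gg, "S": A_sg}  # gene columns
    s_blocks = {"G": A_sg.T, "S": A_ss}           # site columns

    cols = {
        "D": _scale_layer_columns(d_blocks, LAYER_WEIGHTS["D"], len(d_idx), column_policy),
        "G": _scale_layer_columns(g_blocks, LAYER_WEIGHTS["G"], len(g_idx), column_policy),
        "S": _scale_layer_columns(s_blocks, LAYER_WEIGHTS["S"], len(s_idx), column_policy),
    }

    grid = [[cols[c].get(r) for c in "DGS"] for r in "DGS"]
    sizes = {"D": len(d_idx), "G": len(g_idx), "S": len(s_idx)}
    for i, r in enumerate("DGS"):
        for j, c in enumerate("DGS"):
            if grid[i][j] is None:
                grid[i][j] = sparse.csc_matrix((sizes[r], sizes[c]))
    W = sparse.bmat(grid, format="csc")
    return HetNet(reg, W, column_policy)


def _scale_layer_columns(
    blocks: dict[str, sparse.spmatrix],
    weight: float,
    n_cols: int,
    policy: str,
) -> dict[str, sparse.csc_matrix]:
    """Column-normalize each row-block and apply (possibly redistributed)
    layer weights so every non-isolated column of the stack sums to 1."""
    normed = {r: column_normalize(b) for r, b in blocks.items()}
    present = {
        r: np.asarray(b.sum(axis=0)).ravel() > 0 for r, b in normed.items()
    }
    if policy == "redistribute":
        total = np.zeros(n_cols)
        for r in normed:
            total += np.where(present[r], weight, 0.0)
        out = {}
        for r, b in normed.items():
            w_eff = np.divide(
                weight, total, out=np.zeros(n_cols), where=total > 0
            )
            out[r] = (b @ sparse.diags(np.where(present[r], w_eff, 0.0))).tocsc()
        return out
    return {r: (b * weight).tocsc() for r, b in normed.items()}
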