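import numpy as np
import pandas as pd
import pytest

from epiwalk.assoc import AssociationNetwork
from epiwalk.synthetic import SynthConfig, generate


SMALL_CONFIG = SynthConfig(
    n_diseases=10,
    n_genes=60,
    n_sites=120,
    n_conditions=20,
    n_modules=4,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset reused across tests (seeded, read-only)."""
    return generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_networks(small_dataset, tmp_path_factory):
    """The five association networks built by the pipeline on the small dataset."""
    from epiwalk.pipeline import PipelineConfig, build_networks

    d = tmp_path_factory.mktemp("fixtures")
    small_dataset.write(d)
    cfg = PipelineConfig(
        site_ip_rpkm=str(d / "site_ip_rpkm.tsv"),
        site_input_rpkm=str(d / "site_input_rpkm.tsv"),
        gene_rpkm=str(d / "gene_rpkm.tsv"),
        replicate_map=str(d / "replicate_map.tsv"),
        site_table=str(d / "sites.tsv"),
        disease_gene=str(d / "disease_gene.tsv"),
        disease_mesh=str(d / "disease_mesh.tsv"),
    )
    networks, meth, expr, signs = build_networks(cfg)
    return {"networks": networks, "meth": meth, "expr": expr, "signs": signs, "dir": d}


def random_bipartite(n_a=30, n_b=40, n_edges=200, seed=0, layer_pair="DG"):
    """Random simple bipartite network fixture."""
    rng = np.random.default_rng(seed)
    seen = set()
    while len(seen) < n_edges:
        a = int(rng.integers(0, n_a))
        b = int(rng.integers(0, n_b))
        seen.add((f"a{a:03d}", f"b{b:03d}"))
    edges = pd.DataFrame(sorted(seen), columns=["node_a", "node_b"])
    edges["weight"] = 1.0
    return AssociationNetwork(layer_pair, edges)


def random_within(n=40, n_edges=150, seed=0, layer_pair="SS", weighted=False):
    """Random simple undirected network fixture (canonical edges, no loops)."""
    rng = np.random.default_rng(seed)
    seen = set()
    while len(seen) < n_edges:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        seen.add((f"n{i:03d}", f"n{j:03d}"))
    edges = pd.DataFrame(sorted(seen), columns=["node_a", "node_b"])
    edges["weight"] = rng.uniform(0.1, 1.0, size=len(edges)) if weighted else 1.0
    return AssociationNetwork(layer_pair, edges)


def random_column_stochastic(n, seed, density=0.2):
    """Random column-stochastic matrix (every column has support)."""
    rng = np.random.default_rng(seed)
    mat = rng.random((n, n)) * (rng.random((n, n)) < density)
    # guarantee a nonzero in every column
    mat[rng.integers(0, n, size=n), np.arange(n)] += rng.random(n) + 0.1
    return mat / mat.sum(axis=0)
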