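"""Build the three-layer heterogeneous network and rank m6A sites for
one disease with the random walk with restart.

The transition matrix couples disease-disease (MeSH Jaccard),
gene-gene and site-site co-expression/co-methylation, disease-gene and
site-gene networks; the walker starts at a disease node and its
stationary distribution over site nodes is the association ranking."""

import tempfile
from pathlib import Path

from epiwalk import assemble_W, build_registry, rank_sites, rwr_iterate
from epiwalk.pipeline import PipelineConfig, build_networks
from epiwalk.synthetic import SynthConfig, generate

data = generate(SynthConfig(n_diseases=8, n_genes=60, n_sites=150,
                            n_conditions=20, n_modules=4, rng_seed=2))
with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp)
    data.write(d)
    cfg = PipelineConfig(
        site_ip_rpkm=str(d / "site_ip_rpkm.tsv"),
        site_input_rpkm=str(d / "site_input_rpkm.tsv"),
        gene_rpkm=str(d / "gene_rpkm.tsv"),
        replicate_map=str(d / "replicate_map.tsv"),
        site_table=str(d / "sites.tsv"),
        disease_gene=str(d / "disease_gene.tsv"),
        disease_mesh=str(d / "disease_mesh.tsv"),
    )
    networks, meth, expr, _ = build_networks(cfg)

for name, net in networks.items():
    print(f"{name.upper()} network: {net.n_edges} edges")

order = ["dd", "gg", "ss", "dg", "sg"]
registry = build_registry(*[networks[k] for k in order])
het = assemble_W(*[networks[k] for k in order], registry=registry)
print(f"transition matrix: {het.W.shape[0]} nodes, {het.W.nnz} nonzeros")

disease = registry.diseases[0]
result = rwr_iterate(het, disease)
print(f"walk from {disease}: converged in {result.iterations} iterations")

truth_sites = set(data.truth.loc[data.truth["disease"] == disease, "site_id"])
print(f"top 5 sites (planted truth marked *):")
for site_id, prob in rank_sites(result, registry)[:5]:
    mark = "*" if site_id in truth_sites else " "
    print(f"  {mark} {site_id}  p_stationary = {prob:.5f}")
# High-probability sites sit in the same co-regulation module as the
# disease's known genes — the association the walk is meant to surface.
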