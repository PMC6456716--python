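"""Empirical significance and hyper/hypo direction for predicted sites.

Rewires each association network by degree-preserving edge exchange,
re-runs the walk on 30 such null networks, and compares each site's
observed probability to its null sample; then calls the methylation
direction from the median signed correlation to the disease's genes."""

import tempfile
import warnings
from pathlib import Path

import numpy as np

# tiny demo networks are dense enough that some rewires find no legal
# swap; the library warns and keeps the network unchanged
warnings.filterwarnings("ignore", message=".*rigid.*")

from epiwalk import (
    assemble_W,
    build_registry,
    direction_of_association,
    permutation_null_scores,
    rwr_iterate,
    site_empirical_pvalues,
)
from epiwalk.pipeline import PipelineConfig, build_networks
from epiwalk.synthetic import SynthConfig, generate

data = generate(SynthConfig(n_diseases=6, n_genes=50, n_sites=100,
                            n_conditions=20, n_modules=4, rng_seed=3))
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
    networks, meth, expr, signs = build_networks(cfg)

order = ["dd", "gg", "ss", "dg", "sg"]
registry = build_registry(*[networks[k] for k in order])
het = assemble_W(*[networks[k] for k in order], registry=registry)

disease = registry.diseases[0]
observed = rwr_iterate(het, disease).probabilities[registry.layer_slice("S")]
null = permutation_null_scores(networks, disease, registry,
                               n_networks=30, rng_seed=42)
pvals = site_empirical_pvalues(observed, null)

meth_frame = meth.to_frame()
dg = networks["dg"]
disease_genes = sorted(dg.edges.loc[dg.edges["node_a"] == disease, "node_b"])
sign_map = {g: signs.get((disease, g), "over") for g in disease_genes}

top = np.argsort(-observed)[:5]
print(f"{disease}: top 5 sites with empirical p (30 null networks) and direction")
for i in top:
    site_id = registry.sites[i]
    direction, med = direction_of_association(
        meth_frame.loc[site_id].to_numpy(), disease_genes, expr, sign_map
    )
    print(f"  {site_id}  p_stat={observed[i]:.5f}  p_emp={pvals[i]:.3f}  "
          f"direction={direction or 'NA'} (median corr {med:+.2f})")
# Small empirical p: the site's probability is not explained by the
# degree structure alone.  hyper = methylation expected to rise under
# the disease, hypo = expected to fall.
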