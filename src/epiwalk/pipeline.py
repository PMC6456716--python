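"""End-to-end orchestration: profiles -> networks -> walk -> report.

``run_pipeline`` wires the stages together with one configuration
object whose defaults are the method's published operating point
(support > 10, 70/80 percentile filters, Bonferroni alpha 0.05 with a
10-percentile correlation cut, restart probability 0.75, tolerance
1e-10, 100 random networks, top-100 report at significance 0.1) and
writes a reproducibility manifest next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import (
    AssociationNetwork,
    build_correlation_network,
    build_disease_gene_network,
    build_disease_network,
)
from .hetnet import HetNet, assemble_W, build_registry
from .io import (
    read_disease_gene,
    read_disease_terms,
    read_rpkm_table,
    read_site_table,
    write_edge_list,
)
from .profiles import (
    expression_profile_from_rpkm,
    filter_sites,
    methylation_profile_from_rpkm,
)
from .rwr import RWRConfig, rank_sites, rwr_iterate
from .significance import (
    direction_of_association,
    permutation_null_scores,
    site_empirical_pvalues,
)

logger = logging.getLogger("epiwalk")

__all__ = ["PipelineConfig", "run_pipeline", "build_networks"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the published operating point."""

    # inputs
    site_ip_rpkm: str = ""
    site_input_rpkm: str = ""
    gene_rpkm: str = ""
    replicate_map: str = ""
    site_table: str = ""
    disease_gene: str = ""
    disease_mesh: str = ""
    # site filters
    min_support: int = 10
    level_pct: float = 70.0
    var_pct: float = 80.0
    level_rule: str = "le_pct"
    normalize_on: str = "m_values"
    # correlation networks
    alpha: float = 0.05
    pct: float = 10.0
    corr_test: str = "fisher_z"
    # walk
    restart_prob: float = 0.75
    tol: float = 1e-10
    max_iter: int = 1000
    column_policy: str = "redistribute"
    # significance + report
    n_random_networks: int = 100
    swaps_per_edge: int = 10
    top_k: int = 100
    significance_level: float = 0.1
    rng_seed: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def build_networks(config: PipelineConfig):
    """Stage 1-2: profiles and the five association networks.

    Returns ``(networks, meth, expr, signs)`` where ``networks`` maps
    ``dd/gg/ss/dg/sg`` to association networks.
    """
    rep = config.replicate_map or None
    logger.info("loading RPKM tables and annotations")
    ip = read_rpkm_table(config.site_ip_rpkm, rep)
    inp = read_rpkm_table(config.site_input_rpkm, rep)
    gene_tab = read_rpkm_table(config.gene_rpkm, rep)
    sites = read_site_table(config.site_table)
    dg_pairs, signs = read_disease_gene(config.disease_gene)
    terms = read_disease_terms(config.disease_mesh)

    meth = methylation_profile_from_rpkm(
        ip, inp, sites, normalize=True, normalize_on=config.normalize_on
    )
    meth = filter_sites(
        meth,
        min_support=config.min_support,
        level_pct=config.level_pct,
        var_pct=config.var_pct,
        level_rule=config.level_rule,
    )
    logger.info("retained %d sites after filtering", len(meth.sites))
    expr = expression_profile_from_rpkm(gene_tab)

    meth_frame = meth.to_frame()
    expr_frame = expr.to_frame()
    ss = build_correlation_network(
        meth_frame, layer_pair="SS", alpha=config.alpha, pct=config.pct,
        method=config.corr_test,
    )
    gg = build_correlation_network(
        expr_frame, layer_pair="GG", alpha=config.alpha, pct=config.pct,
        method=config.corr_test,
    )
    sg = build_correlation_network(
        meth_frame, expr_frame, layer_pair="SG", alpha=config.alpha,
        pct=config.pct, method=config.corr_test,
    )
    dd = build_disease_network(terms)
    dg = build_disease_gene_network(dg_pairs)
    logger.info(
        "network sizes: DD %d, GG %d, SS %d, DG %d, SG %d edges",
        dd.n_edges, gg.n_edges, ss.n_edges, dg.n_edges, sg.n_edges,
    )
    networks = {"dd": dd, "gg": gg, "ss": ss, "dg": dg, "sg": sg}
    return networks, meth, expr, signs


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    diseases: list[str] | None = None,
    with_significance: bool = True,
) -> Path:
    """Run the full prediction workflow and write one output directory.

    Per disease: ranked site probabilities, empirical p-values from the
    permutation null (when ``with_significance``), and hyper/hypo
    direction calls; plus the serialized network and a run manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    networks, meth, expr, signs = build_networks(config)
    net_dir = out / "network"
    net_dir.mkdir(exist_ok=True)
    for name, net in networks.items():
        write_edge_list(net, net_dir / f"{name}.tsv")

    registry = build_registry(*[networks[k] for k in ("dd", "gg", "ss", "dg", "sg")])
    het = assemble_W(
        *[networks[k] for k in ("dd", "gg", "ss", "dg", "sg")],
        registry=registry,
        column_policy=config.column_policy,
    )
    het.save(net_dir)
    rwr_cfg = RWRConfig(config.restart_prob, config.tol, config.max_iter)

    meth_frame = meth.to_frame()
    dg = networks["dg"]
    disease_genes: dict[str, list[str]] = {}
    for d, g in zip(dg.edges["node_a"], dg.edges["node_b"]):
        disease_genes.setdefault(d, []).append(g)

    target = diseases or list(registry.diseases)
    pred_dir = out / "predictions"
    pred_dir.mkdir(exist_ok=True)
    site_pos = {s: i for i, s in enumerate(registry.sites)}
    for disease in target:
        logger.info("predicting for %s", disease)
        res = rwr_iterate(het, disease, rwr_cfg)
        ranked = rank_sites(res, registry)
        table = pd.DataFrame(ranked, columns=["site_id", "probability"])
        table["rank"] = np.arange(1, len(table) + 1)
        if with_significance:
            null = permutation_null_scores(
                networks,
                disease,
                registry,
                n_networks=config.n_random_networks,
                rng_seed=config.rng_seed,
                swaps_per_edge=config.swaps_per_edge,
                config=rwr_cfg,
                column_policy=config.column_policy,
            )
            observed = res.probabilities[registry.layer_slice("S")]
            pvals = site_empirical_pvalues(observed, null)
            table["empirical_p"] = [
                pvals[site_pos[s]] for s in table["site_id"]
            ]
            table = table[
                (table["rank"] <= config.top_k)
                & (table["empirical_p"] < config.significance_level)
            ]
        else:
            table = table[table["rank"] <= config.top_k]
        genes_d = disease_genes.get(disease, [])
        sign_d = {g: signs.get((disease, g), "over") for g in genes_d}
        directions, medians = [], []
        for site_id in table["site_id"]:
            if site_id in meth_frame.index and genes_d:
                direction, med = direction_of_association(
                    meth_frame.loc[site_id].to_numpy(), genes_d, expr, sign_d
                )
            else:
                direction, med = None, None
            directions.append(direction if direction else "NA")
            medians.append(med if med is not None else np.nan)
        table["direction"] = directions
        table["median_corr"] = medians
        table.to_csv(
            pred_dir / f"{disease}.tsv", sep="\t", index=False, float_format="%.10g"
        )

    cfg_text = yaml.safe_dump(asdict(config), sort_keys=True)
    (out / "config.yaml").write_text(cfg_text)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "rng_seed": config.rng_seed,
        "n_diseases": len(target),
        "n_sites": len(registry.sites),
        "n_genes": len(registry.genes),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
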