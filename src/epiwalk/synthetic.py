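"""Seeded generator of synthetic MeRIP-seq-style fixture datasets.

Emulates the statistical structure the propagation method assumes,
so the whole pipeline can be exercised without any external download:

* genes fall into latent co-regulation modules; each module has one
  latent factor per experimental condition, and a gene's log-expression
  loads on its module factor with per-gene coupling strength u::

      x_g(c) = sqrt(rho) * u_g * f_{mod(g)}(c) + sqrt(1 - rho) * eps

  with rho = ``corr_strength`` and u_g uniform on
  [1 - 1.25 (1 - rho), 1] (at rho = 0.8 that is [0.75, 1]), so two
  same-module genes correlate at about rho — exactly rho for fully
  coupled genes, shading lower for weakly coupled ones, and tending
  to 1 as rho does — while cross-module genes correlate at 0;
* every m6A site sits on a host gene and its M-value profile shares
  the host module's factor with independent noise (residual scale
  ``noise_sd``), so co-methylation and methylation-expression
  networks recover the module structure;
* RPKM values are lognormal around ~12 (roughly 1-100), and the IP
  channel is derived from the input channel and the target M-value,
  so the 0.1 pseudo-count is exercised; six conditions carry two
  jittered biological replicates to exercise replicate merging;
* each disease is annotated to one module (60%) or two (40%) and
  linked to a fraction of that module's genes, sampled with weight
  proportional to exp(8 * (u - u_min)) — disease annotations in
  curated resources are biased toward strongly co-regulated,
  well-studied genes; links carry over/under expression labels;
* diseases of the same module share module-specific MeSH terms, so
  the Jaccard similarity network is informative;
* planted truth: a (disease, site) pair is true when the site's host
  gene belongs to one of the disease's modules.

Everything is drawn from one ``numpy`` generator seeded by
``rng_seed``; identical configurations produce byte-identical output
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import RpkmTable, SiteRecord

__all__ = ["SynthConfig", "SyntheticDataset", "generate"]

U_SPREAD = 1.25  # coupling spread per unit (1 - corr_strength)
LINK_BIAS = 8.0  # exponential tilt of disease-gene links toward high coupling
N_REPLICATED = 6  # conditions emitted with two biological replicates
MODULE_TERMS = 6  # MeSH terms reserved per module
TERMS_FROM_MODULE = 4  # how many of a disease's terms come from its module pool


@dataclass(frozen=True)
class SynthConfig:
    """Benchmark dimensions mirroring the motivating study's shape:
    38 experimental conditions, hundreds of genes and sites grouped in
    latent modules, tens of diseases."""

    n_diseases: int = 50
    n_genes: int = 300
    n_sites: int = 800
    n_conditions: int = 38
    n_modules: int = 10
    corr_strength: float = 0.8
    noise_sd: float = 1.0
    frac_disease_genes: float = 0.5
    mesh_vocab_size: int = 200
    terms_per_disease: int = 8
    rng_seed: int = 7

    def __post_init__(self) -> None:
        for name in (
            "n_diseases",
            "n_genes",
            "n_sites",
            "n_conditions",
            "n_modules",
            "mesh_vocab_size",
            "terms_per_disease",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.corr_strength < 1.0:
            raise ValueError("corr_strength must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.frac_disease_genes < 1.0:
            raise ValueError("frac_disease_genes must be in (0, 1)")
        if self.n_modules > self.n_genes:
            raise ValueError("more modules than genes")
        if self.n_modules * MODULE_TERMS + self.terms_per_disease > self.mesh_vocab_size:
            raise ValueError("MeSH vocabulary too small for the module structure")


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything :func:`generate` emits."""

    config: SynthConfig
    site_ip: RpkmTable
    site_input: RpkmTable
    gene_rpkm: RpkmTable
    sites: list[SiteRecord]
    disease_gene: pd.DataFrame  # disease, gene, regulation
    disease_terms: dict[str, set[str]]
    truth: pd.DataFrame  # disease, site_id
    gene_module: dict[str, int] = field(default_factory=dict)
    disease_modules: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Emit all fixture files as TSV in the formats the readers expect."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in (
            ("site_ip_rpkm", self.site_ip),
            ("site_input_rpkm", self.site_input),
            ("gene_rpkm", self.gene_rpkm),
        ):
            df = table.values.copy()
            df.insert(0, "id", df.index)
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        rep = pd.DataFrame(
            sorted(self.site_ip.replicate_groups.items()),
            columns=["condition_id", "group"],
        )
        rep.to_csv(out / "replicate_map.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "site_id": s.site_id,
                    "score": 0,
                    "strand": s.strand,
                    "host_gene": s.host_gene,
                    "support_count": s.support_count,
                }
                for s in self.sites
            ]
        ).to_csv(out / "sites.tsv", sep="\t", index=False)
        self.disease_gene.to_csv(out / "disease_gene.tsv", sep="\t", index=False)
        rows = [
            {"disease": d, "term": t}
            for d in sorted(self.disease_terms)
            for t in sorted(self.disease_terms[d])
        ]
        pd.DataFrame(rows).to_csv(out / "disease_mesh.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth_disease_site.tsv", sep="\t", index=False)


def generate(config: SynthConfig | None = None) -> SyntheticDataset:
    """Draw one complete synthetic dataset from the latent-factor model."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    width = len(str(max(cfg.n_genes, cfg.n_sites, cfg.n_diseases)))
    genes = [f"gene{g:0{width}d}" for g in range(cfg.n_genes)]
    site_ids = [f"site{s:0{width}d}" for s in range(cfg.n_sites)]
    diseases = [f"disease{d:0{width}d}" for d in range(cfg.n_diseases)]
    conditions = [f"cond{c:02d}" for c in range(cfg.n_conditions)]

    # contiguous gene modules of near-equal size
    bounds = np.linspace(0, cfg.n_genes, cfg.n_modules + 1).astype(int)
    gene_module = {}
    for m in range(cfg.n_modules):
        for g in range(bounds[m], bounds[m + 1]):
            gene_module[genes[g]] = m

    factors = rng.standard_normal((cfg.n_modules, cfg.n_conditions))
    u_low = max(0.0, 1.0 - U_SPREAD * (1.0 - cfg.corr_strength))
    u = rng.uniform(u_low, 1.0, size=cfg.n_genes)
    a = np.sqrt(cfg.corr_strength) * u
    resid = np.sqrt(1.0 - cfg.corr_strength)
    mod_of = np.array([gene_module[g] for g in genes])
    gene_z = a[:, None] * factors[mod_of] + resid * rng.standard_normal(
        (cfg.n_genes, cfg.n_conditions)
    )
    gene_rpkm_vals = np.exp(2.5 + 0.8 * gene_z)  # lognormal, roughly 1-100

    # sites: host gene, shared module factor, independent noise
    host_idx = rng.integers(0, cfg.n_genes, size=cfg.n_sites)
    a_site = a[host_idx]
    site_m = a_site[:, None] * factors[mod_of[host_idx]] + (
        cfg.noise_sd * resid
    ) * rng.standard_normal((cfg.n_sites, cfg.n_conditions))
    site_input_vals = gene_rpkm_vals[host_idx] * np.exp(
        0.1 * rng.standard_normal((cfg.n_sites, cfg.n_conditions))
    )
    site_ip_vals = np.clip(
        (site_input_vals + 0.1) * np.exp2(site_m) - 0.1, 0.0, None
    )

    # replicate structure: first N_REPLICATED conditions get two jittered runs
    def emit(vals: np.ndarray, ids: list[str]) -> RpkmTable:
        cols: dict[str, np.ndarray] = {}
        rep_map: dict[str, str] = {}
        for c, cond in enumerate(conditions):
            if c < N_REPLICATED:
                for r in (1, 2):
                    run = f"{cond}_r{r}"
                    jitter = np.exp(0.05 * rng.standard_normal(vals.shape[0]))
                    cols[run] = vals[:, c] * jitter
                    rep_map[run] = cond
            else:
                cols[cond] = vals[:, c]
                rep_map[cond] = cond
        return RpkmTable(pd.DataFrame(cols, index=ids), rep_map)

    gene_table = emit(gene_rpkm_vals, genes)
    ip_table = emit(site_ip_vals, site_ids)
    input_table = emit(site_input_vals, site_ids)

    chroms = rng.integers(1, 23, size=cfg.n_sites)
    starts = rng.integers(1000, 10_000_000, size=cfg.n_sites)
    strands = rng.choice(["+", "-"], size=cfg.n_sites)
    supports = rng.integers(1, 61, size=cfg.n_sites)
    sites = [
        SiteRecord(
            site_id=site_ids[s],
            chrom=f"chr{chroms[s]}",
            start=int(starts[s]) - 50,
            end=int(starts[s]) + 51,
            strand=str(strands[s]),
            host_gene=genes[host_idx[s]],
            support_count=int(supports[s]),
        )
        for s in range(cfg.n_sites)
    ]

    # diseases: 1 module (60%) or 2 (40%); links biased toward high coupling
    disease_modules: dict[str, tuple[int, ...]] = {}
    dg_rows = []
    for d in diseases:
        k = 1 if rng.uniform() < 0.6 else min(2, cfg.n_modules)
        mods = tuple(int(m) for m in rng.choice(cfg.n_modules, size=k, replace=False))
        disease_modules[d] = mods
        for m in mods:
            members = np.flatnonzero(mod_of == m)
            n_link = max(1, round(cfg.frac_disease_genes * members.size))
            w = np.exp(LINK_BIAS * (u[members] - u_low))
            chosen = rng.choice(
                members, size=min(n_link, members.size), replace=False, p=w / w.sum()
            )
            for g in chosen:
                reg = "over" if rng.uniform() < 0.7 else "under"
                dg_rows.append({"disease": d, "gene": genes[g], "regulation": reg})
    disease_gene = pd.DataFrame(dg_rows)

    # MeSH terms: per-module pools plus shared background vocabulary
    vocab = [f"T{t:03d}" for t in range(cfg.mesh_vocab_size)]
    module_pool = {
        m: vocab[m * MODULE_TERMS : (m + 1) * MODULE_TERMS] for m in range(cfg.n_modules)
    }
    background = vocab[cfg.n_modules * MODULE_TERMS :]
    disease_terms: dict[str, set[str]] = {}
    for d in diseases:
        terms: set[str] = set()
        n_from_module = min(TERMS_FROM_MODULE, cfg.terms_per_disease)
        for m in disease_modules[d]:
            take = rng.choice(MODULE_TERMS, size=n_from_module, replace=False)
            terms.update(module_pool[m][t] for t in take)
        while len(terms) < cfg.terms_per_disease:
            terms.add(background[int(rng.integers(0, len(background)))])
        disease_terms[d] = terms

    truth_rows = [
        {"disease": d, "site_id": site_ids[s]}
        for d in diseases
        for s in range(cfg.n_sites)
        if mod_of[host_idx[s]] in disease_modules[d]
    ]
    truth = pd.DataFrame(truth_rows)

    return SyntheticDataset(
        config=cfg,
        site_ip=ip_table,
        site_input=input_table,
        gene_rpkm=gene_table,
        sites=sites,
        disease_gene=disease_gene,
        disease_terms=disease_terms,
        truth=truth,
        gene_module=gene_module,
        disease_modules={d: disease_modules[d] for d in diseases},
    )
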