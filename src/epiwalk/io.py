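"""Readers and writers for the plain-text interchange formats.

All inputs are TSV: RPKM matrices (first column row id, header row of
run ids), a BED6-compatible site table with ``site_id``, ``host_gene``
and ``support_count`` columns, two-column disease-gene pairs (with an
optional ``regulation`` column carrying over/under labels), one
disease/MeSH-term pair per row, and 3-column weighted edge lists.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .assoc import AssociationNetwork
from .profiles import RpkmTable, SiteRecord

__all__ = [
    "read_rpkm_table",
    "read_site_table",
    "read_disease_gene",
    "read_disease_terms",
    "read_edge_list",
    "write_edge_list",
]


def read_rpkm_table(path: str | Path, replicate_map: str | Path | None = None) -> RpkmTable:
    """RPKM matrix TSV; optional 2-column run-to-condition replicate map."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = None
    groups: dict[str, str] = {}
    if replicate_map is not None:
        rep = pd.read_csv(replicate_map, sep="\t")
        if rep.shape[1] < 2:
            raise ValueError(f"{replicate_map}: replicate map needs 2 columns")
        groups = dict(zip(rep.iloc[:, 0].astype(str), rep.iloc[:, 1].astype(str)))
        groups = {c: groups[c] for c in df.columns if c in groups}
        missing = set(df.columns) - set(groups)
        if missing:
            raise ValueError(f"runs missing from replicate map: {sorted(missing)[:5]}")
    return RpkmTable(df.astype(float), groups)


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """BED-style site annotation (0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "site_id", "strand", "host_gene", "support_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SiteRecord(
            site_id=str(r.site_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            host_gene=str(r.host_gene),
            support_count=int(r.support_count),
        )
        for r in df.itertuples()
    ]


def read_disease_gene(path: str | Path) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    """Disease-gene pair TSV; returns the pair table and an over/under
    label map keyed by (disease, gene) when a ``regulation`` column exists."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns")
    cols = list(df.columns)
    if "disease" not in cols or "gene" not in cols:
        df = df.rename(columns={cols[0]: "disease", cols[1]: "gene"})
    bad = df.index[df["disease"].isna() | df["gene"].isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    if df.empty:
        warnings.warn(f"{path}: empty disease-gene table", stacklevel=2)
    signs: dict[tuple[str, str], str] = {}
    if "regulation" in df.columns:
        signs = {
            (d, g): s
            for d, g, s in zip(df["disease"], df["gene"], df["regulation"])
        }
    return df, signs


def read_disease_terms(path: str | Path) -> dict[str, set[str]]:
    """One (disease, MeSH term) pair per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns")
    out: dict[str, set[str]] = {}
    for d, t in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(d), set()).add(str(t))
    return out


def write_edge_list(net: AssociationNetwork, path: str | Path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_list(path: str | Path, layer_pair: str) -> AssociationNetwork:
    edges = pd.read_csv(path, sep="\t")
    return AssociationNetwork(layer_pair, edges)
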