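"""Methylation and expression profiles from RPKM tables.

MeRIP-seq quantifies the methylation status of an m6A site as the
M-value, the log2 fold change of IP over input read abundance::

    M = log2((RPKM_IP + 0.1) / (RPKM_Input + 0.1))

with a fixed 0.1 pseudo-count guarding against zero abundance.  This
module builds sites x conditions M-value matrices and genes x conditions
expression matrices from per-condition RPKM tables, merging biological
replicates, quantile-normalizing across conditions, and filtering sites
down to the robustly measured, actively regulated subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

PSEUDO_COUNT = 0.1  # fixed by the M-value definition; not configurable

__all__ = [
    "SiteRecord",
    "RpkmTable",
    "MethylationProfile",
    "ExpressionProfile",
    "m_value",
    "merge_replicates",
    "quantile_normalize",
    "filter_sites",
    "FilterDiagnostics",
]


@dataclass(frozen=True)
class SiteRecord:
    """One m6A site: genomic locus, host gene, and experimental support.

    Coordinates are 0-based half-open; ``start``/``end`` delimit the
    flanking window used for read counting.  ``support_count`` is the
    number of independent experiments reporting the site.
    """

    site_id: str
    chrom: str
    start: int
    end: int
    strand: str
    host_gene: str
    support_count: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"site {self.site_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.site_id}: strand must be '+' or '-'")
        if self.support_count < 0:
            raise ValueError(f"site {self.site_id}: negative support_count")


@dataclass
class RpkmTable:
    """Non-negative RPKM matrix (rows x sequencing runs) with replicate map.

    ``values`` is indexed by row id (site or gene) with one column per
    sequencing run; ``replicate_groups`` maps each run/column id to its
    experimental-condition label.
    """

    values: pd.DataFrame
    replicate_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate row id: {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")
        if not self.replicate_groups:
            # identity map: each column is its own condition
            self.replicate_groups = {c: c for c in self.values.columns}
        missing = set(self.values.columns) - set(self.replicate_groups)
        if missing:
            raise ValueError(f"columns without a replicate group: {sorted(missing)}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MethylationProfile:
    """Sites x conditions matrix of M-values with site metadata."""

    sites: list[SiteRecord]
    condition_ids: list[str]
    m_values: np.ndarray

    def __post_init__(self) -> None:
        self.m_values = np.asarray(self.m_values, dtype=float)
        if self.m_values.shape != (len(self.sites), len(self.condition_ids)):
            raise ValueError(
                f"m_values shape {self.m_values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.condition_ids)} conditions"
            )
        if not np.isfinite(self.m_values).all():
            raise ValueError("m_values must be finite")

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.m_values, index=self.site_ids, columns=self.condition_ids)


@dataclass
class ExpressionProfile:
    """Genes x conditions matrix of normalized expression."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError("expression matrix shape does not match ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)


def m_value(rpkm_ip, rpkm_input):
    """M-value: log2((RPKM_IP + 0.1) / (RPKM_Input + 0.1)).

    Accepts scalars or arrays (broadcast elementwise); always finite for
    non-negative inputs thanks to the pseudo-count.
    """
    ip = np.asarray(rpkm_ip, dtype=float)
    inp = np.asarray(rpkm_input, dtype=float)
    if (ip < 0).any() or (inp < 0).any():
        raise ValueError("RPKM values must be non-negative")
    out = np.log2((ip + PSEUDO_COUNT) / (inp + PSEUDO_COUNT))
    if out.ndim == 0:
        return float(out)
    return out


def merge_replicates(table: RpkmTable) -> RpkmTable:
    """Collapse biological replicates to one column per condition.

    The merged value is the arithmetic mean of the replicate RPKMs;
    condition order follows first appearance of each group label.
    """
    groups: dict[str, list[str]] = {}
    for col in table.values.columns:
        groups.setdefault(table.replicate_groups[col], []).append(col)
    for label, cols in groups.items():
        if not cols:
            raise ValueError(f"empty replicate group {label!r}")
    merged = pd.DataFrame(
        {label: table.values[cols].mean(axis=1) for label, cols in groups.items()},
        index=table.values.index,
    )
    return RpkmTable(values=merged, replicate_groups={c: c for c in merged.columns})


def quantile_normalize(matrix):
    """Force every column onto the common rank-mean reference distribution.

    The reference distribution is the row-wise mean of the per-column
    order statistics.  Tied values within a column receive the mean of
    the reference values at their tied positions, so ranks (including
    ties) are preserved exactly.  Accepts a DataFrame or 2-D array and
    returns the same type.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    arr = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if arr.size == 0:
        raise ValueError("empty matrix")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    n_rows, n_cols = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(n_cols):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_rows)
        assigned[order] = reference
        # ties: average the reference values over each tied block
        ranks = rankdata(col, method="dense")
        sums = np.bincount(ranks, weights=assigned)
        counts = np.bincount(ranks)
        out[:, j] = sums[ranks] / counts[ranks]
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass(frozen=True)
class FilterDiagnostics:
    """Per-step survivor counts from :func:`filter_sites`."""

    n_input: int
    n_after_support: int
    n_after_level: int
    n_after_variance: int


def filter_sites(
    profile: MethylationProfile,
    min_support: int = 10,
    level_pct: float = 70.0,
    var_pct: float = 80.0,
    level_rule: str = "le_pct",
    return_diagnostics: bool = False,
):
    """Keep robustly supported, moderately methylated, variable sites.

    Three sequential filters, each percentile computed on the survivors
    of the previous step:

    1. ``support_count > min_support`` (strictly more experiments);
    2. mean M-value at or below the ``level_pct``-th percentile of
       per-site means (``level_rule='ge_pct'`` flips to at-or-above,
       keeping the most methylated instead);
    3. per-site variance at or above the ``(100 - var_pct)``-th
       percentile, i.e. the top ``var_pct`` percent most variable sites.

    Ties at a percentile threshold are retained.  Raises if no site
    survives, reporting the per-step counts.
    """
    if not profile.sites:
        raise ValueError("empty profile")
    if level_rule not in ("le_pct", "ge_pct"):
        raise ValueError(f"unknown level_rule {level_rule!r}")

    keep = np.array([s.support_count > min_support for s in profile.sites])
    n_support = int(keep.sum())

    if n_support:
        means = profile.m_values[keep].mean(axis=1)
        thr = np.percentile(means, level_pct)
        ok = means <= thr if level_rule == "le_pct" else means >= np.percentile(means, 100 - level_pct)
        idx = np.flatnonzero(keep)
        keep = np.zeros_like(keep)
        keep[idx[ok]] = True
    n_level = int(keep.sum())

    if n_level:
        variances = profile.m_values[keep].var(axis=1, ddof=0)
        thr = np.percentile(variances, 100.0 - var_pct)
        idx = np.flatnonzero(keep)
        keep = np.zeros_like(keep)
        keep[idx[variances >= thr]] = True
    n_var = int(keep.sum())

    diag = FilterDiagnostics(len(profile.sites), n_support, n_level, n_var)
    if n_var == 0:
        raise ValueError(
            "all sites filtered out "
            f"(input={diag.n_input}, after support={diag.n_after_support}, "
            f"after level={diag.n_after_level}, after variance={diag.n_after_variance})"
        )
    kept_idx = np.flatnonzero(keep)
    filtered = MethylationProfile(
        sites=[profile.sites[i] for i in kept_idx],
        condition_ids=list(profile.condition_ids),
        m_values=profile.m_values[kept_idx],
    )
    if return_diagnostics:
        return filtered, diag
    return filtered


def methylation_profile_from_rpkm(
    ip: RpkmTable,
    inp: RpkmTable,
    sites: list[SiteRecord],
    normalize: bool = True,
    normalize_on: str = "m_values",
) -> MethylationProfile:
    """Full methylation pipeline: merge replicates, M-values, quantile normalize.

    By default replicates are merged, M-values computed per merged
    condition, and the M-value matrix quantile-normalized
    (``normalize_on='rpkm'`` instead normalizes the merged IP and input
    RPKM tables before taking M-values).
    """
    by_id = {s.site_id: s for s in sites}
    missing = [r for r in ip.row_ids if r not in by_id]
    if missing:
        raise ValueError(f"sites missing from annotation: {missing[:5]}")
    ip_m = merge_replicates(ip)
    inp_m = merge_replicates(inp)
    if list(ip_m.values.columns) != list(inp_m.values.columns):
        raise ValueError("IP and input tables disagree on conditions")
    inp_aligned = inp_m.values.loc[ip_m.values.index]
    if normalize and normalize_on == "rpkm":
        ip_vals = quantile_normalize(ip_m.values).to_numpy()
        inp_vals = quantile_normalize(inp_aligned).to_numpy()
        m = m_value(ip_vals, inp_vals)
    else:
        m = m_value(ip_m.values.to_numpy(), inp_aligned.to_numpy())
        if normalize:
            m = quantile_normalize(m)
    return MethylationProfile(
        sites=[by_id[r] for r in ip_m.values.index],
        condition_ids=list(ip_m.values.columns),
        m_values=m,
    )


def expression_profile_from_rpkm(
    table: RpkmTable, normalize: bool = True, log2: bool = True
) -> ExpressionProfile:
    """Expression pipeline: merge replicates, quantile normalize, log2(x+0.1)."""
    merged = merge_replicates(table)
    vals = merged.values
    if normalize:
        vals = quantile_normalize(vals)
    arr = vals.to_numpy(dtype=float)
    if log2:
        arr = np.log2(arr + PSEUDO_COUNT)
    return ExpressionProfile(
        gene_ids=list(merged.values.index),
        condition_ids=list(merged.values.columns),
        values=arr,
    )
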