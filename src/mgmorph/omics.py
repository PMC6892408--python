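"""Threshold-based genomics filters.

Implements the explicit numeric rules used around a differential-expression
engine: Benjamini-Hochberg FDR adjustment; the joint DEG criterion (mean
expression > 4 TPM, at least a 30% fold-change difference, FDR < 0.05);
top-k DEG list construction by p-value and list unions; gene-set overlap
counts; top-variable-gene selection; ChIP peak filtering (TSS +-1 kb
window, < 4-read removal, 2-fold + IDR < 0.05 significance); and the
double normalisation of qPCR Ct values (to a reference gene, then to the
mean of the wild-type group).

The differential tests themselves (negative-binomial models, IDR) are
consumed as table columns, not computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class FilterCriteria:
    """Joint DEG criterion.

    ``fc_min_ratio`` is on the ratio scale; "at least a 30% difference"
    reads symmetrically by default (pass iff FC >= 1.3 or FC <= 1/1.3).
    Set ``symmetric_down=False`` for the alternative reading FC <= 0.7.
    """

    tpm_min: float = 4.0
    fc_min_ratio: float = 1.3
    fdr_max: float = 0.05
    symmetric_down: bool = True

    def __post_init__(self) -> None:
        if self.tpm_min < 0:
            raise ValueError("tpm_min must be >= 0")
        if not self.fc_min_ratio > 1:
            raise ValueError("fc_min_ratio must be > 1")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must lie in (0, 1)")

    @property
    def fc_down_max(self) -> float:
        """Down-regulation cutoff: 1/ratio, or the linear reading 2 - ratio."""
        if self.symmetric_down:
            return 1.0 / self.fc_min_ratio
        return max(2.0 - self.fc_min_ratio, 0.0)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <= 1)."""
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values,
                   dtype=float)
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def deg_filter(
    table: pd.DataFrame, criteria: FilterCriteria = FilterCriteria()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a gene table into (up-regulated, down-regulated) DEG tables.

    A gene passes iff ``mean_tpm > tpm_min`` (strictly greater) and
    ``fdr < fdr_max`` and its fold change clears the ratio criterion in
    either direction.  If the ``fdr`` column is absent or entirely missing
    it is computed from ``p`` by :func:`bh_adjust` first.
    """
    table = table.copy()
    if "fdr" not in table.columns or table["fdr"].isna().all():
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    expressed = table["mean_tpm"] > criteria.tpm_min
    significant = table["fdr"] < criteria.fdr_max
    up = table["fold_change"] >= criteria.fc_min_ratio
    down = table["fold_change"] <= criteria.fc_down_max
    passing = expressed & significant & (up | down)
    return table[passing & up], table[passing & down]


def deg_gene_set(
    table: pd.DataFrame, criteria: FilterCriteria = FilterCriteria()
) -> set[str]:
    """Convenience: the set of gene ids passing :func:`deg_filter`."""
    up, down = deg_filter(table, criteria)
    return set(up["gene_id"]) | set(down["gene_id"])


def top_deg_lists(
    tables: Mapping[str, pd.DataFrame],
    k: int,
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[dict[str, list[str]], list[str]]:
    """Top-k DEGs per comparison (ascending p, ties by gene id) plus union.

    The union preserves first-seen order across comparisons (iteration
    order of ``tables``).  Comparisons with fewer than ``k`` DEGs
    contribute all of them, with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    per_comparison: dict[str, list[str]] = {}
    union: list[str] = []
    seen: set[str] = set()
    for name, table in tables.items():
        up, down = deg_filter(table, criteria)
        degs = pd.concat([up, down]).sort_values(["p", "gene_id"], kind="mergesort")
        if len(degs) < k:
            warnings.warn(
                f"comparison {name!r} has only {len(degs)} DEGs (< k={k})",
                stacklevel=2,
            )
        top = degs["gene_id"].head(k).tolist()
        per_comparison[name] = top
        for gene in top:
            if gene not in seen:
                seen.add(gene)
                union.append(gene)
    return per_comparison, union


def set_overlap(a: Iterable[str], b: Iterable[str]) -> tuple[int, int, int]:
    """Counts (|a only|, |a and b|, |b only|) for two gene sets."""
    sa, sb = set(a), set(b)
    inter = sa & sb
    return len(sa - inter), len(inter), len(sb - inter)


def top_variable_genes(matrix: pd.DataFrame, k: int = 500) -> list[str]:
    """The k genes with highest across-sample variance (ties by gene id).

    ``matrix`` is genes x samples and is assumed already variance-
    stabilised; the ranking is invariant to sample column order.
    """
    variances = matrix.var(axis=1, ddof=1)
    if k > np.isfinite(variances).sum():
        raise ValueError("k exceeds the number of genes with finite variance")
    # mergesort is stable; pre-sort the index so variance ties break by gene id
    order = (
        pd.DataFrame({"var": variances})
        .sort_index()
        .sort_values(by=["var"], ascending=False, kind="mergesort")
    )
    return order.head(k).index.tolist()


def chip_peak_filter(
    peaks: pd.DataFrame,
    window_bp: int = 1000,
    min_reads: int = 4,
    fc_min: float = 2.0,
    idr_max: float = 0.05,
    read_columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain promoter-proximal, adequately covered peaks; flag significant ones.

    Retained: ``|tss_distance| <= window_bp`` (inclusive; negative distances
    are upstream) and at least ``min_reads`` reads in at least one genotype.
    Significant (subset of retained): at least ``fc_min``-fold difference in
    either direction and ``idr < idr_max``.  Read-count columns default to
    every column starting with ``"reads_"``.
    """
    if read_columns is None:
        read_columns = [c for c in peaks.columns if c.startswith("reads_")]
    if not read_columns:
        raise ValueError("no read-count columns found or given")
    in_window = peaks["tss_distance"].abs() <= window_bp
    covered = peaks[list(read_columns)].max(axis=1) >= min_reads
    retained = peaks[in_window & covered]
    strong = (retained["fold_change"] >= fc_min) | (
        retained["fold_change"] <= 1.0 / fc_min
    )
    significant = retained[strong & (retained["idr"] < idr_max)]
    return retained, significant


def qpcr_relative_expression(
    ct_gene: Sequence[float],
    ct_reference: Sequence[float],
    group_labels: Sequence[str],
    reference_group: str = "WT",
) -> pd.Series:
    """Relative expression, normalised to a reference gene then to WT mean.

    Per sample s: ``rel_s = 2 ** -(ct_gene_s - ct_reference_s)``; the
    result divides ``rel_s`` by the mean of ``rel`` over the reference
    group, so the reference group averages exactly 1.  Samples with a
    missing Ct are dropped with a warning.  Returns a Series indexed by
    sample position with the group label stored in ``.attrs["groups"]``.
    """
    ct_gene = np.asarray(ct_gene, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    groups = np.asarray(group_labels)
    if not (len(ct_gene) == len(ct_reference) == len(groups)):
        raise ValueError("sample vectors must be matched in length")
    keep = ~(np.isnan(ct_gene) | np.isnan(ct_reference))
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} sample(s) with missing Ct", stacklevel=2
        )
    rel = 2.0 ** -(ct_gene[keep] - ct_reference[keep])
    ref = rel[groups[keep] == reference_group]
    if ref.size == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    out = pd.Series(rel / ref.mean(), index=np.nonzero(keep)[0])
    out.attrs["groups"] = groups[keep]
    return out
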