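"""Normalization, cell/gene filters and a rank-based differential test.

The filter chain mirrors a deep full-length single-cell protocol:
sequencing-depth filter (strictly more than ``min_reads`` total counts),
median-diversity filter (median gene count above zero), an
enrichment-based transfection-evidence filter (transfected cells must
show depletion of the introduced miRNA's targets), then a gene-level
mean-count filter.  Normalization is median-of-ratios size factors.
Differential expression is a Wilcoxon rank-sum test per gene with Holm
family-wise correction, with log2 fold changes of pseudocounted means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "FilterReport",
    "DEResult",
    "compute_size_factors",
    "basic_cell_filters",
    "transfection_evidence_filter",
    "choose_gene_cutoff_ks",
    "filter_genes_by_mean",
    "differential_expression",
]


@dataclass
class ExpressionMatrix:
    """Raw integer counts, genes x cells, with per-cell condition labels."""

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate cell ids")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("counts must be finite and non-negative")
        self.conditions = self.conditions.reindex(self.counts.columns)

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts[cells], self.conditions[cells])


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized expression with filter provenance."""

    values: pd.DataFrame
    size_factors: pd.Series
    conditions: pd.Series
    provenance: list = field(default_factory=list)

    def subset(self, genes=None, cells=None, note: str | None = None) -> "NormalizedMatrix":
        v = self.values
        if genes is not None:
            v = v.loc[genes]
        if cells is not None:
            v = v[cells]
        prov = self.provenance + ([note] if note else [])
        return NormalizedMatrix(v, self.size_factors[v.columns], self.conditions[v.columns], prov)


@dataclass
class FilterStage:
    name: str
    before: int
    after: int
    removed: tuple[str, ...]
    reason: str

    def __post_init__(self) -> None:
        if self.before - len(self.removed) != self.after:
            raise ValueError(f"stage {self.name!r}: before - removed != after")


@dataclass
class FilterReport:
    """Per-stage before/after counts with removed ids and reason codes."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, before: int, after: int, removed, reason: str) -> None:
        self.stages.append(FilterStage(name, before, after, tuple(removed), reason))

    def to_dict(self) -> dict:
        return {
            s.name: {"before": s.before, "after": s.after,
                     "removed": list(s.removed), "reason": s.reason}
            for s in self.stages
        }


@dataclass
class DEResult:
    """Per-gene log2 fold change of pseudocounted means, raw and
    Holm-adjusted rank-sum p-values."""

    table: pd.DataFrame  # columns: log2_fc, p, p_adj
    cond_a: str
    cond_b: str

    def downregulated(self, alpha: float = 0.1) -> pd.Index:
        t = self.table
        return t.index[(t["p_adj"] < alpha) & (t["log2_fc"] < 0)]


def compute_size_factors(m: ExpressionMatrix) -> NormalizedMatrix:
    """Median-of-ratios size factors: per cell, the median over reference
    genes (positive in every cell) of count / geometric mean across cells."""
    counts = m.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every cell; prefilter cells or genes first"
        )
    ref = counts[positive]
    log_geo = np.mean(np.log(ref), axis=1)
    sf = np.exp(np.median(np.log(ref) - log_geo[:, None], axis=0))
    size_factors = pd.Series(sf, index=m.counts.columns, name="size_factor")
    values = m.counts / size_factors
    return NormalizedMatrix(values, size_factors, m.conditions.copy(), ["size_factor_normalized"])


def basic_cell_filters(
    m: ExpressionMatrix, min_reads: int = 500_000
) -> tuple[ExpressionMatrix, FilterReport]:
    """Depth filter (keep cells with total counts strictly above
    ``min_reads``) followed by the median-diversity filter (drop cells
    whose median gene count is 0)."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    report = FilterReport()
    totals = m.counts.sum(axis=0)
    keep_depth = totals > min_reads
    removed_depth = list(m.counts.columns[~keep_depth])
    report.add("depth", m.counts.shape[1], int(keep_depth.sum()), removed_depth, "depth")
    m1 = m.subset_cells(m.counts.columns[keep_depth])

    medians = m1.counts.median(axis=0)
    keep_med = medians > 0
    removed_med = list(m1.counts.columns[~keep_med])
    report.add("median", m1.counts.shape[1], int(keep_med.sum()), removed_med, "median")
    m2 = m1.subset_cells(m1.counts.columns[keep_med])
    if m2.counts.shape[1] == 0:
        raise ValueError("all cells removed by basic filters")
    return m2, report


def transfection_evidence_filter(
    nm: NormalizedMatrix,
    targets: set[str] | dict[str, set[str]],
    reference_condition: str,
    transfected_conditions: tuple[str, ...] | None = None,
    seed: int = 0,
) -> tuple[NormalizedMatrix, FilterReport]:
    """Drop transfected cells with no evidence of target repression.

    Per transfected cell, genes are ranked by log2(cell expression /
    mean expression in the reference condition) descending; the signed
    KS enrichment score of the miRNA's target set on that ranking must
    be negative (targets depleted from the top) for the cell to be kept.

    ``targets`` may be one gene set (applied to every transfected
    condition) or a mapping condition -> target set.
    """
    from rmicell.enrichment import ks_enrichment

    ref_cells = nm.conditions.index[nm.conditions == reference_condition]
    if len(ref_cells) == 0:
        raise ValueError(f"reference condition {reference_condition!r} has no cells")
    ref_mean = nm.values[ref_cells].mean(axis=1)

    if transfected_conditions is None:
        if isinstance(targets, dict):
            transfected_conditions = tuple(targets)
        else:
            transfected_conditions = tuple(
                c for c in nm.conditions.unique() if c != reference_condition
            )
    report = FilterReport()
    drop: list[str] = []
    eps = 1e-9
    rng = np.random.default_rng(seed)
    for cond in transfected_conditions:
        tset = targets[cond] if isinstance(targets, dict) else targets
        tset = set(tset) & set(nm.values.index)
        if not tset:
            raise ValueError(f"no target gene of condition {cond!r} is measured")
        cells = nm.conditions.index[nm.conditions == cond]
        for cell in cells:
            ratio = np.log2((nm.values[cell] + eps) / (ref_mean + eps))
            order = np.lexsort((rng.random(len(ratio)), -ratio.to_numpy()))
            ranking = list(ratio.index[order])
            es = ks_enrichment(ranking, tset).ES
            if es >= 0:
                drop.append(cell)
    keep = [c for c in nm.values.columns if c not in set(drop)]
    report.add("gsea", nm.values.shape[1], len(keep), drop, "gsea")
    return nm.subset(cells=keep, note="transfection_evidence_filter"), report


def choose_gene_cutoff_ks(
    paired_samples: list[tuple[pd.Series, pd.Series]],
    candidate_cutoffs: list[float],
    min_genes: int = 10,
) -> float:
    """Pick the per-gene count cutoff minimizing the mean two-sample KS
    distance between paired (resequenced) expression profiles.

    Genes enter a pair's comparison when both members have count >= c.
    Cutoffs leaving fewer than ``min_genes`` genes in some pair are
    skipped with a warning; ties go to the smallest cutoff.
    """
    if not paired_samples:
        raise ValueError("need at least one pair")
    cutoffs = sorted(candidate_cutoffs)
    best_c, best_d = None, np.inf
    for c in cutoffs:
        dists = []
        ok = True
        for a, b in paired_samples:
            keep = (a >= c) & (b >= c)
            if keep.sum() < min_genes:
                logger.warning("cutoff %s leaves <%d genes in a pair; skipped", c, min_genes)
                ok = False
                break
            dists.append(stats.ks_2samp(a[keep], b[keep]).statistic)
        if not ok:
            continue
        mean_d = float(np.mean(dists))
        if mean_d < best_d - 1e-15:
            best_c, best_d = c, mean_d
    if best_c is None:
        raise ValueError("no candidate cutoff evaluable")
    return best_c


def filter_genes_by_mean(
    nm: NormalizedMatrix, min_mean: float = 5.0
) -> tuple[NormalizedMatrix, FilterReport]:
    """Remove genes whose mean across retained cells is below ``min_mean``."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    means = nm.values.mean(axis=1)
    keep = means >= min_mean
    report = FilterReport()
    report.add("gene-mean", nm.values.shape[0], int(keep.sum()),
               list(nm.values.index[~keep]), "gene-mean")
    return nm.subset(genes=nm.values.index[keep], note=f"gene_mean>={min_mean}"), report


def differential_expression(
    nm: NormalizedMatrix, cond_a: str, cond_b: str, pseudocount: float = 1.0
) -> DEResult:
    """Per-gene Wilcoxon rank-sum test between two conditions with Holm
    correction; fold change is log2((mean_a + eps) / (mean_b + eps))."""
    cells_a = nm.conditions.index[nm.conditions == cond_a]
    cells_b = nm.conditions.index[nm.conditions == cond_b]
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("need >= 3 cells per condition")
    A = nm.values[cells_a].to_numpy()
    B = nm.values[cells_b].to_numpy()
    lfc = np.log2((A.mean(axis=1) + pseudocount) / (B.mean(axis=1) + pseudocount))
    res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    p_adj = multipletests(pvals, method="holm")[1]
    table = pd.DataFrame({"log2_fc": lfc, "p": pvals, "p_adj": p_adj}, index=nm.values.index)
    return DEResult(table=table, cond_a=cond_a, cond_b=cond_b)
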