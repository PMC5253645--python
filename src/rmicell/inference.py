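"""Significance machinery around RMI.

Two permutation schemes guard against the two main confounders of
co-expression estimates in single-cell counts:

* the expression-matched test draws null gene sets bin-by-bin from genes
  of similar mean expression (bins of 500 genes along the mean-expression
  ranking), so a high RMI cannot be explained by expression level alone;
* the differential (delta-RMI) test compares one gene set's RMI between
  two cell populations against a null of random same-size gene draws,
  with the tail chosen by the sign of the observed difference.

A bootstrap over random subsets makes large target sets tractable (the
kNN entropy estimate degrades when the number of genes approaches the
number of cells), and a per-condition entropy prefilter removes the
lowest-information genes before differential testing.  Target-set
definition intersects downregulated genes with the union of prediction
sources, keeping multi-source-supported genes as high confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rmicell._utils import as_frame
from rmicell.rmi import RMIConfig, renyi_entropy, rmi

__all__ = [
    "BinAssignment",
    "PermutationResult",
    "TargetSets",
    "expression_bins",
    "rmi_permutation_test",
    "rmi_bootstrap_distribution",
    "entropy_prefilter",
    "delta_rmi_test",
    "define_targets",
]


@dataclass
class BinAssignment:
    """Expression bins: contiguous blocks of ``bin_size`` genes along the
    mean-expression ranking (descending); the remainder forms the final,
    smaller bin.  Tied means are ordered stably by gene id."""

    bin_of: pd.Series          # gene -> bin index
    bins: list[tuple[str, ...]]
    bin_size: int


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null and the empirical p.

    ``p`` is the empirical p-value, floored at 1/trials so it is never
    zero: the right-tail fraction for the RMI test, and twice the
    smaller tail (two-sided) for delta-RMI.
    """

    observed: float
    null: np.ndarray
    p: float
    trials: int
    seed: int
    statistic: str = "rmi"
    extra: dict = field(default_factory=dict)


@dataclass
class TargetSets:
    """Predicted and high-confidence miRNA target sets."""

    predicted: tuple[str, ...]
    high_confidence: tuple[str, ...]
    support: pd.Series  # per predicted gene: number of supporting sources

    def __post_init__(self) -> None:
        assert set(self.high_confidence) <= set(self.predicted)


def expression_bins(nm, bin_size: int = 500) -> BinAssignment:
    """Assign every gene to a bin of ``bin_size`` genes of similar mean
    expression (stable sort, descending)."""
    values = as_frame(nm)
    if values.shape[0] < 1:
        raise ValueError("need at least one gene")
    means = values.mean(axis=1)
    order = means.sort_values(ascending=False, kind="stable").index
    # stable tie rule: equal means keep gene-id order
    tmp = pd.DataFrame({"m": -means.loc[order].to_numpy()}, index=order)
    order = tmp.sort_values(["m"], kind="stable").index
    bins: list[tuple[str, ...]] = []
    bin_of = {}
    for b, lo in enumerate(range(0, len(order), bin_size)):
        block = tuple(order[lo:lo + bin_size])
        bins.append(block)
        for g in block:
            bin_of[g] = b
    return BinAssignment(pd.Series(bin_of, name="bin"), bins, bin_size)


def _matrix_for(nm, genes) -> np.ndarray:
    values = as_frame(nm)
    return values.loc[list(genes)].to_numpy().T  # cells x genes


def rmi_permutation_test(
    nm,
    gene_set,
    bins: BinAssignment,
    trials: int = 10_000,
    config: RMIConfig | None = None,
    seed: int = 0,
) -> PermutationResult:
    """Expression-matched permutation test of a gene set's RMI.

    Each trial draws, without replacement within the trial, one random
    gene from the expression bin of every set gene and computes the
    trial set's RMI; p is the fraction of trials with RMI at least the
    observed one.
    """
    if config is None:
        config = RMIConfig()
    if trials < 100:
        raise ValueError("trials must be >= 100")
    gene_set = list(gene_set)
    values = as_frame(nm)
    missing = [g for g in gene_set if g not in values.index]
    if missing:
        raise KeyError(f"set genes absent from matrix: {missing[:5]}")
    for g in gene_set:
        if g not in bins.bin_of.index:
            raise KeyError(f"gene {g!r} has no expression bin")
    observed = rmi(_matrix_for(nm, gene_set), config).I_alpha

    rng = np.random.default_rng(seed)
    X = values.to_numpy().T  # cells x genes
    row = {g: i for i, g in enumerate(values.index)}
    bin_rows = [np.array([row[g] for g in b]) for b in bins.bins]
    set_bins = [bins.bin_of[g] for g in gene_set]
    null = np.empty(trials)
    for t in range(trials):
        chosen: list[int] = []
        taken: set[int] = set()
        for b in set_bins:
            pool = bin_rows[b]
            g = int(pool[rng.integers(pool.size)])
            while g in taken:
                g = int(pool[rng.integers(pool.size)])
            taken.add(g)
            chosen.append(g)
        null[t] = rmi(X[:, chosen], config).I_alpha
    count = int(np.sum(null >= observed))
    p = max(count, 1) / trials
    return PermutationResult(observed, null, p, trials, seed, statistic="rmi")


def rmi_bootstrap_distribution(
    nm,
    large_target_set,
    subset_size: int = 10,
    trials: int = 10_000,
    config: RMIConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap RMI distribution for a large gene set: per trial, a
    random subset of ``subset_size`` distinct genes is drawn (subsets
    with replacement across trials) and its RMI computed."""
    if config is None:
        config = RMIConfig()
    pool = np.asarray(list(large_target_set))
    if pool.size < subset_size:
        raise ValueError("gene set smaller than subset_size")
    rng = np.random.default_rng(seed)
    out = np.empty(trials)
    for t in range(trials):
        subset = rng.choice(pool, size=subset_size, replace=False)
        out[t] = rmi(_matrix_for(nm, subset), config).I_alpha
    return out


def entropy_prefilter(
    nm_by_condition: dict[str, object],
    percentile: float = 5.0,
    config: RMIConfig | None = None,
) -> list[str]:
    """Drop the lowest-entropy genes per condition; keep the intersection.

    Per condition, each gene's 1-D Renyi entropy across cells is
    estimated and the ceil(percentile% * G) genes of smallest entropy
    are excluded; a gene must survive in every condition to be retained.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    if config is None:
        config = RMIConfig()
    survivors: list[set[str]] = []
    for cond, nm in nm_by_condition.items():
        values = as_frame(nm)
        genes = list(values.index)
        ent = []
        for g in genes:
            x = values.loc[g].to_numpy(dtype=float)
            z = _as_column(x)
            ent.append(renyi_entropy(z, config).H_alpha)
        ent = pd.Series(ent, index=genes)
        m = int(np.ceil(percentile / 100.0 * len(genes)))
        dropped = set(ent.sort_values(kind="stable").index[:m])
        survivors.append(set(genes) - dropped)
    values0 = next(iter(nm_by_condition.values()))
    values0 = as_frame(values0)
    common = set.intersection(*survivors)
    return [g for g in values0.index if g in common]


def _as_column(x: np.ndarray) -> np.ndarray:
    """A gene's raw expression values as an n x 1 sample for the 1-D
    entropy.  The univariate copula transform would erase all
    information (every gene becomes the same grid), so the prefilter
    works on raw values: differential entropy then grows with expression
    spread, and constant or heavily tied genes collapse onto few points
    and get strongly negative entropy."""
    return np.asarray(x, dtype=float)[:, None]


def delta_rmi_test(
    nm_a,
    nm_b,
    gene_set,
    trials: int = 1_000,
    config: RMIConfig | None = None,
    seed: int = 0,
    binned: BinAssignment | None = None,
) -> PermutationResult:
    """Signed differential co-expression test.

    delta = RMI(A) - RMI(B) for the gene set; the null draws random
    same-size gene sets (from the common measured genes; optionally
    expression-binned when ``binned`` is supplied) and recomputes delta.
    p is the two-sided empirical p-value — twice the smaller tail
    fraction, floored at 1/trials — so the test holds its nominal size;
    the sign of delta carries the direction.
    """
    if config is None:
        config = RMIConfig()
    if trials < 100:
        raise ValueError("trials must be >= 100")
    va = as_frame(nm_a)
    vb = as_frame(nm_b)
    common = [g for g in va.index if g in set(vb.index)]
    gene_set = [g for g in gene_set if g in set(common)]
    d = len(gene_set)
    if d < 2:
        raise ValueError("gene set empty (or singleton) after restriction to common genes")

    Xa = va.loc[common].to_numpy().T  # cells x common genes
    Xb = vb.loc[common].to_numpy().T
    row = {g: i for i, g in enumerate(common)}

    def delta(rows) -> float:
        ia = rmi(Xa[:, rows], config).I_alpha
        ib = rmi(Xb[:, rows], config).I_alpha
        return ia - ib

    set_rows = [row[g] for g in gene_set]
    observed = delta(set_rows)
    rng = np.random.default_rng(seed)
    null = np.empty(trials)
    if binned is None:
        for t in range(trials):
            null[t] = delta(rng.choice(len(common), size=d, replace=False))
    else:
        common_set = set(common)
        bin_rows = [np.array([row[g] for g in b if g in common_set]) for b in binned.bins]
        set_bins = [binned.bin_of[g] for g in gene_set]
        for t in range(trials):
            chosen: list[int] = []
            taken: set[int] = set()
            for b in set_bins:
                pool = bin_rows[b]
                g = int(pool[rng.integers(pool.size)])
                while g in taken:
                    g = int(pool[rng.integers(pool.size)])
                taken.add(g)
                chosen.append(g)
            null[t] = delta(chosen)
    # two-sided empirical p: twice the smaller tail (floored at 1/trials)
    # so the test holds its nominal size; the direction is carried by the
    # sign of the observed delta
    count_hi = int(np.sum(null >= observed))
    count_lo = int(np.sum(null <= observed))
    p = min(1.0, 2.0 * max(min(count_hi, count_lo), 1) / trials)
    return PermutationResult(observed, null, p, trials, seed, statistic="delta_rmi")


def define_targets(
    de_down,
    sources: dict[str, object],
    de_down_wt=None,
    min_support: int = 2,
) -> TargetSets:
    """Predicted targets = downregulated genes that any prediction source
    supports; high confidence = those supported by at least
    ``min_support`` sources, optionally further intersected with genes
    also downregulated in the wild-type comparison (for an endogenously
    expressed miRNA family)."""
    if not sources:
        raise ValueError("need at least one prediction source")
    down = list(de_down)
    union: set[str] = set()
    support = {}
    for name, genes in sources.items():
        union |= set(genes)
    predicted = [g for g in down if g in union]
    for g in predicted:
        support[g] = sum(1 for genes in sources.values() if g in set(genes))
    hc = [g for g in predicted if support[g] >= min_support]
    if de_down_wt is not None:
        wt = set(de_down_wt)
        hc = [g for g in hc if g in wt]
    return TargetSets(
        predicted=tuple(predicted),
        high_confidence=tuple(hc),
        support=pd.Series(support, dtype=int, name="support"),
    )
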