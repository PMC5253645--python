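"""Cell-cell correlation distances, heterogeneity tests and
subpopulation discovery.

The cell-cell distance convention is ``1 - |PCC|``: pairs of cells with
strongly correlated (or anti-correlated) transcriptomes are close.
Subpopulations come from an average-linkage dendrogram cut adaptively
(a hybrid dynamic cut): candidate cuts at every depth are scored by
silhouette quality, clusters below the minimum size are dissolved and
their cells reassigned to the nearest surviving cluster by mean
distance, and a split is only accepted when it beats the
single-population solution by a sensitivity margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rmicell._utils import as_frame
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "DistanceMatrix",
    "SubpopulationAssignment",
    "cell_distance_matrix",
    "compare_population_correlation",
    "find_subpopulations",
    "intercluster_distance_test",
]


@dataclass
class DistanceMatrix:
    """Symmetric cell-cell distances with the convention recorded."""

    values: pd.DataFrame
    convention: str = "one_minus_abs_pcc"

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(v, 0.0)

    @property
    def cells(self) -> pd.Index:
        return self.values.index


@dataclass
class SubpopulationAssignment:
    """Cluster label per cell (0 = unassigned), with the linkage used."""

    labels: pd.Series
    linkage: np.ndarray
    min_cluster_size: int
    deep_split: float

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels > 0])))


def cell_distance_matrix(nm, gene_subset=None) -> DistanceMatrix:
    """Pairwise cell distance 1 - |Pearson correlation| across genes."""
    values = as_frame(nm)
    if gene_subset is not None:
        values = values.loc[[g for g in gene_subset if g in values.index]]
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 cells")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 genes after subsetting")
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        bad = values.columns[constant][0]
        raise ValueError(f"cell {bad!r} has zero variance across genes")
    R = np.corrcoef(X.T)
    D = 1.0 - np.abs(R)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    df = pd.DataFrame(D, index=values.columns, columns=values.columns)
    return DistanceMatrix(df)


def _within_condition_pcc(nm) -> np.ndarray:
    X = as_frame(nm).to_numpy(dtype=float)
    R = np.corrcoef(X.T)
    iu = np.triu_indices_from(R, k=1)
    return R[iu]


def compare_population_correlation(nm_a, nm_b, alternative: str):
    """One-tailed Mann-Whitney U comparing the two conditions' sets of
    within-condition pairwise cell-cell Pearson correlations.

    ``alternative``: 'greater' tests whether condition A's correlations
    are stochastically larger (A more homogeneous), 'less' the reverse.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    pcc_a = _within_condition_pcc(nm_a)
    pcc_b = _within_condition_pcc(nm_b)
    if pcc_a.size < 3 or pcc_b.size < 3:
        raise ValueError("need >= 3 cells per condition")
    res = stats.mannwhitneyu(pcc_a, pcc_b, alternative=alternative)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "median_diff": float(np.median(pcc_a) - np.median(pcc_b)),
    }


def _dissolve_small(labels: np.ndarray, D: np.ndarray, min_size: int) -> np.ndarray:
    """Dissolve clusters below ``min_size`` and reassign their cells to
    the nearest retained cluster by mean distance (the PAM-like stage of
    a hybrid tree cut)."""
    labels = labels.copy()
    sizes = pd.Series(labels).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_size]
    if not keep:
        return np.ones_like(labels)
    small = set(sizes.index) - set(keep)
    if small:
        for i in np.where(np.isin(labels, list(small)))[0]:
            mean_d = {c: D[i, labels == c].mean() for c in keep}
            labels[i] = min(mean_d, key=mean_d.get)
    # relabel 1..K by cluster size (largest first) for determinism
    remap = {c: r + 1 for r, c in enumerate(pd.Series(labels).value_counts().index)}
    return np.array([remap[c] for c in labels])


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width over cells for a precomputed distance
    matrix (cluster cohesion vs separation, in [-1, 1])."""
    n = D.shape[0]
    clusters = np.unique(labels)
    if clusters.size < 2:
        return 0.0
    s = np.empty(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        a = D[i, own].mean() if own.any() else 0.0
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


def find_subpopulations(
    d: DistanceMatrix,
    min_cluster_size: int = 5,
    deep_split: float = 0.08,
    max_clusters: int | None = None,
) -> SubpopulationAssignment:
    """Hybrid adaptive cut of the average-linkage tree on ``d``.

    Candidate partitions are generated by cutting the dendrogram into
    k = 2..K_max branches; each candidate has its undersized branches
    (below ``min_cluster_size``, typically outlying cells split off near
    the root) dissolved and reassigned to the nearest retained cluster
    by mean distance.  The partition with the highest mean silhouette
    width wins, and a split is accepted over the single-cluster solution
    only when that silhouette reaches ``deep_split`` — the
    split-sensitivity knob: lower values split more readily.
    Deterministic given the distance matrix.
    """
    D = d.values.to_numpy()
    n = D.shape[0]
    if n < 2 * min_cluster_size:
        raise ValueError(f"need >= {2 * min_cluster_size} cells")
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    k_max = max_clusters if max_clusters is not None else max(2, n // min_cluster_size)
    best_labels = np.ones(n, dtype=int)
    best_score = deep_split
    for k in range(2, min(k_max, n - 1) + 1):
        cand = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        cand = _dissolve_small(cand, D, min_cluster_size)
        if len(np.unique(cand)) < 2:
            continue
        score = _mean_silhouette(D, cand)
        if score > best_score:
            best_score, best_labels = score, cand
    return SubpopulationAssignment(
        labels=pd.Series(best_labels, index=d.cells, name="subpopulation"),
        linkage=Z,
        min_cluster_size=min_cluster_size,
        deep_split=deep_split,
    )


def _percell_intercluster(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per cell, mean distance to every cell outside its own cluster."""
    out = np.empty(D.shape[0])
    for i in range(D.shape[0]):
        mask = labels != labels[i]
        out[i] = D[i, mask].mean()
    return out


def intercluster_distance_test(
    d_a: DistanceMatrix, labels_a: pd.Series, d_b: DistanceMatrix, labels_b: pd.Series
):
    """Two-tailed Mann-Whitney test comparing conditions by each cell's
    mean distance to cells outside its own subpopulation — larger values
    mean more distinct, better-separated subpopulations."""
    la = labels_a.reindex(d_a.cells).to_numpy()
    lb = labels_b.reindex(d_b.cells).to_numpy()
    for name, lab in (("A", la), ("B", lb)):
        if len(set(lab)) < 2:
            raise ValueError(f"condition {name} has a single cluster; statistic undefined")
    stat_a = _percell_intercluster(d_a.values.to_numpy(), la)
    stat_b = _percell_intercluster(d_b.values.to_numpy(), lb)
    res = stats.mannwhitneyu(stat_a, stat_b, alternative="two-sided")
    return {
        "per_cell_a": pd.Series(stat_a, index=d_a.cells),
        "per_cell_b": pd.Series(stat_b, index=d_b.cells),
        "U": float(res.statistic),
        "p": float(res.pvalue),
    }
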