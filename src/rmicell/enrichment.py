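"""Gene-set enrichment scoring (classical KS running sum), PCA, and
ANOVA of per-cell enrichment scores across subpopulations.

The enrichment score (ES) of a gene set on a ranked gene list is the
signed maximal deviation of a running sum that steps up by 1/|hits| at
set members and down by 1/|misses| otherwise — exactly the two-sample
Kolmogorov-Smirnov statistic between member and non-member positions,
signed by whichever extremum is larger in magnitude (positive ES: the
set is concentrated at the top of the ranking; negative: depleted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentScore",
    "ks_enrichment",
    "cell_pathway_scores",
    "pca_embed",
    "pc_loading_gsea",
    "subpopulation_anova",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. hallmark pathways or phase programs."""

    sets: dict[str, tuple[str, ...]]
    source: str | None = None

    def __post_init__(self) -> None:
        self.sets = {name: tuple(genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict(self, universe, min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with the measured-gene universe, dropping
        sets that fall below ``min_size`` (with a warning)."""
        uni = set(universe)
        out: dict[str, tuple[str, ...]] = {}
        for name, genes in self.sets.items():
            kept = tuple(g for g in genes if g in uni)
            if len(kept) >= min_size:
                out[name] = kept
            else:
                logger.warning("gene set %r empty after intersection; dropped", name)
        return GeneSetCollection(out, self.source)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = tuple(g for g in parts[2:] if g)
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.source or "rmicell", *genes]) + "\n")


@dataclass(frozen=True)
class EnrichmentScore:
    ES: float
    p: float
    fdr: float | None = None
    set_name: str | None = None


def _signed_ks(hit_mask: np.ndarray) -> float:
    """Signed maximal running-sum deviation for a boolean hit vector along
    a ranking.  Sign follows the larger-magnitude extremum; on an exact
    magnitude tie the extremum reached first along the ranking wins."""
    n = hit_mask.size
    m = int(hit_mask.sum())
    if m == 0 or m == n:
        raise ValueError("gene set must be a proper nonempty subset of the ranking")
    step = np.where(hit_mask, 1.0 / m, -1.0 / (n - m))
    run = np.cumsum(step)
    i_max = int(np.argmax(run))
    i_min = int(np.argmin(run))
    hi, lo = run[i_max], run[i_min]
    if abs(hi) > abs(lo) + 1e-15:
        return float(hi)
    if abs(lo) > abs(hi) + 1e-15:
        return float(lo)
    return float(hi if i_max < i_min else lo)


def ks_enrichment(ranking, gene_set) -> EnrichmentScore:
    """ES and KS p-value of ``gene_set`` on an ordered gene list."""
    ranking = list(ranking)
    members = set(gene_set) & set(ranking)
    if not members:
        raise ValueError("gene set does not intersect the ranking")
    if len(members) == len(ranking):
        raise ValueError("gene set covers the whole ranking; ES undefined")
    hit = np.fromiter((g in members for g in ranking), dtype=bool, count=len(ranking))
    es = _signed_ks(hit)
    pos = np.arange(len(ranking))
    p = float(stats.ks_2samp(pos[hit], pos[~hit]).pvalue)
    return EnrichmentScore(ES=es, p=p)


def cell_pathway_scores(
    nm, collection: GeneSetCollection, seed: int = 0
) -> pd.DataFrame:
    """Cells x sets matrix of per-cell enrichment scores.

    Per cell, genes are ranked by that cell's expression descending; ties
    (pervasive in counts) are broken by a seeded random shuffle so the
    result is deterministic given the seed.
    """
    values = nm.values
    coll = collection.restrict(values.index)
    if len(coll) == 0:
        raise ValueError("no gene set survives intersection with measured genes")
    genes = np.asarray(values.index)
    rng = np.random.default_rng(seed)
    masks = {name: np.isin(genes, list(gset)) for name, gset in coll}
    out = np.empty((values.shape[1], len(coll)))
    for ci, cell in enumerate(values.columns):
        x = values[cell].to_numpy()
        order = np.lexsort((rng.random(x.size), -x))
        for si, (name, _) in enumerate(coll):
            out[ci, si] = _signed_ks(masks[name][order])
    return pd.DataFrame(out, index=values.columns, columns=[n for n, _ in coll])


def pca_embed(nm, n_components: int = 10):
    """Centred (unscaled) PCA of cells over genes.

    Returns ``(scores, loadings, variance_ratio)``; sign fixed so each
    loading vector's largest-magnitude entry is positive.
    """
    X = nm.values.to_numpy().T  # cells x genes
    n_cells = X.shape[0]
    if n_cells < 2:
        raise ValueError("need >= 2 cells")
    k = min(n_components, n_cells - 1, X.shape[1])
    if k < n_components:
        logger.warning("truncating to %d components (requested %d)", k, n_components)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=nm.values.columns, columns=cols),
        pd.DataFrame(loadings, index=nm.values.index, columns=cols),
        pd.Series(pca.explained_variance_ratio_, index=cols, name="variance_ratio"),
    )


def pc_loading_gsea(
    loadings: pd.Series, collection: GeneSetCollection, fdr_threshold: float = 0.10
) -> pd.DataFrame:
    """GSEA on one component's loadings, genes ranked by descending
    loading.  Returns the full per-set table (es, p, fdr, significant);
    ``significant`` marks positive-ES sets at FDR below the threshold,
    the table is ordered by p so significant sets rank first."""
    ranking = list(loadings.sort_values(ascending=False).index)
    coll = collection.restrict(ranking)
    rows = []
    for name, gset in coll:
        sc = ks_enrichment(ranking, gset)
        rows.append((name, sc.ES, sc.p))
    tab = pd.DataFrame(rows, columns=["set", "es", "p"]).set_index("set")
    tab["fdr"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
    tab["significant"] = (tab["es"] > 0) & (tab["fdr"] < fdr_threshold)
    return tab.sort_values("p")


def subpopulation_anova(
    es_matrix: pd.DataFrame, labels: pd.Series, fdr_threshold: float = 0.10
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per gene set of per-cell enrichment
    scores across subpopulations, BH-corrected across sets.  Singleton
    groups are excluded with a warning."""
    labels = labels.reindex(es_matrix.index)
    counts = labels.value_counts()
    good = [g for g in counts.index if counts[g] >= 2]
    dropped = [g for g in counts.index if counts[g] < 2]
    if dropped:
        logger.warning("excluding singleton groups: %s", dropped)
    if len(good) < 2:
        raise ValueError("need >= 2 groups with >= 2 cells each")
    groups_idx = [labels.index[labels == g] for g in good]
    pvals = []
    for s in es_matrix.columns:
        samples = [es_matrix.loc[idx, s].to_numpy() for idx in groups_idx]
        pvals.append(float(stats.f_oneway(*samples).pvalue))
    tab = pd.DataFrame({"p": pvals}, index=es_matrix.columns)
    tab["fdr"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
    tab["significant"] = tab["fdr"] < fdr_threshold
    return tab.sort_values("p")
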