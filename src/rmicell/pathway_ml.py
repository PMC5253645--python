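"""Pathway ranking by SVM recursive feature elimination.

Pathways (per-cell enrichment-score features) are ranked by how often a
linear maximum-margin classifier keeps them when discriminating two cell
groups.  Many small training instances are drawn (a few cells per
class), RFE removes the feature with the smallest squared weight at each
step, and the per-instance retained feature set is the one maximizing
leave-one-out accuracy along the elimination path.  The selection
frequency across instances is the pathway's relevance; nested relevance
tiers (10/25/50/75%) are evaluated by cross-validated ROC AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["RFERanking", "rfe_rank_pathways", "evaluate_relevance_subsets"]

TIERS = (10.0, 25.0, 50.0, 75.0)


@dataclass
class RFERanking:
    """Per-pathway selection frequency and relevance tier membership."""

    frequency: pd.Series          # pathway -> selections / instances
    n_instances: int
    tiers: dict[float, tuple[str, ...]]  # cutoff percent -> pathways at/above it

    def table(self) -> pd.DataFrame:
        t = pd.DataFrame({"frequency": self.frequency.sort_values(ascending=False)})
        t["rank"] = np.arange(1, len(t) + 1)
        for c in sorted(self.tiers):
            t[f"tier_{int(c)}"] = t.index.isin(self.tiers[c])
        return t


def _loo_accuracy(X: np.ndarray, y: np.ndarray, C: float) -> float:
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
    return correct / n


def _rfe_instance(
    X: np.ndarray, y: np.ndarray, C: float
) -> np.ndarray:
    """One RFE run: eliminate by smallest squared weight, return the
    feature indices of the leave-one-out-optimal step (ties -> fewer
    features)."""
    active = np.arange(X.shape[1])
    best_acc, best_set = -1.0, active.copy()
    while active.size >= 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, active], y)
        acc = _loo_accuracy(X[:, active], y, C)
        if acc >= best_acc:  # >= prefers smaller sets, visited later
            best_acc, best_set = acc, active.copy()
        if active.size == 1:
            break
        w2 = np.asarray(clf.coef_).ravel() ** 2
        # halve the active set each step: with a handful of cells per
        # class the LOO criterion cannot resolve finer granularity anyway
        drop = np.argsort(w2)[: max(1, active.size // 2)]
        active = np.delete(active, drop)
    return best_set


def rfe_rank_pathways(
    es_matrix: pd.DataFrame,
    labels: pd.Series,
    n_instances: int = 1000,
    cells_per_class: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> RFERanking:
    """Rank pathways by RFE selection frequency over random instances.

    Each instance subsamples ``cells_per_class`` cells from each of the
    two classes; degenerate instances (duplicated feature rows) are
    redrawn with a warning.  Deterministic given ``seed``.
    """
    labels = labels.reindex(es_matrix.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    idx_by_class = {c: np.asarray(labels.index[labels == c]) for c in classes}
    for c, idx in idx_by_class.items():
        if len(idx) < cells_per_class:
            raise ValueError(f"class {c!r} has fewer than {cells_per_class} cells")
    rng = np.random.default_rng(seed)
    Xall = es_matrix.to_numpy(dtype=float)
    pos = {cell: i for i, cell in enumerate(es_matrix.index)}
    counts = np.zeros(es_matrix.shape[1])
    for _ in range(n_instances):
        for _attempt in range(10):
            cells = np.concatenate([
                rng.choice(idx_by_class[c], size=cells_per_class, replace=False)
                for c in classes
            ])
            rows = [pos[c] for c in cells]
            X = Xall[rows]
            y = np.array([0] * cells_per_class + [1] * cells_per_class)
            if np.unique(X, axis=0).shape[0] == X.shape[0]:
                break
            logger.warning("degenerate instance (identical cells); resampled")
        selected = _rfe_instance(X, y, C)
        counts[selected] += 1
    freq = pd.Series(counts / n_instances, index=es_matrix.columns, name="frequency")
    tiers = {c: tuple(freq.index[freq >= c / 100.0]) for c in TIERS}
    return RFERanking(frequency=freq, n_instances=n_instances, tiers=tiers)


def evaluate_relevance_subsets(
    es_matrix: pd.DataFrame,
    labels: pd.Series,
    ranking: RFERanking,
    cutoffs=TIERS,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> pd.Series:
    """Cross-validated ROC AUC of a linear SVM restricted to the pathways
    at or above each relevance cutoff; empty subsets yield NaN."""
    labels = labels.reindex(es_matrix.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = (labels == classes[1]).to_numpy(dtype=int)
    out = {}
    for cut in cutoffs:
        if not 0 < cut <= 100:
            raise ValueError("cutoffs must lie in (0, 100]")
        feats = [p for p in es_matrix.columns if ranking.frequency[p] >= cut / 100.0]
        if not feats:
            logger.warning("cutoff %s%%: no pathway qualifies; not evaluable", cut)
            out[cut] = np.nan
            continue
        X = es_matrix[feats].to_numpy(dtype=float)
        n_splits = min(folds, int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        aucs = []
        for tr, te in skf.split(X, y):
            clf = SVC(kernel="linear", C=C)
            clf.fit(X[tr], y[tr])
            score = clf.decision_function(X[te])
            if len(set(y[te])) < 2:
                continue
            aucs.append(roc_auc_score(y[te], score))
        out[cut] = float(np.mean(aucs)) if aucs else np.nan
    return pd.Series(out, name="cv_auc")
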