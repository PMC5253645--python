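"""Marker-pair cell-cycle phase calls and phase-structure statistics.

Phase assignment uses a relative-expression ("pairs") vote: during
training, gene pairs are kept whose within-cell ordering (g1 > g2) is
characteristic of one phase — frequent inside the phase, infrequent
outside.  At prediction time each phase scores the fraction of its pairs
whose ordering holds in the cell; the phase with the highest score wins.
Because only within-cell orderings are used, no further normalization of
the expression matrix is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from rmicell._utils import as_frame

PHASES = ("G1", "S", "G2M")

__all__ = [
    "MarkerPairs",
    "PhaseCall",
    "train_pairs",
    "predict_phase",
    "phase_composition_test",
    "phase_gene_correlation",
]


@dataclass
class MarkerPairs:
    """Per-phase marker gene pairs with their training frequencies."""

    pairs: dict[str, list[tuple[str, str]]]
    in_phase_freq: dict[str, list[float]]
    out_phase_freq: dict[str, list[float]]
    margin: float


@dataclass
class PhaseCall:
    """Per-cell phase scores and the winning call."""

    scores: pd.DataFrame        # cells x phases, each in [0, 1]
    calls: pd.Series            # per cell: phase or "unassigned"
    margin: pd.Series           # winner score minus runner-up score


def train_pairs(
    training_matrix: pd.DataFrame,
    phase_labels: pd.Series,
    candidate_genes=None,
    margin: float = 0.2,
) -> MarkerPairs:
    """Select phase-characteristic gene pairs from labelled cells.

    An ordered pair (g1, g2) is a marker of phase P when g1 > g2 holds in
    at least ``0.5 + margin`` of P cells and at most ``0.5 - margin`` of
    non-P cells.  Deterministic.
    """
    labels = phase_labels.reindex(training_matrix.columns)
    phases = [p for p in PHASES if (labels == p).sum() > 0]
    for p in phases:
        if (labels == p).sum() < 3:
            raise ValueError(f"need >= 3 training cells for phase {p}")
    genes = list(candidate_genes) if candidate_genes is not None else list(training_matrix.index)
    genes = [g for g in genes if g in training_matrix.index]
    X = training_matrix.loc[genes].to_numpy(dtype=float)

    pairs: dict[str, list[tuple[str, str]]] = {p: [] for p in phases}
    fin: dict[str, list[float]] = {p: [] for p in phases}
    fout: dict[str, list[float]] = {p: [] for p in phases}
    for p in phases:
        in_mask = (labels == p).to_numpy()
        out_mask = ~in_mask
        Xin, Xout = X[:, in_mask], X[:, out_mask]
        for i, j in permutations(range(len(genes)), 2):
            f_in = float(np.mean(Xin[i] > Xin[j]))
            f_out = float(np.mean(Xout[i] > Xout[j]))
            if f_in >= 0.5 + margin and f_out <= 0.5 - margin:
                pairs[p].append((genes[i], genes[j]))
                fin[p].append(f_in)
                fout[p].append(f_out)
    if all(len(v) == 0 for v in pairs.values()):
        raise ValueError("no marker pair passed the margin; try a lower margin")
    return MarkerPairs(pairs=pairs, in_phase_freq=fin, out_phase_freq=fout, margin=margin)


def predict_phase(nm, pairs: MarkerPairs) -> PhaseCall:
    """Score each cell against every phase's marker pairs and call the
    argmax phase; exact score ties give "unassigned"."""
    values = as_frame(nm)
    usable = {}
    for p, plist in pairs.pairs.items():
        plist = [(a, b) for a, b in plist if a in values.index and b in values.index]
        if not plist:
            raise ValueError(f"phase {p} has no usable marker pair in the matrix")
        usable[p] = plist
    phases = list(usable)
    scores = np.zeros((values.shape[1], len(phases)))
    X = values.to_numpy(dtype=float)
    gidx = {g: i for i, g in enumerate(values.index)}
    for pi, p in enumerate(phases):
        ia = np.array([gidx[a] for a, _ in usable[p]])
        ib = np.array([gidx[b] for _, b in usable[p]])
        scores[:, pi] = (X[ia] > X[ib]).mean(axis=0)
    sc = pd.DataFrame(scores, index=values.columns, columns=phases)
    ordered = np.sort(scores, axis=1)
    top = ordered[:, -1]
    second = ordered[:, -2] if len(phases) > 1 else np.zeros_like(top)
    calls = []
    for i in range(scores.shape[0]):
        winners = [phases[j] for j in range(len(phases)) if scores[i, j] == top[i]]
        calls.append(winners[0] if len(winners) == 1 else "unassigned")
    return PhaseCall(
        scores=sc,
        calls=pd.Series(calls, index=values.columns, name="phase"),
        margin=pd.Series(top - second, index=values.columns, name="margin"),
    )


def phase_composition_test(calls_a: pd.Series, calls_b: pd.Series) -> pd.DataFrame:
    """Per phase, Fisher's exact test (two-sided) on the 2x2 table of
    in-phase versus other cells between the two conditions."""
    if len(calls_a) == 0 or len(calls_b) == 0:
        raise ValueError("both conditions must have cells")
    rows = []
    for p in PHASES:
        a_in = int((calls_a == p).sum())
        b_in = int((calls_b == p).sum())
        table = [[a_in, len(calls_a) - a_in], [b_in, len(calls_b) - b_in]]
        odds, pval = stats.fisher_exact(table, alternative="two-sided")
        rows.append((p, a_in, b_in, odds, pval))
    return pd.DataFrame(rows, columns=["phase", "n_a", "n_b", "odds_ratio", "p"]).set_index("phase")


def phase_gene_correlation(
    nm, phase_sets, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-gene correlation among phase-annotated genes, block-ordered
    by phase, with the mean off-diagonal within-phase correlation as the
    per-phase summary.  Missing genes raise with an explicit list."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    values = as_frame(nm)
    if values.shape[1] < 3:
        raise ValueError("need >= 3 cells")
    sets = phase_sets.sets if hasattr(phase_sets, "sets") else phase_sets
    missing = [g for genes in sets.values() for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"phase genes missing from matrix: {sorted(set(missing))}")
    ordered: list[str] = []
    blocks: dict[str, list[str]] = {}
    for p, genes in sets.items():
        genes = list(genes)
        if len(genes) < 2:
            raise ValueError(f"phase {p!r} needs >= 2 genes")
        blocks[p] = genes
        ordered.extend(genes)
    sub = values.loc[ordered].T  # cells x genes
    corr = sub.corr(method=method)
    summary = {}
    for p, genes in blocks.items():
        block = corr.loc[genes, genes].to_numpy()
        iu = np.triu_indices_from(block, k=1)
        summary[p] = float(block[iu].mean())
    return corr, pd.Series(summary, name=f"mean_within_phase_{method}")
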