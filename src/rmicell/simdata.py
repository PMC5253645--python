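"""Synthetic single-cell count data with controllable structure.

The generator emulates a four-condition single-miRNA-transfection
experiment in miRNA-deficient mouse embryonic stem cells: an untreated
miRNA-deficient control, two miRNA-transfected conditions, and a
wild-type-like condition.  Counts follow a Gaussian copula over
negative-binomial marginals, so marginal behaviour (per-gene mean and
dispersion, per-cell library size) and dependence structure (latent
correlation blocks) are independently tunable:

1. per cell, a latent multivariate normal is drawn whose correlation
   matrix carries compound-symmetric blocks for the miRNA target sets,
   the three cell-cycle phase programs, and whose mean carries shifts for
   the cell's phase and discrete subpopulation;
2. each latent coordinate is pushed through the standard normal CDF to a
   uniform;
3. the uniform is inverted through the gene's negative-binomial quantile
   function at mean ``mu_g * library_factor * 2**(-delta)`` (the
   repression ``delta`` applies to target genes in the matching
   transfected condition only).

Ground truth (target sets, block correlations, per-cell phase and
subpopulation labels, expected fold changes) is returned alongside the
counts so every downstream stage can be scored without external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TargetBlock",
    "PhasePrograms",
    "Subpopulations",
    "SimConfig",
    "GroundTruth",
    "simulate_experiment",
    "make_gene_sets",
    "make_target_predictions",
    "write_experiment",
]

PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class TargetBlock:
    """A miRNA's true target genes and their induced structure.

    rho : latent within-block correlation per condition.
    delta : log2 repression applied in the conditions listed in
        ``repressed_in`` (typically the matching transfected condition,
        plus the wild-type-like condition for an endogenously expressed
        miRNA family).
    """

    genes: tuple[int, ...]
    rho: dict[str, float]
    delta: float = 1.0
    repressed_in: tuple[str, ...] = ()


@dataclass(frozen=True)
class PhasePrograms:
    """Cell-cycle phase gene programs (G1, S, G2/M blocks)."""

    genes: dict[str, tuple[int, ...]]  # phase -> gene indices
    rho: float = 0.4                   # within-phase latent correlation
    mean_shift: float = 2.0            # latent up-shift of a phase's program in its phase
    proportions: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    # condition -> (G1, S, G2M) mixing proportions


@dataclass(frozen=True)
class Subpopulations:
    """Discrete subpopulation structure within each condition."""

    n_groups: int = 0
    genes_per_group: int = 30
    mean_shift: float = 2.0            # latent SD units on the group's gene block
    probabilities: dict[str, tuple[float, ...]] = field(default_factory=dict)
    # condition -> assignment probabilities (len n_groups)


@dataclass(frozen=True)
class SimConfig:
    """Full generative configuration; deterministic given ``seed``."""

    n_genes: int = 2000
    n_cells_per_condition: int = 60
    conditions: tuple[str, ...] = ("dgcr8", "mir294", "let7c", "wt")
    target_blocks: dict[str, TargetBlock] = field(default_factory=dict)
    phase_programs: PhasePrograms | None = None
    subpopulations: Subpopulations | None = None
    mean_log_mu: float = np.log(50.0)  # per-gene mean ~ log-normal
    sd_log_mu: float = 2.0
    dispersion: float = 1.0            # NB size parameter (1/overdispersion)
    sigma_lib: float = 0.3             # per-cell log-normal library factor
    seed: int = 0

    def validate(self) -> None:
        blocks: list[tuple[str, tuple[int, ...]]] = [
            (name, tb.genes) for name, tb in self.target_blocks.items()
        ]
        if self.phase_programs is not None:
            blocks += [(f"phase:{ph}", g) for ph, g in self.phase_programs.genes.items()]
        seen: dict[int, str] = {}
        for name, genes in blocks:
            for g in genes:
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"block {name!r}: gene index {g} >= n_genes")
                if g in seen:
                    raise ValueError(f"blocks {seen[g]!r} and {name!r} overlap at gene {g}")
                seen[g] = name
        for name, tb in self.target_blocks.items():
            for cond, rho in tb.rho.items():
                m = len(tb.genes)
                if m > 1 and not (-1.0 / (m - 1) <= rho <= 1.0):
                    raise ValueError(
                        f"target block {name!r}, condition {cond!r}: rho={rho} makes the "
                        f"compound-symmetric {m}x{m} latent correlation non-PSD"
                    )
        pp = self.phase_programs
        if pp is not None:
            for cond, props in pp.proportions.items():
                if len(props) != 3 or abs(sum(props) - 1.0) > 1e-9:
                    raise ValueError(f"phase proportions for {cond!r} must be 3 values summing to 1")
            for ph, g in pp.genes.items():
                m = len(g)
                if m > 1 and not (-1.0 / (m - 1) <= pp.rho <= 1.0):
                    raise ValueError(f"phase block {ph!r}: rho={pp.rho} non-PSD for size {m}")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-like configuration: two miRNAs with 40-gene
    target blocks (correlated and 2-fold repressed in the matching
    transfected condition; the ESCC-like miRNA also acts in the
    wild-type-like condition), three 12-gene phase programs with
    condition-specific phase mixing, and three subpopulations."""
    tb = {
        "mir294": TargetBlock(
            genes=tuple(range(0, 40)),
            rho={"dgcr8": 0.0, "mir294": 0.6, "let7c": 0.0, "wt": 0.6},
            delta=1.0,
            repressed_in=("mir294", "wt"),
        ),
        "let7c": TargetBlock(
            genes=tuple(range(40, 80)),
            rho={"dgcr8": 0.0, "mir294": 0.0, "let7c": 0.6, "wt": 0.0},
            delta=1.0,
            repressed_in=("let7c",),
        ),
    }
    pp = PhasePrograms(
        genes={"G1": tuple(range(80, 92)), "S": tuple(range(92, 104)), "G2M": tuple(range(104, 116))},
        rho=0.4,
        mean_shift=2.0,
        proportions={
            "dgcr8": (0.50, 0.30, 0.20),
            "mir294": (0.30, 0.40, 0.30),
            "let7c": (0.65, 0.20, 0.15),
            "wt": (0.30, 0.40, 0.30),
        },
    )
    n_genes = int(overrides.get("n_genes", 2000))
    sub = Subpopulations(
        n_groups=3,
        genes_per_group=max(20, n_genes // 20),  # ~5% of genes per program
        mean_shift=2.0,
        probabilities={c: (1 / 3, 1 / 3, 1 / 3) for c in ("dgcr8", "mir294", "let7c", "wt")},
    )
    cfg = dict(
        seed=seed, target_blocks=tb, phase_programs=pp, subpopulations=sub,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


@dataclass
class GroundTruth:
    """What the generator actually planted, for scoring recovery."""

    true_targets: dict[str, tuple[str, ...]]            # miRNA -> gene ids
    block_rho: dict[str, dict[str, float]]              # miRNA -> condition -> rho
    phase_genes: dict[str, tuple[str, ...]]             # phase -> gene ids
    phase_labels: pd.Series                             # per cell
    subpop_labels: pd.Series                            # per cell
    expected_log2_fc: pd.DataFrame                      # gene x condition (vs control)
    conditions: pd.Series                               # per cell

    def to_json(self, path: str | Path) -> None:
        obj = {
            "true_targets": {k: list(v) for k, v in self.true_targets.items()},
            "block_rho": self.block_rho,
            "phase_genes": {k: list(v) for k, v in self.phase_genes.items()},
            "phase_labels": self.phase_labels.to_dict(),
            "subpop_labels": {k: int(v) for k, v in self.subpop_labels.items()},
            "conditions": self.conditions.to_dict(),
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _sample_condition_latent(
    rng: np.random.Generator,
    cfg: SimConfig,
    condition: str,
    n_cells: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent N(0,1)-marginal matrix (cells x genes) with the condition's
    block correlations and per-cell phase/subpopulation mean shifts.
    Compound-symmetric blocks with rho >= 0 are sampled through a shared
    factor; negative rho (valid down to -1/(m-1)) through a Cholesky root.
    """
    G = cfg.n_genes
    Z = rng.standard_normal((n_cells, G))

    def fill_block(genes: tuple[int, ...], rho: float) -> None:
        m = len(genes)
        if m < 2 or rho == 0.0:
            return
        idx = np.asarray(genes)
        if rho > 0:
            shared = rng.standard_normal((n_cells, 1))
            Z[:, idx] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n_cells, m))
        else:
            R = np.full((m, m), rho)
            np.fill_diagonal(R, 1.0)
            try:
                Lc = np.linalg.cholesky(R + 1e-12 * np.eye(m))
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"non-PSD latent correlation for block of size {m}, rho={rho}") from exc
            Z[:, idx] = rng.standard_normal((n_cells, m)) @ Lc.T

    for name, tb in cfg.target_blocks.items():
        fill_block(tb.genes, tb.rho.get(condition, 0.0))

    phase_labels = np.array([""] * n_cells, dtype=object)
    pp = cfg.phase_programs
    if pp is not None:
        props = pp.proportions.get(condition, (1 / 3, 1 / 3, 1 / 3))
        phase_labels = rng.choice(PHASES, size=n_cells, p=props)
        for ph in PHASES:
            fill_block(pp.genes.get(ph, ()), pp.rho)
        for ph in PHASES:
            genes = np.asarray(pp.genes.get(ph, ()), dtype=int)
            if genes.size:
                Z[np.ix_(phase_labels == ph, genes)] += pp.mean_shift

    subpop_labels = np.zeros(n_cells, dtype=int)
    sp = cfg.subpopulations
    if sp is not None and sp.n_groups > 0:
        probs = sp.probabilities.get(condition, tuple([1 / sp.n_groups] * sp.n_groups))
        subpop_labels = rng.choice(sp.n_groups, size=n_cells, p=np.asarray(probs)) + 1
        # subpopulation gene blocks sit after the structured blocks, one per group
        start = _first_free_index(cfg)
        for g in range(sp.n_groups):
            lo = start + g * sp.genes_per_group
            hi = min(lo + sp.genes_per_group, G)
            Z[np.ix_(subpop_labels == g + 1, np.arange(lo, hi))] += sp.mean_shift
    return Z, phase_labels, subpop_labels


def _first_free_index(cfg: SimConfig) -> int:
    used = [g for tb in cfg.target_blocks.values() for g in tb.genes]
    if cfg.phase_programs is not None:
        used += [g for gs in cfg.phase_programs.genes.values() for g in gs]
    return (max(used) + 1) if used else 0


def simulate_experiment(config: SimConfig):
    """Draw the full experiment; returns ``(ExpressionMatrix, GroundTruth)``.

    Bit-identical counts for identical ``(config, seed)``.
    """
    from rmicell.preprocess import ExpressionMatrix  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    G, C = config.n_genes, config.conditions
    gene_ids = np.array([f"g{i:05d}" for i in range(G)])

    mu = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, size=G))
    r = config.dispersion

    counts_parts, cells, cond_labels, phases, subpops = [], [], [], [], []
    for cond in C:
        n = config.n_cells_per_condition
        Z, phase_lab, sub_lab = _sample_condition_latent(rng, config, cond, n)
        U = stats.norm.cdf(Z)
        lib = np.exp(rng.normal(0.0, config.sigma_lib, size=n))
        mean = lib[:, None] * mu[None, :]
        for tb in config.target_blocks.values():
            if cond in tb.repressed_in:
                mean[:, np.asarray(tb.genes)] *= 2.0 ** (-tb.delta)
        p_nb = r / (r + mean)
        # clip away u == 1 which would map to infinity in the quantile
        U = np.clip(U, 1e-12, 1 - 1e-12)
        block = stats.nbinom.ppf(U, r, p_nb).astype(np.int64)
        counts_parts.append(block)
        cells.extend(f"{cond}_c{i:03d}" for i in range(n))
        cond_labels.extend([cond] * n)
        phases.extend(phase_lab)
        subpops.extend(sub_lab)

    counts = pd.DataFrame(np.vstack(counts_parts).T, index=gene_ids, columns=cells)
    conditions = pd.Series(cond_labels, index=cells, name="condition")

    fc = pd.DataFrame(0.0, index=gene_ids, columns=list(C))
    for tb in config.target_blocks.values():
        for cond in tb.repressed_in:
            fc.iloc[np.asarray(tb.genes), fc.columns.get_loc(cond)] = -tb.delta

    truth = GroundTruth(
        true_targets={
            name: tuple(gene_ids[np.asarray(tb.genes)]) for name, tb in config.target_blocks.items()
        },
        block_rho={name: dict(tb.rho) for name, tb in config.target_blocks.items()},
        phase_genes=(
            {ph: tuple(gene_ids[np.asarray(g)]) for ph, g in config.phase_programs.genes.items()}
            if config.phase_programs is not None else {}
        ),
        phase_labels=pd.Series(phases, index=cells, name="phase"),
        subpop_labels=pd.Series(subpops, index=cells, name="subpopulation"),
        expected_log2_fc=fc,
        conditions=conditions,
    )
    return ExpressionMatrix(counts=counts, conditions=conditions), truth


def make_gene_sets(truth: GroundTruth, n_decoys_per_set: int = 1, seed: int = 0):
    """Gene-set collection from the planted truth: one set per true target
    list, one per phase program, plus size-matched decoy sets drawn from
    genes outside every planted block.  Empty sets are skipped with a
    warning."""
    from rmicell.enrichment import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = np.asarray(truth.expected_log2_fc.index)
    block_genes: set[str] = set()
    for genes in truth.true_targets.values():
        block_genes.update(genes)
    for genes in truth.phase_genes.values():
        block_genes.update(genes)
    free = np.asarray(sorted(set(universe) - block_genes))

    sets: dict[str, tuple[str, ...]] = {}
    for name, genes in {**{f"targets_{k}": v for k, v in truth.true_targets.items()},
                        **{f"phase_{k}": v for k, v in truth.phase_genes.items()}}.items():
        if not genes:
            logger.warning("gene set %r is empty; omitted", name)
            continue
        sets[name] = tuple(genes)
        for j in range(n_decoys_per_set):
            decoy = rng.choice(free, size=min(len(genes), free.size), replace=False)
            sets[f"decoy_{name}_{j}"] = tuple(sorted(decoy))
    return GeneSetCollection(sets)


def make_target_predictions(
    truth: GroundTruth,
    n_sources: int = 3,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, dict[str, tuple[str, ...]]]:
    """Per-source predicted target lists: the true targets minus false
    negatives (each dropped independently with ``fn_rate``) plus false
    positives (non-targets added with ``fp_rate``), independently per
    source.  Returns ``{miRNA: {source_name: genes}}``."""
    if not (0.0 <= fp_rate <= 1.0 and 0.0 <= fn_rate <= 1.0):
        raise ValueError("fp_rate and fn_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = np.asarray(truth.expected_log2_fc.index)
    out: dict[str, dict[str, tuple[str, ...]]] = {}
    for mirna, targets in truth.true_targets.items():
        targets = np.asarray(targets)
        non_targets = np.asarray(sorted(set(universe) - set(targets)))
        sources: dict[str, tuple[str, ...]] = {}
        for s in range(n_sources):
            keep = targets[rng.random(targets.size) >= fn_rate]
            fps = non_targets[rng.random(non_targets.size) < fp_rate]
            sources[f"source{s + 1}"] = tuple(sorted(set(keep) | set(fps)))
        out[mirna] = sources
    return out


def write_experiment(outdir: str | Path, em, truth: GroundTruth) -> None:
    """Write counts (TSV and MatrixMarket), labels, and truth JSON."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    em.counts.to_csv(outdir / "counts.tsv", sep="\t")
    mmwrite(str(outdir / "counts.mtx"), csr_matrix(em.counts.values))
    (outdir / "genes.tsv").write_text("\n".join(em.counts.index) + "\n")
    (outdir / "cells.tsv").write_text("\n".join(em.counts.columns) + "\n")
    em.conditions.to_csv(outdir / "conditions.tsv", sep="\t", header=True)
    truth.to_json(outdir / "truth.json")
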