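# rmicell

Single-cell analysis of how a microRNA reshapes its target genes'
co-expression, built around a set-wise dependence statistic: **Rényi
multi-information (RMI)** estimated from the empirical copula with a
k-nearest-neighbour-graph entropy estimator.

## The problem

A miRNA represses many target mRNAs at once. Population (bulk) assays
show the average repression, but only single-cell data can show whether
the targets *covary* — whether cells with strong repression of one
target also repress the others, so the target set fluctuates as a unit.
The motivating experimental design introduces single miRNAs (an
ESC-enriched cell-cycle miRNA, or a let-7 family member) into
miRNA-deficient (*Dgcr8*-null-like) embryonic stem cells and sequences
single cells under four conditions: untreated control, two transfected
conditions and a wild-type-like condition. The analysis questions are:

1. Are the miRNA's targets repressed *and* more co-expressed in the
   transfected cells?
2. Does the miRNA increase or decrease cell-to-cell transcriptional
   heterogeneity, and does heterogeneity come from discrete
   subpopulations?
3. How do cell-cycle phase composition and phase-gene co-expression
   change?
4. Which pathways discriminate the transfected conditions?

`rmicell` implements the full statistical pipeline for these questions,
driven by a synthetic-data generator that plants known target blocks,
cell-cycle phase programs and subpopulations, so every stage is testable
without any download.

## The core statistic

For a set of d genes with joint density f and marginals f_j, the Rényi
multi-information of order α is the Rényi divergence between the joint
and the product of marginals. It is estimated in two steps:

1. **Empirical copula transform** — each gene's values across n cells
   are replaced by ranks/n, giving a sample Ẑ on (0,1]^d that carries
   only the dependence structure (exactly invariant under monotone
   per-gene transformations such as normalization or log scaling).
2. **kNN-graph Rényi entropy** — with p = d(1−α),

       Ĥ_α = 1/(1−α) · log( L_p(Ẑ) / (γ n^(1−p/d)) ),

   where L_p is the sum of p-th powers of the Euclidean distances from
   each point to its S-indexed nearest neighbours (defaults k=3,
   S={1,2,3}) and γ is a normalising constant calibrated by Monte Carlo
   at the same (n,d). Then **I_α = −Ĥ_α(Ẑ)**: zero for independent
   genes, increasing with joint dependence; α=0.99 approximates
   classical (Shannon) multi-information.

Around the estimator the package provides expression-matched permutation
tests (null gene sets drawn from 500-gene expression bins), a signed
differential statistic **ΔRMI** between two cell populations with a
permutation null and entropy prefiltering, and a bootstrap over gene
subsets for large target sets.

## Modules

| module | contents |
| --- | --- |
| `rmicell.simdata` | Gaussian-copula / negative-binomial experiment generator with planted ground truth; GMT/TSV/MatrixMarket output |
| `rmicell.preprocess` | median-of-ratios size factors, depth/median/transfection-evidence/gene-mean filters, rank-sum differential expression (Holm) |
| `rmicell.enrichment` | KS running-sum enrichment scores (per ranking and per cell), PCA, PC-loading GSEA, enrichment-score ANOVA across subpopulations |
| `rmicell.heterogeneity` | 1−|PCC| cell distances, heterogeneity comparison (Mann–Whitney), hybrid dendrogram cut subpopulations, inter-cluster separation test |
| `rmicell.rmi` | empirical copula, kNN-graph entropy, γ calibration, RMI |
| `rmicell.inference` | expression bins, RMI permutation test, ΔRMI test, bootstrap RMI, entropy prefilter, miRNA target-set definition |
| `rmicell.cellcycle` | marker-pair phase classifier, Fisher phase-composition tests, phase-gene correlation |
| `rmicell.pathway_ml` | SVM-RFE pathway ranking and relevance-tier AUC evaluation |

A thin `rmicell` CLI exposes the main operations
(`rmicell simulate`, `rmicell rmi compute`, `rmicell coexpr delta`, ...).

## Worked example

```python
import numpy as np
from rmicell import simdata
from rmicell.preprocess import compute_size_factors, differential_expression
from rmicell.inference import (define_targets, delta_rmi_test, entropy_prefilter,
                               expression_bins, rmi_permutation_test)
from rmicell.rmi import RMIConfig

cfg = simdata.default_config(seed=1, n_genes=600, n_cells_per_condition=60)
em, truth = simdata.simulate_experiment(cfg)      # 600 genes x 240 cells
nm = compute_size_factors(em)

# targets = downregulated genes supported by prediction sources
de = differential_expression(nm, "mir294", "dgcr8")
preds = simdata.make_target_predictions(truth, n_sources=3,
                                        fp_rate=0.02, fn_rate=0.2, seed=1)
ts = define_targets(de.downregulated(alpha=0.1), preds["mir294"])

tx = nm.values.loc[:, nm.conditions == "mir294"]
ctrl = nm.values.loc[:, nm.conditions == "dgcr8"]
hc = list(ts.high_confidence)

res = rmi_permutation_test(tx, hc, expression_bins(tx), trials=1000,
                           config=RMIConfig(seed=1), seed=1)
res0 = rmi_permutation_test(ctrl, hc, expression_bins(ctrl), trials=1000,
                            config=RMIConfig(seed=1), seed=1)
kept = entropy_prefilter({"tx": tx, "ctrl": ctrl}, config=RMIConfig(seed=1))
dres = delta_rmi_test(tx.loc[kept], ctrl.loc[kept],
                      [g for g in hc if g in set(kept)],
                      trials=1000, config=RMIConfig(seed=1), seed=1)
```

Output for this seed:

```
downregulated genes (mir294 vs control): 4
predicted targets: 4   high-confidence: 3
RMI of targets in transfected cells: 0.420 (permutation p = 0.002)
RMI of targets in control cells:    -0.175 (permutation p = 0.980)
delta-RMI (transfected - control):  +0.595 (p = 0.002)
target mean-expression ratio (transfected / control): 0.46
```

Reading: the rank-sum screen recovers a few of the planted targets
(single-cell differential expression is deliberately low-powered at 60
cells); those targets are repressed about two-fold in the transfected
cells (ratio 0.46), show no co-expression in the control (RMI ≈ 0,
p ≈ 1) but strong set-wise co-expression after transfection (RMI 0.42
against the expression-matched null, p = 0.002), and the difference
between conditions is itself significant (ΔRMI +0.60, p = 0.002) —
repression and induced co-expression at once, which is the signature
the pipeline is built to detect.

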