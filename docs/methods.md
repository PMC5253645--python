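# Methods

This note documents the models, estimators and numerical choices behind
`rmicell`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic experiment generator (`simdata`)

**Model.** Counts follow a Gaussian copula over negative-binomial (NB)
marginals. For cell i in condition c, a latent vector
z_i ~ N(m_i, Σ_c) with unit variances is drawn; u_ij = Φ(z_ij); the
count is the NB quantile
k_ij = F⁻¹_NB(u_ij; μ_j · ℓ_i · 2^(−δ·[j targeted in c]), r), with
per-gene mean μ_j ~ log-normal, per-cell library factor
ℓ_i ~ log-normal(0, σ_lib) and dispersion (NB size) r. The copula
construction separates marginal behaviour from dependence: latent
correlation blocks survive the quantile mapping as rank dependence, and
the library factor enters the NB mean so the quantile inversion stays
exact (no post-hoc thinning).

**Structure planted.**

* *Target blocks* — one gene block per miRNA, compound-symmetric latent
  correlation ρ_t per condition, log2 repression δ applied in the
  conditions where that miRNA is active. The ESC-cell-cycle-miRNA-like
  block is also active in the wild-type-like condition, mirroring an
  endogenously expressed family.
* *Phase programs* — three disjoint blocks (G1, S, G2/M) with
  within-block correlation ρ_p; cells draw a phase from
  condition-specific mixing proportions and receive a latent up-shift
  of that phase's program.
* *Subpopulations* — k discrete groups per condition; each group
  up-shifts its own gene block.

Compound symmetry keeps each block one-parameter and makes the PSD
check trivial (ρ ≥ −1/(m−1)); positive-ρ blocks are sampled through a
shared factor, negative-ρ blocks through a Cholesky root with an
explicit error naming the offending block.

**Defaults and why.** Per-gene means log-normal(ln 50, sd 2.0): a
desk-scale analogue of deep (>500k-read) full-length single-cell
libraries, deep enough that some genes are detected in every cell —
required by median-of-ratios normalization. Dispersion r = 1
(CV² ≈ 1 above Poisson), σ_lib = 0.3. Four conditions, 60 cells each.
Target blocks of 40 genes with ρ_t = 0.6 and δ = 1 (two-fold
repression) in the matching transfected condition — the source study
reports no effect sizes, so these are calibration choices fixed once.
Phase programs of 12 genes, ρ_p = 0.4, latent shift 2 (curated phase
*markers* are strongly phase-restricted in real data; a 1-SD shift
produces overlapping, non-marker-grade programs). Condition-specific
phase proportions encode the known directions: control G1-long
(0.5/0.3/0.2), ESCC-miRNA-like G1-short (0.3/0.4/0.3), let-7-like
G1-enriched (0.65/0.2/0.15). Subpopulations: three groups, each with a
program of ~5% of genes shifted 2 latent SD.

**What it does not emulate.** No UMI or dropout-specific zero
inflation beyond NB sampling, no read-level simulation, no
gene-length or GC effects, no batch structure, no ortholog mapping.
Passing tests therefore demonstrate the statistical machinery under a
clean dependence model, not robustness to every artefact of real
droplet or full-length data.

## 2. Normalization, filters and the differential screen (`preprocess`)

Size factors are median-of-ratios: factor = median over all-positive
genes of count / per-gene geometric mean. Scaling one of m cells by c
rescales its factor by c^((m−1)/m) and all normalized values by one
global constant — the estimator is scale-equivariant only up to that
reference shift, which is inherent to a geometric-mean reference.

The cell filter chain is: depth (strictly more than `min_reads` total
counts), median diversity (median gene count > 0), then
transfection-evidence. The evidence filter ranks each transfected
cell's genes by log2(cell / reference-condition mean) descending and
requires the signed KS enrichment score of the miRNA's target set to
be negative (targets depleted from the top of the ranking); the
ranking statistic is a package choice — repression is only defined
relative to untransfected cells. Gene filtering keeps genes with mean
≥ `min_mean` (strictly-below removed); the cutoff itself can be chosen
by minimizing the mean two-sample KS distance between resequenced cell
pairs across candidate cutoffs (ties to the smallest cutoff; genes
enter a pair when both members reach the cutoff).

Differential expression is a per-gene Wilcoxon rank-sum test with Holm
family-wise correction and log2 fold changes of pseudocounted (ε = 1)
means. This is a deliberate, well-calibrated substitute for a full
Bayesian single-cell error model: only the resulting downregulated-gene
set feeds later stages, and synthetic evaluation scores recovery
against planted truth.

## 3. Enrichment scoring (`enrichment`)

The enrichment score is the classical (unweighted) KS running sum: walk
the ranking, step +1/|hits| at members and −1/|misses| otherwise; ES is
the extremum of largest magnitude (ties: the extremum reached first),
so |ES| ≤ 1, positive means concentration at the top. P-values come
from the two-sample KS distribution of member vs non-member positions.
Per-cell scores rank genes by that cell's expression descending with
ties broken by a seeded shuffle — count data make ties pervasive and
the seed keeps results reproducible. PCA is centred and unscaled, with
the sign fixed by making each loading vector's largest-magnitude entry
positive. PC-loading GSEA ranks genes by descending loading, applies
Benjamini–Hochberg across gene sets and retains positive-ES sets at
FDR < 10%. The subpopulation ANOVA is one-way fixed-effects per gene
set on per-cell ES values, BH-corrected, singleton groups excluded.

## 4. Heterogeneity and subpopulations (`heterogeneity`)

Cell-cell distance is 1 − |PCC| (the absolute value makes perfectly
anti-correlated profiles close; both statements of the convention in
the source carry the absolute value on PCC, and the package uses
1 − |PCC| everywhere). Distances are computed on whatever expression
values are supplied; the pipeline passes log1p-transformed normalized
expression, since on the raw scale the few highest-mean genes dominate
the correlation and planted subpopulations become invisible.

Subpopulation discovery is a hybrid adaptive cut of the average-linkage
dendrogram: candidate partitions are generated by cutting into
k = 2..⌊n/min_cluster_size⌋ branches; each candidate's undersized
branches (typically outlying cells split off near the root — the
classic failure of fixed-height cuts) are dissolved and their cells
reassigned to the nearest retained cluster by mean distance; the
candidate with the highest mean silhouette width wins, and any split
must reach silhouette ≥ `deep_split` to beat the single-cluster
solution. `deep_split` = 0.08 by default, chosen so that unstructured
correlation-distance matrices stay a single cluster while planted
2-SD-shift subpopulations split; `min_cluster_size` = 5 because
cohorts of ~48–60 cells carrying three subpopulations are incompatible
with the R tool's default minimum of 20. The procedure is
deterministic given the distance matrix.

Heterogeneity comparison is a one-tailed Mann–Whitney U on the two
conditions' sets of within-condition pairwise cell-cell correlations;
the caller states the direction. The inter-cluster statistic is, per
cell, the mean distance to all cells outside its own subpopulation;
conditions are compared two-tailed.

## 5. The RMI estimator (`rmi`)

Empirical copula: entry (i,j) = rank(x_ij)/n with rank(x, A) = #{a ∈ A:
a ≤ x}; ties are broken by a seeded random order so each column is an
exact permutation of {1/n, …, 1}. Entropy: Ĥ_α = (1/(1−α)) ·
log(L_p / (γ n^(1−p/d))) with p = d(1−α); L_p sums the p-th powers of
each point's distances to its S-indexed nearest neighbours (directed
graph: every point contributes its own edges; S = {1,…,k} with k = 3,
α = 0.99). RMI is minus the entropy of the copula sample. Everything
is in nats; γ calibration absorbs any base constant, so only
comparisons across gene sets and conditions are meaningful.

Numerical choices:

* γ is calibrated at the data's own (n, d) as the Monte-Carlo mean of
  L_p/n^(1−p/d) over null samples, and cached. For generic entropy
  estimation the null is i.i.d. uniform on [0,1]^d. For RMI the null
  sample instead has *grid marginals* (each coordinate an independent
  permutation of {1/n,…,1}), exactly matching the marginals that the
  empirical copula enforces; with i.i.d.-uniform calibration the
  copula's overly regular marginals bias RMI by about −0.17 nats at
  (n, d) = (60, 10), and the grid-marginal null removes this at the
  source. In ΔRMI the constant cancels entirely.
* Zero neighbour distances (residual exact ties) are floored at
  ε = 1e−12 before the power, keeping the logarithm finite.
* Because 1/(1−α) = 100 multiplies the log, a single-sample entropy
  estimate at (n, d) = (1000, 5) carries ~0.03 nats of Monte-Carlo
  noise; identities such as "uniform sample ⇒ H ≈ 0" are therefore
  checked on rep-averaged estimates.

**Known limitation.** The estimator carries a positive finite-sample
bias that grows with dimension and dependence strength, driven by the
boundary behaviour of concentrated copula densities (mass near the
corners of [0,1]^d); it shrinks only like n^(−1/d). At n = 2000 the
closed-form Gaussian check −½ ln det R is met within ±0.10 nats for
all tested (d, ρ) combinations except d = 5, ρ = 0.8, where the bias
is ≈ +0.2 nats and persists (≈ +0.17 at n = 8000) under every
neighbour-set convention. Cross-condition comparisons at fixed (n, d)
— the package's main use — are unaffected because the bias largely
cancels.

## 6. Inference around RMI (`inference`)

*Expression-matched permutation test.* Genes are sorted by mean
expression (stable, ties by gene id) into bins of 500; each null trial
replaces every set gene with a random same-bin gene (distinct within a
trial) and recomputes RMI; p = fraction of trials ≥ observed, floored
at 1/trials. This conditions the null on expression level, the main
confounder of rank-based dependence in count data.

*ΔRMI.* ΔRMI = RMI_A − RMI_B for one gene set over the genes measured
in both populations. The null redraws d genes at random (unbinned by
default — an expression-binned variant is available) and recomputes Δ.
The reported p is the two-sided empirical p — twice the smaller tail,
floored at 1/trials — because a sign-directed single tail at nominal
level 0.05 has true size 0.10 by construction; the sign of ΔRMI
carries the direction. Swapping the populations negates ΔRMI exactly
and preserves p. BH correction across gene sets is applied by the
caller at FDR 10%.

*Entropy prefilter.* Before ΔRMI, each condition drops its
⌈5%⌉ lowest-entropy genes, entropy being the 1-D kNN Rényi estimate on
the gene's raw values across cells (the univariate copula would erase
all information; on raw values differential entropy grows with
expression spread, so constant and near-constant genes rank lowest).
A gene must survive in every condition.

*Bootstrap for large sets.* The estimator degrades when d approaches
n, so large target sets are summarised by the RMI distribution over
random subsets (default 10 distinct genes per trial, subsets drawn
with replacement across trials); conclusions should be stable across
subset sizes (checked at 8/10/12).

*Target definition.* Predicted targets = downregulated genes (adjusted
p < 0.1, negative fold change) supported by any prediction source;
high-confidence = supported by ≥ 2 sources, optionally intersected
with genes also downregulated in the wild-type-like comparison (the
endogenously-expressed-miRNA case).

## 7. Cell-cycle phase calls (`cellcycle`)

The classifier is a relative-expression pairs vote: training keeps
ordered gene pairs whose in-cell ordering holds in ≥ 0.5 + margin of a
phase's cells and ≤ 0.5 − margin of other cells (margin 0.2 by
default); prediction scores each phase by the fraction of its pairs
whose ordering holds in the cell and calls the argmax, with exact ties
"unassigned". Only within-cell orderings are used, so no normalization
is needed and the classifier can never emit a phase absent from
training. This is a simplified mechanism in the spirit of published
pair-based phase classifiers, trained here on labelled synthetic
cells; it does not reproduce any external tool's trained thresholds.
Phase-composition differences are two-sided Fisher exact tests per
phase (2×2: in-phase vs not, condition A vs B); the implementation is
checked against exhaustive hypergeometric enumeration. Phase-gene
structure is summarised by the mean within-phase off-diagonal
correlation (Pearson default, Spearman available — the two appear
interchangeably in the source material; both are implemented).

## 8. Pathway ranking by SVM-RFE (`pathway_ml`)

Cells are represented by per-pathway enrichment scores. Many small
training instances (default 5 cells per class) are subsampled; in each,
a linear SVM (C = 1 throughout, keeping instances comparable) is fitted
and the feature set is halved repeatedly by smallest squared weight —
with a handful of cells per class, leave-one-out accuracy cannot
resolve finer granularity than the resulting nested sets. The retained
set is the nested set maximizing leave-one-out accuracy (ties to the
smaller set); a pathway's relevance is its selection frequency across
instances. The original span-estimate stopping rule is replaced by
this leave-one-out criterion — a documented substitution. Relevance
tiers at 10/25/50/75% are evaluated by stratified cross-validated ROC
AUC of a linear SVM restricted to each tier.

## 9. Problem sizes used by the test suite and acceptance script

Desk-scale settings keep the default run on one CPU in minutes:
synthetic experiments of 300–600 genes and 48–120 cells per condition;
permutation tests at 200–500 trials (the full-scale analyses would use
10,000/1,000); type-I calibration over 200 null repetitions; RFE at
200 instances (down from 1,000); closed-form estimator checks at
n = 2000 over 10–20 seeds. These sizes are the package's chosen
defaults for its own verification; all are parameters that scale up
directly.

## 10. Design choices that were genuinely open

* Neighbour set S = {1..k}, directed edges: the source formulation
  leaves both unstated; all-of-first-k averages more edges and was
  retained after the alternatives ({k} only, {1}) showed no accuracy
  advantage.
* Natural-log base everywhere; γ absorbs the constant.
* The ΔRMI null is unbinned (the differential procedure, unlike the
  single-condition test, is described without bins); the binned
  variant is one flag away.
* Whether RMI is computed on normalized or log values is immaterial by
  rank invariance — asserted bit-exactly in the tests.
* The transfection-evidence ranking statistic, the per-cell tie rule,
  the clustering linkage and the silhouette acceptance threshold are
  package choices, each documented above next to its default.
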