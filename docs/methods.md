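# Methods

`pleionet` prioritizes genes with pleiotropic effects — loci that move two
or more traits at once — by chaining a multi-trait association statistic,
gene-level p-value combination, network construction from expression and
annotation data, graph embeddings, and a hierarchical mixture model that
fuses everything into a per-gene posterior probability of association
(PPA). This note records the models, their assumptions, the defaults that
matter, and the choices made where the design was genuinely open.

## Single-trait association and the multi-trait statistic

Each trait is scanned with the leave-one-chromosome-out (LOCO) mixed linear
model y = a + b·x + g + e, where x is the 0/1/2 allele dosage and g is a
polygenic effect with covariance proportional to a genomic relationship
matrix (GRM) built from all chromosomes except the tested marker's. The GRM
is the allele-frequency-standardized form
A = (1/m) Σ_i (x_i − 2p_i)(x_i − 2p_i)′ / (2p_i(1−p_i)).
Variance components are estimated once per (trait, left-out chromosome) by
REML — profiled over the heritability ratio on the GRM eigenbasis — and
then held fixed for a generalized-least-squares Wald test per marker
(the EMMAX-style approximation). This trades exact per-marker REML for a
scan whose cost is one eigendecomposition per chromosome; at the
heritabilities and sample sizes the package targets the approximation error
is negligible, and the null-calibration check in the acceptance suite
verifies the resulting test is exact-level to within binomial error.

Phenotype panels with covariates are pre-adjusted first: the null mixed
model (covariates + polygenic effect) is fitted by REML and the
fixed-effect residuals y − Xβ̂ carry forward. Breeding-value-like panels
skip adjustment and are tested directly.

The pleiotropy statistic per marker is χ² = t′V⁻¹t, where t stacks the
signed Wald t-values across traits and V is the Pearson correlation matrix
of the t columns computed over all QC-passing markers (a pruned-subset
option was considered and not needed at simulated LD levels; the choice is
configurable). The p-value uses a chi-square with one degree of freedom per
trait. V near singularity (condition number > 1e8, e.g. duplicated traits)
is an error by default, with an optional ridge V + εI.

Genotype QC removes markers with MAF < 0.01 or call rate < 0.95, both
boundaries strict (equality retains). Missing dosages surviving QC are
mean-imputed per marker for the GRM and the scan.

## Gene-level p-values

Markers map to every gene whose interval (optionally ± a window, default
0 bp) contains them. Each marker p is transformed to the chi-square-1 upper
quantile and summed within the gene: T_g = Σ_i Q_{χ²₁}(1 − p_i). Under the
null, T_g follows a weighted sum of chi-square-1 variables whose weights
are the eigenvalues of the gene's marker correlation (signed r, not r²)
matrix — signed, because the quadratic-form null concerns the correlation
of the underlying z statistics. The tail is evaluated with the Liu
moment-matching approximation: cumulants c₁..c₄ of the weighted sum are
matched to a noncentral chi-square (skewness-matched when s₁² > s₂,
kurtosis-corrected central match otherwise). Single-marker genes return the
marker p unchanged; marker p-values of exactly 0 are floored at 1e−300.
The test suite ships a million-draw Monte-Carlo oracle; agreement is within
0.005 at the checked points.

## Co-expression networks

Counts are FPKM-normalized (count·10⁹ / (length·library size)) when not
already FPKM; genes with mean FPKM < 0.2 are dropped (strict boundary; a
per-sample variant is exposed). Correlations are Pearson on log2(FPKM+1) —
the log transform is a package choice; correlation on raw FPKM is not
offered because heavy-tailed abundances dominate it. The signed adjacency
is a_ij = ((1 + r_ij)/2)^β, so strongly negatively correlated genes get
weight ≈ 0, and β is the smallest power in 1..20 whose connectivity
distribution is approximately scale-free (R² ≥ 0.8 of the log-log
frequency/connectivity regression over equal-width bins, requiring a
negative slope). When no power reaches the target the best-fitting power is
used; when the fit index is degenerate at every power (uniformly dense
input with no decaying-degree regime) the fallback is the signed-network
convention by sample size (18/16/14/12 for < 20/30/40/≥40 samples).

Modules come from average-linkage hierarchical clustering of 1 − TOM
(topological overlap), cut at a fixed fraction (default 0.95) of the
maximum merge height with a minimum module size of 30. This is a
simplification of the dynamic hybrid tree cut; on well-separated modular
data the two agree, and the subsequent refinement absorbs most of the
difference on messier data. Refinement is the k-means-style reallocation:
up to 20 rounds in which each gene moves to the module whose eigengene
(first principal component of the standardized module expression, sign
oriented along the module mean profile) it correlates with most, with
eigengenes recomputed after each round. Within a round, reassignment
against fixed eigengenes can only increase the summed gene–eigengene
correlation; the recorded objective trace asserts this during every run.
Genes falling in sub-threshold clusters start unassigned and are absorbed
in the first reallocation round.

## Enrichment and incidence networks

Gene-set enrichment is the one-sided hypergeometric upper tail P(X ≥ k)
with Benjamini–Hochberg control at 5% FDR. The background is the gene set
carried into the respective network (module enrichment uses all network
genes; prioritized-list enrichment uses all scored genes); this is a
configurable package choice. Gene symbols are matched case-insensitively;
genes without symbols cannot join symbol-keyed term networks and are
counted in the log. QTL annotation links a gene to every QTL interval
intersecting a 100-kb window upstream/downstream of the gene body (window
clamped at position 1); QTL-trait enrichment applies the same
hypergeometric machinery to per-trait annotated gene counts, genome-wide
(not chromosome-stratified — a simpler test than some annotation tools
use, noted as a divergence). Enriched terms/traits become binary gene ×
term incidence matrices; genes in no enriched term are excluded from the
matrix and recorded.

## Embeddings and diagnostics

Gene–gene adjacencies and gene–term incidences become undirected weighted
graphs (incidence rows/columns as a bipartite graph with unit edges).
Second-order biased random walks sample 10 walks of up to 80 nodes per
node; from state (prev u, current v) a neighbor x is drawn proportionally
to w(v,x)·α with α = 0.25 for stepping back to u, 1 for a neighbor of u,
and 1.0 otherwise — the config stores these two factors directly (the
return bias 1/p and in-out bias 1/q) to avoid inversion ambiguity. Walks
stop at dead ends; isolated nodes yield singleton walks.

Node vectors (32 dimensions) are trained by skip-gram with negative
sampling implemented in numpy: dynamic context windows (cap 32), 5
negatives from the unigram^(3/4) distribution, learning rate 0.025
decaying linearly to 1e−4, 20 epochs by default, single-threaded and
deterministic given the seed. Mini-batch updates normalize each row's
summed gradient by its repeat count within the batch, which keeps the
effective per-row step bounded on small vocabularies. Nodes absent from
every walk receive zero vectors with a warning.

Two diagnostics summarize where the most significant genes sit: the
weighted edge density of the top K genes, WED_K = Σ_{i<j≤K} w_ij /
(K(K−1)/2), for gene–gene networks, and the mean (exact, unweighted)
betweenness centrality of the top K genes for bipartite networks, where
term nodes are excluded from the mean. "Top" means ascending gene p-value
(most significant first). The K grid is 100..5000 step 100, capped at the
network size.

## Representative learning and the hierarchical model

The hierarchical model: each gene carries a latent Z_g ~
Bernoulli(σ(β₀ + β′x_g)); the gene-level p-value follows Beta(a, 1) with
a ∈ (0, 1] given Z = 1 and Uniform(0,1) given Z = 0. This
Beta-vs-uniform mixture with a logistic prior is the minimal model
consistent with a binary association indicator, soft labels and a PPA
output; both component choices are isolated behind the fitting functions.
EM alternates the posterior
PPA_g = π_g a p_g^{a−1} / (π_g a p_g^{a−1} + 1 − π_g)
with the weighted Beta-shape MLE a = ΣPPA / (−Σ PPA ln p) and a
Newton/IRLS logistic regression on the soft responses (with step-halving);
the observed-data log-likelihood is non-decreasing by construction and
asserted on every fixture. Convergence is relative tolerance 1e−6, at most
500 iterations. With no features the model nests the null mixture
π·Beta(a,1) + (1−π)·Uniform, which is also fitted first (π clamped to
[1e−6, 1−1e−6]) to provide the soft labels for representative learning.
When the fitted shape reaches a ≈ 1 the alternative is indistinguishable
from the null and π is unidentifiable; the fit is resolved toward the
no-signal reading (π at the lower clamp).

Features are one-dimensional reductions of each network's embedding by
soft-label linear discriminant analysis: class means and within/between
scatter are weighted by PPA and 1 − PPA, the projection direction is
(S_w + ridge)⁻¹(m₁ − m₀) (the leading eigenvector of S_w⁻¹S_b, since S_b
is rank one), ridge 1e−6·trace-scaled, sign oriented so the high-PPA class
maps higher. Per network, features are z-scored over the genes present;
genes absent from a network get the column mean (0) with an absence
indicator recorded. One column per network, concatenated.

Prioritization retains the top ⌈0.01·N⌉ genes by PPA (ties broken by
smaller gene p, then gene id — outputs are deterministic) and flags the
subset also significant at the gene level (nominal α = 0.05 by default;
BH option available). Overlap summaries between two candidate lists report
100·|A∩B| / |A∪B| rounded to one decimal.

## The synthetic-data generator

The generator produces the data classes the pipeline assumes, with ground
truth for recovery scoring. What it emulates — and what it does not:

* **Genotypes**: diploid dosages from two thresholded latent AR(1)
  Gaussian haplotypes per block (correlation 0.9 between adjacent markers,
  block size 20, MAF uniform in [0.05, 0.5]), giving Hardy–Weinberg
  genotypes and within-block r² decaying with distance. No demography,
  pedigree, imputation error or missingness by default (a missing-rate
  knob exists to exercise the call-rate filter).
* **Traits**: genetic values from 20 causal markers, half carrying effects
  on every trait (the pleiotropic truth set), half trait-specific; noise is
  multivariate normal with a configurable trait correlation, scaled per
  trait so realized h² hits the target (0.5 default). A breeding-value-like
  panel is the same construction with shrunken noise rather than a full
  animal-model fit.
* **Expression**: genes in a planted module share a latent sample factor
  giving pairwise latent correlation equal to `within_cor`; values are
  exponentiated to an FPKM-like scale. Real expression has correlated
  noise, batch structure and count overdispersion that this does not.
* **Annotation**: planted terms sample members with a probability
  multiplier (default 5×) for pleiotropic genes; QTL intervals are placed
  so half sit within 100 kb of a pleiotropic gene.

Because the generator plants clean, well-separated structure, passing
recovery tests demonstrates correctness of the machinery — not expected
performance on real data, where signals are weaker and confounded.

## Problem sizes and numerical choices

The default demonstration scale is 500 samples × 1000 markers × 3 traits
(3 chromosomes, ~200 genes), 30 expression samples, 20 terms and 20 QTLs;
the calibration run for the null statistic uses 2000 independent markers
and 5 traits. End-to-end runs at this scale use reduced embedding training
(window 8, 3 epochs) — sufficient for the scale of these networks, while
the per-parameter defaults remain the full values above. Degenerate inputs
are errors, not silent repairs: zero-variance genes or markers in
correlation matrices, empty graphs, all-zero eigenvalues, all-equal soft
labels, p-values outside (0, 1]. Eigenvalues of LD matrices that come out
slightly negative numerically are clipped to zero with a warning.

## Known limitations

* The fixed-height tree cut is cruder than the dynamic hybrid cut; very
  nested module structure may need the cut fraction adjusted.
* The skip-gram trainer is plain numpy; very large networks (tens of
  thousands of nodes) will be slow compared to compiled word2vec
  implementations.
* The hierarchical model assumes a monotone Beta(a,1) alternative; sharply
  bimodal p-value distributions are outside its family.
* The QTL enrichment test is genome-wide hypergeometric and ignores
  chromosome-level clustering of QTL intervals.
* REML here supports one genomic variance component plus residual; more
  complex covariance structures (permanent environment, repeated records)
  must be absorbed upstream or into covariates.
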