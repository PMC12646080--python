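# pleionet

Prioritizing genes with **pleiotropic effects** — loci that influence two or
more traits at once — from multi-trait GWAS, expression and annotation data.
The package is aimed at quantitative geneticists working with livestock or
other outbred populations who have per-trait association scans, a
transcriptome for a relevant tissue, and gene-set / QTL annotation tracks,
and who want a ranked, probabilistic candidate gene list rather than a
collection of per-trait Manhattan plots.

## What it computes

1. **Multi-trait pleiotropy statistic.** Each trait is scanned with a
   leave-one-chromosome-out mixed linear model (y = a + bx + g + e, g a
   polygenic effect from a genomic relationship matrix). Per marker, the
   signed Wald t-values across traits are combined as

   χ² = t′ V⁻¹ t,  df = number of traits,

   with V the correlation matrix of the t columns over all markers.
2. **Gene-level p-values.** Marker p-values map into genes and combine as
   T_g = Σ_i Q_{χ²₁}(1 − p_i), referred to the weighted-χ² null whose
   weights are the eigenvalues of the gene's LD matrix, via the Liu
   moment-matching tail approximation.
3. **Networks.** Signed weighted co-expression networks
   (a_ij = ((1+r)/2)^β) with topological-overlap module detection and
   k-means eigengene reallocation; gene×term incidence networks from
   hypergeometric GO/pathway and 100-kb-window QTL enrichment at 5% FDR.
4. **Embeddings.** node2vec-style biased random walks (return bias 0.25,
   in-out bias 1, 10 walks × length 80 per node) + skip-gram with negative
   sampling → 32-dimensional node vectors per network; WED_K and mean
   betweenness top-K diagnostic curves.
5. **Hierarchical model.** Per gene, a latent association indicator
   Z_g ~ Bernoulli(σ(β₀ + β′x_g)) with p_g | Z=1 ~ Beta(a,1) and
   p_g | Z=0 ~ Uniform(0,1), where x_g are one-dimensional soft-label LDA
   reductions of the network embeddings. EM yields the **posterior
   probability of association (PPA)** per gene; the top 1% by PPA, further
   filtered by gene-level significance, is the candidate list.

A first-class synthetic-data module generates LD-blocked genotypes,
correlated traits with planted pleiotropic loci, modular expression and
biased annotation tracks — with ground-truth labels — so every stage can be
tested for recovery.

## Worked example

`examples/` contains one short script per capability. Module detection on a
planted fixture (`python examples/03_coexpression_modules.py`) prints:

```
soft-threshold power beta = 9 (best scale-free fit 0.59)
detected modules and sizes: {1: 108, 2: 98, 3: 94}
adjusted Rand index against the 3 planted 50-gene modules: 1.000
ARI = 1 means the planted co-expression modules were recovered exactly;
the remaining genes are background noise.
```

Three modules of 50 co-expressed genes were planted among 150 noise genes;
the detected partition matches the planted one perfectly (ARI = 1), with
noise genes distributed across the modules by the reallocation step.

The full pipeline on a simulated study
(`python examples/05_full_pipeline.py`) finishes with:

```
genes scored: 201
top-1% by PPA: ['gene41', 'gene112', 'gene146']
also significant at gene level: ['gene41', 'gene112', 'gene146']
planted pleiotropic genes recovered: ['gene112', 'gene41'] of 10 planted
```

Two of the three candidates are genes that truly carry shared-effect causal
markers — roughly 13× what random selection of three genes from 201 would
recover.

## Command line

A thin CLI wraps the library:

```sh
pleionet simulate out/bundle --n-samples 500 --n-markers 1000 --seed 1
pleionet run --config pipeline.yaml --set seed=1 --set out_dir=out/results
```

`pleionet run` executes every stage and writes per-stage TSV/JSON
artifacts, a JSON-lines log, the resolved configuration and a checksum
manifest into the output directory.

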