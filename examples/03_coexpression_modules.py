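"""Detect co-expression modules in a planted-structure expression matrix.

Builds the signed weighted adjacency ((1 + r)/2)^beta at an automatically
chosen soft-threshold power, clusters the topological-overlap dissimilarity,
refines labels by k-means-style eigengene reallocation, and compares the
result with the planted module labels.
"""

from sklearn.metrics import adjusted_rand_score

from pleionet import coexpr, synthio
from pleionet.types import GeneModel

genes = [GeneModel(gene_id=f"g{i}", chrom="chr1", start=i * 1000 + 1,
                   end=i * 1000 + 500) for i in range(300)]
expr, truth = synthio.simulate_expression(
    genes, {1: 50, 2: 50, 3: 50}, n_samples=30, within_cor=0.9, seed=3
)

beta, fit_table = coexpr.pick_soft_threshold(expr)
print(f"soft-threshold power beta = {beta} "
      f"(best scale-free fit {fit_table['fit'].max():.2f})")

adj = coexpr.signed_adjacency(expr, beta)
tom = coexpr.compute_tom(adj)
modules, report = coexpr.detect_modules(adj, tom, expr, seed=3)

print(f"detected modules and sizes: {modules.labels.value_counts().to_dict()}")
planted = [g for g in modules.labels.index if g in truth.module_labels]
ari = adjusted_rand_score([truth.module_labels[g] for g in planted],
                          modules.labels.loc[planted])
print(f"adjusted Rand index against the 3 planted 50-gene modules: {ari:.3f}")
print("ARI = 1 means the planted co-expression modules were recovered "
      "exactly; the remaining genes are background noise.")
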