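"""Shared container types for the pleiotropy prioritization pipeline.

Conventions used throughout the package:

* genomic coordinates are 1-based inclusive internally; BED input/output is
  converted at the I/O boundary,
* genotype dosages count copies of the alternate allele (0/1/2), with NaN
  marking missing calls prior to QC,
* all matrices carry explicit row/column identifiers so stages can be
  re-aligned after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a user-supplied configuration value is invalid."""


class EmptyResultError(RuntimeError):
    """Raised when a filtering step removes every row it was given."""


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with marker metadata.

    ``dosages`` holds alternate-allele counts in {0, 1, 2} (float array; NaN =
    missing before QC).  ``markers`` is a DataFrame indexed by marker id with
    columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ConfigurationError("dosages must be 2-D (samples x markers)")
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ConfigurationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.markers.index.has_duplicates:
            raise ConfigurationError("marker ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        idx = self.markers.index.get_indexer(marker_ids)
        if (idx < 0).any():
            missing = [m for m, i in zip(marker_ids, idx) if i < 0]
            raise KeyError(f"markers not present: {missing[:5]}")
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            markers=self.markers.iloc[idx].copy(),
            samples=list(self.samples),
        )


@dataclass
class TraitPanel:
    """Samples x traits phenotype (or EBV-like) matrix plus fixed covariates."""

    traits: pd.DataFrame  # index = sample ids, columns = trait names
    covariates: pd.DataFrame | None = None  # same index; design columns

    def __post_init__(self) -> None:
        if self.covariates is not None and not self.covariates.index.equals(
            self.traits.index
        ):
            raise ConfigurationError("covariate rows must align with trait rows")

    @property
    def n_traits(self) -> int:
        return self.traits.shape[1]

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)


@dataclass
class MarkerStats:
    """Per-trait single-marker association results.

    Each field is a DataFrame indexed by marker id with one column per trait:
    ``beta`` (additive effect), ``se``, ``t`` (signed Wald t = beta/se), ``p``.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame


@dataclass
class PleioTable:
    """Per-marker multi-trait chi-square statistic and p-value.

    ``table`` is indexed by marker id with columns ``chi2``, ``df``, ``p`` and
    marker coordinates; ``V`` is the traits x traits correlation matrix of the
    signed t-values used to decorrelate the statistic.
    """

    table: pd.DataFrame
    V: pd.DataFrame


@dataclass(frozen=True)
class GeneModel:
    """A gene interval; ``start``/``end`` are 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    symbol: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class GeneScoreTable:
    """Gene-level combined p-values.

    ``table`` indexed by gene id: ``symbol``, ``chrom``, ``n_snps``, ``T``
    (sum of marker chi-square-1 quantiles), ``p``.  ``eigenvalues`` maps gene
    id -> LD-matrix eigenvalues used in the Liu tail approximation.
    """

    table: pd.DataFrame
    eigenvalues: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (raw counts or FPKM)."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    is_fpkm: bool = False
    gene_lengths: pd.Series | None = None  # bp, required to normalize counts

    def __post_init__(self) -> None:
        if (np.asarray(self.values) < 0).any():
            raise ConfigurationError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            raise ConfigurationError("gene ids must be unique")


@dataclass
class WeightedAdjacency:
    """Symmetric gene x gene co-expression adjacency with weights in [0, 1]."""

    weights: pd.DataFrame  # square, index == columns == gene ids
    beta: float = 1.0  # soft-threshold power used to build it

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape[0] != w.shape[1]:
            raise ConfigurationError("adjacency must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ConfigurationError("adjacency must be symmetric")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus module eigengenes (first PC per module)."""

    labels: pd.Series  # index = gene ids, values = int module labels
    eigengenes: pd.DataFrame  # index = sample ids, columns = module labels

    def modules(self) -> list[int]:
        return sorted(self.labels.unique())

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class TermSetCollection:
    """Gene-set annotation: term id -> set of (uppercased) gene symbols."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = "GO"

    def __post_init__(self) -> None:
        self.sets = {t: {g.upper() for g in gs} for t, gs in self.sets.items()}
        for term, members in self.sets.items():
            if not members:
                raise ConfigurationError(f"term {term} has no members")


@dataclass(frozen=True)
class QTLRecord:
    """A QTL interval labelled with trait name and class (1-based inclusive)."""

    trait: str
    trait_class: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(f"QTL {self.trait}: start > end")


@dataclass
class TermIncidence:
    """Binary gene x enriched-term incidence matrix.

    Genes with no enriched-term membership are excluded from the matrix and
    listed in ``unannotated``; ``qvalues`` maps term -> BH q-value.
    """

    matrix: pd.DataFrame  # index = gene ids, columns = term ids, values 0/1
    qvalues: pd.Series
    unannotated: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class WalkConfig:
    """Biased (node2vec-style) random-walk parameters.

    ``return_weight`` is the factor applied to stepping back to the previous
    node (the 1/p bias) and ``inout_weight`` to moving further from it (1/q).
    """

    n_walks: int = 10
    walk_length: int = 80
    return_weight: float = 0.25
    inout_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walks < 1 or self.walk_length < 1:
            raise ConfigurationError("walk counts/lengths must be >= 1")
        if self.return_weight <= 0 or self.inout_weight <= 0:
            raise ConfigurationError("walk bias weights must be > 0")


@dataclass
class EmbeddingSet:
    """Node embeddings for one network: node id -> fixed-length vector."""

    vectors: pd.DataFrame  # index = node ids, columns = 0..dims-1
    config: dict = field(default_factory=dict)

    @property
    def dims(self) -> int:
        return self.vectors.shape[1]


@dataclass
class TopKCurve:
    """Diagnostic curve: one value (WED or mean betweenness) per K."""

    K: np.ndarray
    values: np.ndarray
    ranking: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.K) < 0):
            raise ConfigurationError("K grid must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.K, "value": self.values, "network": self.label})


@dataclass
class FeatureMatrix:
    """Gene x network one-dimensional reduced-embedding features.

    Columns are standardized (mean 0, unit variance); genes absent from a
    network carry 0 in that column with the absence recorded in ``missing``.
    """

    features: pd.DataFrame
    missing: pd.DataFrame  # boolean, same shape: True where gene absent


@dataclass
class HierarchicalFit:
    """Result of the hierarchical EM mixture fit.

    The model: per-gene latent Z ~ Bernoulli(sigmoid(b0 + b'x)); gene p-value
    ~ Beta(a, 1) when Z=1 and Uniform(0,1) when Z=0.  ``ppa`` is the posterior
    P(Z=1 | p, x) per gene.
    """

    a: float
    b0: float
    b: np.ndarray
    ppa: pd.Series
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if not (0 < self.a <= 1):
            raise ConfigurationError("alternative Beta shape must be in (0, 1]")
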