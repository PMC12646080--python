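"""Signed weighted gene co-expression networks and module detection.

Expression counts are FPKM-normalized and low-expression genes dropped,
correlations are computed on log2(FPKM + 1), the signed adjacency
a_ij = ((1 + cor_ij) / 2) ** beta is soft-thresholded at a power chosen for
approximate scale-free topology, modules come from average-linkage
clustering of the topological-overlap dissimilarity with a fixed-height cut,
and a k-means-style reallocation refines the labels: each gene moves to the
module whose eigengene (first principal component) it correlates with most,
for a bounded number of rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import (
    ConfigurationError,
    EmptyResultError,
    ExpressionMatrix,
    ModuleAssignment,
    WeightedAdjacency,
)

log = logging.getLogger(__name__)


def fpkm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Fragments per kilobase per million: count * 1e9 / (length * libsize)."""
    if counts.gene_lengths is None:
        raise ConfigurationError("gene lengths are required for FPKM normalization")
    lengths = counts.gene_lengths.reindex(counts.values.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ConfigurationError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:5]
        raise ConfigurationError(f"non-positive gene lengths for {bad}")
    libsize = counts.values.sum(axis=0)
    if (libsize <= 0).any():
        raise ConfigurationError("library sizes must be positive")
    fpkm = counts.values * 1e9
    fpkm = fpkm.div(lengths, axis=0).div(libsize, axis=1)
    return ExpressionMatrix(values=fpkm, is_fpkm=True)


def filter_low_expression(
    expr: ExpressionMatrix, min_fpkm: float = 0.2, per_sample: bool = False
) -> tuple[ExpressionMatrix, int]:
    """Drop genes whose mean FPKM (default) falls below ``min_fpkm``.

    The boundary is strict: a gene at exactly ``min_fpkm`` is retained.
    With ``per_sample=True`` a gene is dropped if every sample is below the
    threshold.
    """
    if not expr.is_fpkm:
        raise ConfigurationError("filter expects FPKM-scale input")
    if per_sample:
        keep = (expr.values >= min_fpkm).any(axis=1)
    else:
        keep = expr.values.mean(axis=1) >= min_fpkm
    n_removed = int((~keep).sum())
    if not keep.any():
        raise EmptyResultError("low-expression filter removed every gene")
    return ExpressionMatrix(values=expr.values.loc[keep], is_fpkm=True), n_removed


def _log_expr(expr: ExpressionMatrix) -> np.ndarray:
    """log2(FPKM + 1), genes x samples."""
    return np.log2(expr.values.to_numpy(dtype=float) + 1.0)


def _correlation(expr: ExpressionMatrix) -> np.ndarray:
    X = _log_expr(expr)
    sd = X.std(axis=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        names = [expr.values.index[i] for i in zero[:5]]
        raise ConfigurationError(f"zero-variance gene(s): {names}")
    return np.corrcoef(X)


def signed_adjacency(expr: ExpressionMatrix, beta: float) -> WeightedAdjacency:
    """Signed soft-threshold adjacency a_ij = ((1 + cor_ij)/2) ** beta."""
    if beta < 1:
        raise ConfigurationError("soft-threshold power must be >= 1")
    cor = _correlation(expr)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return WeightedAdjacency(
        weights=pd.DataFrame(
            adj, index=expr.values.index, columns=expr.values.index
        ),
        beta=float(beta),
    )


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: range | list[int] = range(1, 21),
    target_fit: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest power with scale-free topology fit R^2 >= ``target_fit``.

    The fit regresses log10 frequency on log10 mean connectivity over
    equal-occupancy bins of the connectivity distribution; a positive slope
    scores 0 (scale-free degree distributions decay).  If no power reaches
    the target, the power maximizing R^2 is returned with a warning.
    """
    if expr.values.shape[0] < 20:
        raise ConfigurationError("need at least 20 genes to assess topology")
    cor = _correlation(expr)
    half = (1.0 + cor) / 2.0
    np.fill_diagonal(half, 0.0)
    records = []
    for power in powers:
        k = (half**power).sum(axis=1)
        records.append({"power": int(power), "fit": _scale_free_fit(k, n_bins)})
    table = pd.DataFrame(records)
    ok = table[table["fit"] >= target_fit]
    if len(ok):
        best = int(ok.iloc[0]["power"])
    elif table["fit"].max() > 0:
        best = int(table.loc[table["fit"].idxmax(), "power"])
        log.warning(
            "no power reached scale-free fit %.2f; using power %d (fit %.3f)",
            target_fit, best, table["fit"].max(),
        )
    else:
        # no power shows any decaying degree regime (e.g. uniformly dense
        # input); fall back to the signed-network convention by sample size
        n = expr.values.shape[1]
        best = 18 if n < 20 else 16 if n < 30 else 14 if n < 40 else 12
        best = int(min(best, max(powers)))
        log.warning(
            "scale-free fit degenerate at every power; falling back to the "
            "sample-size convention power %d", best,
        )
    return best, table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    log_k, log_p = [], []
    n = k.size
    for b in range(len(edges) - 1):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / n))
    if len(log_k) < 3:
        return 0.0
    slope, intercept = np.polyfit(log_k, log_p, 1)
    pred = slope * np.asarray(log_k) + intercept
    ss_res = float(((np.asarray(log_p) - pred) ** 2).sum())
    ss_tot = float(((np.asarray(log_p) - np.mean(log_p)) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    r2 = 1 - ss_res / ss_tot
    return float(max(r2, 0.0)) if slope < 0 else 0.0


def compute_tom(adj: WeightedAdjacency) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    A = adj.weights.to_numpy(dtype=float)
    if A.min() < 0 or A.max() > 1:
        raise ConfigurationError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.weights.index, columns=adj.weights.columns)


@dataclass
class ModuleDetectionReport:
    n_initial_modules: int
    rounds: int
    objective_trace: list[tuple[float, float]] = field(default_factory=list)
    # (objective before reassignment, after reassignment) per round,
    # both evaluated with that round's eigengenes held fixed


def detect_modules(
    adj: WeightedAdjacency,
    tom: pd.DataFrame,
    expr: ExpressionMatrix,
    min_module_size: int = 30,
    kmeans_iters: int = 20,
    cut_height_frac: float = 0.95,
    seed: int = 0,
) -> tuple[ModuleAssignment, ModuleDetectionReport]:
    """Hierarchical module detection with k-means eigengene reallocation.

    Average-linkage clustering of 1 - TOM is cut at ``cut_height_frac`` of
    the maximum merge height; clusters below ``min_module_size`` are
    dissolved and their genes (re)assigned during the reallocation rounds,
    in which every gene moves to the module whose eigengene it correlates
    with most and eigengenes are then recomputed.  Labels are integers
    1..n_modules; deterministic given the inputs.
    """
    gene_ids = list(adj.weights.index)
    if list(tom.index) != gene_ids or list(expr.values.index) != gene_ids:
        raise ConfigurationError("adjacency, TOM and expression must share gene order")
    n = len(gene_ids)
    X = _log_expr(expr)
    Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)

    if n < min_module_size:
        log.warning("fewer genes than min_module_size: one catch-all module")
        labels = pd.Series(1, index=pd.Index(gene_ids, name="gene"))
        eig = _eigengenes(Xz, labels, expr.values.columns)
        return (
            ModuleAssignment(labels=labels, eigengenes=eig),
            ModuleDetectionReport(n_initial_modules=1, rounds=0),
        )

    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = cut_height_frac * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")

    # keep clusters that meet the size floor as seed modules
    labels = np.zeros(n, dtype=int)
    next_label = 1
    for cluster in np.unique(raw):
        members = raw == cluster
        if members.sum() >= min_module_size:
            labels[members] = next_label
            next_label += 1
    if next_label == 1:
        log.warning("no cluster reached min_module_size: one catch-all module")
        labels[:] = 1
        next_label = 2
    n_initial = next_label - 1

    series = pd.Series(labels, index=pd.Index(gene_ids, name="gene"))
    report = ModuleDetectionReport(n_initial_modules=n_initial, rounds=0)

    # k-means-style reallocation on eigengene correlation
    for round_ in range(kmeans_iters):
        eig = _eigengenes(Xz, series, expr.values.columns, skip_zero=True)
        if eig.shape[1] == 0:
            break
        E = eig.to_numpy()  # samples x modules, already standardized columns
        cors = (Xz @ E) / Xz.shape[1]  # genes x modules: Pearson r
        before = _objective(cors, series, list(eig.columns))
        new_labels = np.asarray(eig.columns)[np.argmax(cors, axis=1)]
        after = float(np.max(cors, axis=1).sum())
        report.objective_trace.append((before, after))
        new_series = pd.Series(new_labels, index=series.index)
        report.rounds = round_ + 1
        if new_series.equals(series):
            series = new_series
            break
        series = new_series

    # relabel contiguously by module size (largest = 1); 0 stays unassigned
    sizes = series[series != 0].value_counts()
    relabel = {old: i + 1 for i, old in enumerate(sizes.index)}
    relabel[0] = 0
    series = series.map(relabel)
    eig = _eigengenes(Xz, series, expr.values.columns)
    return ModuleAssignment(labels=series, eigengenes=eig), report


def _objective(
    cors: np.ndarray, labels: pd.Series, module_order: list[int]
) -> float:
    """Sum over genes of cor(gene, eigengene of its current module)."""
    col = {m: j for j, m in enumerate(module_order)}
    total = 0.0
    lab = labels.to_numpy()
    for i, m in enumerate(lab):
        j = col.get(m)
        if j is not None:
            total += cors[i, j]
    return float(total)


def _eigengenes(
    Xz: np.ndarray,
    labels: pd.Series,
    sample_ids,
    skip_zero: bool = False,
) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    The sign is oriented so the eigengene correlates positively with the
    module's mean profile; the returned columns are z-scored across samples.
    """
    cols = {}
    for module in sorted(labels.unique()):
        if skip_zero and module == 0:
            continue
        members = labels.to_numpy() == module
        if members.sum() == 0:
            continue
        M = Xz[members]  # genes x samples
        # first right-singular vector = leading PC over samples
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        pc = vt[0]
        mean_profile = M.mean(axis=0)
        if np.dot(pc, mean_profile) < 0:
            pc = -pc
        sd = pc.std()
        cols[module] = (pc - pc.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(cols, index=sample_ids)


def adjacency_edge_list(
    adj: WeightedAdjacency, min_weight: float = 0.0
) -> pd.DataFrame:
    """Upper-triangle edge list (gene_i, gene_j, weight >= min_weight)."""
    A = adj.weights.to_numpy()
    ids = np.asarray(adj.weights.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    w = A[iu, ju]
    keep = w >= min_weight
    return pd.DataFrame(
        {"gene_i": ids[iu[keep]], "gene_j": ids[ju[keep]], "weight": w[keep]}
    )
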