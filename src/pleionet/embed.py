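"""Graph embeddings and top-K network diagnostics.

Weighted gene-gene adjacencies and gene-term incidence matrices become
undirected walk graphs; second-order biased random walks (node2vec style:
a return bias 1/p on stepping back and an in-out bias 1/q on moving further
from the previous node) sample node sentences, and a skip-gram model with
negative sampling trains fixed-dimension node vectors from them.

Two diagnostics summarize how the most significant genes sit in a network:
the weighted edge density of the top K genes,
WED_K = sum_{i<j<=K} w_ij / (K (K-1) / 2), and the mean betweenness
centrality of the top K genes, both on a K grid of 100..5000 step 100
(capped at the network size).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    EmbeddingSet,
    TermIncidence,
    TopKCurve,
    WalkConfig,
    WeightedAdjacency,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- graphs


def build_walk_graph(
    source: WeightedAdjacency | TermIncidence | pd.DataFrame,
    bipartite_weight: float = 1.0,
) -> nx.Graph:
    """Build the undirected weighted graph walked for embedding.

    A gene-gene adjacency keeps its weights (diagonal ignored, zero-weight
    edges dropped, isolated nodes retained); a gene x term incidence expands
    to a bipartite graph with unit-weight gene-term edges.
    """
    G = nx.Graph()
    if isinstance(source, TermIncidence):
        inc = source.matrix
        G.add_nodes_from(inc.index)
        G.add_nodes_from(inc.columns)
        rows, cols = np.nonzero(inc.to_numpy())
        for r, c in zip(rows, cols):
            G.add_edge(inc.index[r], inc.columns[c], weight=bipartite_weight)
    else:
        W = source.weights if isinstance(source, WeightedAdjacency) else source
        ids = list(W.index)
        G.add_nodes_from(ids)
        A = W.to_numpy(dtype=float)
        iu, ju = np.triu_indices(len(ids), k=1)
        w = A[iu, ju]
        keep = w > 0
        G.add_weighted_edges_from(
            (ids[i], ids[j], float(wv))
            for i, j, wv in zip(iu[keep], ju[keep], w[keep])
        )
    if G.number_of_nodes() == 0:
        raise ConfigurationError("empty graph")
    return G


# ---------------------------------------------------------------- walks


def biased_random_walks(G: nx.Graph, cfg: WalkConfig) -> list[list]:
    """Second-order biased random walks over a weighted graph.

    From state (previous u, current v) a neighbor x is drawn with
    unnormalized weight w(v, x) * alpha, where alpha = ``return_weight`` if
    x == u, 1 if x neighbors u, and ``inout_weight`` otherwise.  Each node
    starts ``n_walks`` walks of at most ``walk_length`` nodes; walks stop at
    dead ends.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    nodes = list(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    nbrs: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    nbr_sets: list[set[int]] = []
    for v in nodes:
        ns = [index[x] for x in G.neighbors(v)]
        ws = np.array([G[v][x].get("weight", 1.0) for x in G.neighbors(v)])
        nbrs.append(np.array(ns, dtype=int))
        wts.append(ws)
        nbr_sets.append(set(ns))

    walks: list[list] = []
    for start in range(len(nodes)):
        for _ in range(cfg.n_walks):
            walk = [start]
            if nbrs[start].size == 0:
                walks.append([nodes[start]])
                continue
            # first step: plain weighted choice
            w0 = wts[start]
            cur = int(nbrs[start][_weighted_pick(rng, w0)])
            walk.append(cur)
            while len(walk) < cfg.walk_length:
                prev = walk[-2]
                cand = nbrs[cur]
                if cand.size == 0:
                    break
                alpha = np.where(
                    cand == prev,
                    cfg.return_weight,
                    np.where(
                        [c in nbr_sets[prev] for c in cand],
                        1.0,
                        cfg.inout_weight,
                    ),
                )
                cur = int(cand[_weighted_pick(rng, wts[cur] * alpha)])
                walk.append(cur)
            walks.append([nodes[i] for i in walk])
    return walks


def _weighted_pick(rng: np.random.Generator, weights: np.ndarray) -> int:
    cum = np.cumsum(weights)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def walk_transition_probs(
    G: nx.Graph, prev, cur, cfg: WalkConfig
) -> dict:
    """Analytic next-step distribution from state (prev, cur); test oracle aid."""
    out = {}
    prev_nbrs = set(G.neighbors(prev))
    for x in G.neighbors(cur):
        w = G[cur][x].get("weight", 1.0)
        if x == prev:
            out[x] = w * cfg.return_weight
        elif x in prev_nbrs:
            out[x] = w
        else:
            out[x] = w * cfg.inout_weight
    total = sum(out.values())
    return {x: v / total for x, v in out.items()}


# ---------------------------------------------------------------- skip-gram


def skipgram_embed(
    walks: list[list],
    nodes: list | None = None,
    dims: int = 32,
    window: int = 32,
    epochs: int = 20,
    negative: int = 5,
    lr: float = 0.025,
    lr_min: float = 1e-4,
    batch_size: int = 4096,
    seed: int = 0,
) -> EmbeddingSet:
    """Train skip-gram-with-negative-sampling node vectors from walks.

    Context windows are dynamically shrunk per position (the standard
    word2vec scheme), negatives are drawn from the unigram distribution
    raised to 3/4, and the learning rate decays linearly over all updates.
    Nodes absent from every walk receive a zero vector with a warning.
    """
    rng = np.random.default_rng(seed)
    vocab = list(dict.fromkeys(n for w in walks for n in w))
    if nodes is not None:
        missing = [n for n in nodes if n not in set(vocab)]
        if missing:
            log.warning("%d nodes absent from all walks get zero vectors", len(missing))
    index = {v: i for i, v in enumerate(vocab)}
    V = len(vocab)
    sents = [np.array([index[n] for n in w], dtype=np.int64) for w in walks if len(w) > 1]

    counts = np.bincount(
        np.concatenate(sents) if sents else np.array([], dtype=np.int64),
        minlength=V,
    ).astype(float)
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum()) if noise.sum() > 0 else None

    W = (rng.random((V, dims)) - 0.5) / dims  # input vectors
    C = np.zeros((V, dims))  # output (context) vectors

    # group equal-length sentences so pair generation vectorizes
    by_len: dict[int, list[np.ndarray]] = {}
    for s in sents:
        by_len.setdefault(len(s), []).append(s)
    groups = [np.vstack(v) for v in by_len.values()]

    n_pairs_estimate = None
    seen_batches = 0
    for epoch in range(epochs):
        centers_l, ctx_l = [], []
        for S in groups:
            L = S.shape[1]
            b = rng.integers(1, window + 1, size=S.shape)
            for d in range(1, min(window, L - 1) + 1):
                m = b[:, :-d] >= d
                centers_l.append(S[:, :-d][m]); ctx_l.append(S[:, d:][m])
                m = b[:, d:] >= d
                centers_l.append(S[:, d:][m]); ctx_l.append(S[:, :-d][m])
        if not centers_l:
            break
        centers = np.concatenate(centers_l)
        ctx = np.concatenate(ctx_l)
        perm = rng.permutation(len(centers))
        centers, ctx = centers[perm], ctx[perm]
        if n_pairs_estimate is None:
            n_pairs_estimate = len(centers)
        total_batches = max(1, (n_pairs_estimate // batch_size + 1) * epochs)
        for lo in range(0, len(centers), batch_size):
            cur_lr = max(lr_min, lr * (1 - seen_batches / total_batches))
            _sgns_batch(
                W, C,
                centers[lo : lo + batch_size],
                ctx[lo : lo + batch_size],
                noise_cdf, negative, cur_lr, rng,
            )
            seen_batches += 1

    vectors = pd.DataFrame(W, index=pd.Index(vocab, name="node"))
    if nodes is not None:
        vectors = vectors.reindex(nodes, fill_value=0.0)
    return EmbeddingSet(
        vectors=vectors,
        config={
            "dims": dims, "window": window, "epochs": epochs,
            "negative": negative, "lr": lr, "seed": seed,
        },
    )


def _sgns_batch(W, C, centers, ctx, noise_cdf, negative, lr, rng) -> None:
    """One mini-batch SGNS step.

    Rows repeated within a batch have their summed gradient divided by the
    repeat count, so the per-row step size stays bounded regardless of how
    small the vocabulary is relative to the batch.
    """
    B, d = len(centers), W.shape[1]
    if B == 0:
        return
    neg = np.searchsorted(
        noise_cdf, rng.random((B, negative)), side="right"
    ).clip(max=len(noise_cdf) - 1)
    Wc = W[centers]
    Cp = C[ctx]
    Cn = C[neg]
    gp = lr * (1.0 - _sigmoid(np.einsum("bd,bd->b", Wc, Cp)))
    gn = -lr * _sigmoid(np.einsum("bd,bkd->bk", Wc, Cn))
    dW = gp[:, None] * Cp + np.einsum("bk,bkd->bd", gn, Cn)

    V = W.shape[0]
    cnt_w = np.bincount(centers, minlength=V).astype(float)
    scale_w = 1.0 / np.maximum(cnt_w[centers], 1.0)
    c_idx = np.concatenate([ctx, neg.ravel()])
    cnt_c = np.bincount(c_idx, minlength=V).astype(float)
    dC = np.concatenate(
        [gp[:, None] * Wc, (gn[..., None] * Wc[:, None, :]).reshape(-1, d)]
    )
    scale_c = 1.0 / np.maximum(cnt_c[c_idx], 1.0)
    np.add.at(C, c_idx, scale_c[:, None] * dC)
    np.add.at(W, centers, scale_w[:, None] * dW)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------- diagnostics


def default_k_grid(n_genes: int, k_max: int = 5000, step: int = 100) -> np.ndarray:
    """The 100..5000 step-100 K grid, capped at the available gene count."""
    grid = np.arange(step, k_max + 1, step)
    grid = grid[grid <= n_genes]
    if grid.size == 0:
        grid = np.array([n_genes])
    return grid


def wed_topk(
    adj: WeightedAdjacency,
    ranking: list[str],
    k_grid: np.ndarray | list[int] | None = None,
) -> TopKCurve:
    """Weighted edge density among the top-K ranked genes for each K.

    ``ranking`` lists genes most-significant first (ascending p).  For each
    K the value is the mean pairwise adjacency weight among the first K
    ranked genes, i.e. sum_{i<j<=K} w_ij / (K (K-1) / 2).
    """
    ranked = [g for g in ranking if g in adj.weights.index]
    if len(ranked) < 2:
        raise ConfigurationError("need at least 2 ranked genes in the adjacency")
    if k_grid is None:
        k_grid = default_k_grid(len(ranked))
    k_grid = np.asarray(k_grid, dtype=int)
    if k_grid.size == 0:
        raise ConfigurationError("K grid is empty")
    k_grid = np.minimum(k_grid, len(ranked))
    k_grid = k_grid[k_grid >= 2]
    if k_grid.size == 0:
        raise ConfigurationError("K grid has no entry >= 2")

    idx = adj.weights.index.get_indexer(ranked)
    A = adj.weights.to_numpy()[np.ix_(idx, idx)]
    # cumulative sum of pairwise weights as genes enter in rank order
    k_max = int(k_grid.max())
    cum = np.zeros(k_max + 1)
    for k in range(2, k_max + 1):
        cum[k] = cum[k - 1] + A[k - 1, : k - 1].sum()
    values = np.array([cum[k] / (k * (k - 1) / 2) for k in k_grid])
    return TopKCurve(K=k_grid, values=values, ranking=ranked, label="WED")


def betweenness(G: nx.Graph) -> pd.Series:
    """Exact unweighted betweenness; undirected pairs counted once.

    B(v) = sum over ordered-once pairs s != v != t of the fraction of
    shortest s-t paths passing through v; disconnected pairs contribute 0.
    """
    scores = nx.betweenness_centrality(G, normalized=False, weight=None)
    return pd.Series(scores)


def mean_betweenness_topk(
    scores: pd.Series,
    ranking: list[str],
    k_grid: np.ndarray | list[int] | None = None,
) -> TopKCurve:
    """Mean betweenness of the top-K ranked genes for each K.

    Nodes in ``scores`` but not in ``ranking`` (e.g. term nodes of a
    bipartite network) never enter the mean.
    """
    ranked = [g for g in ranking if g in scores.index]
    if not ranked:
        raise ConfigurationError("no ranked gene has a betweenness score")
    if k_grid is None:
        k_grid = default_k_grid(len(ranked))
    k_grid = np.asarray(k_grid, dtype=int)
    if k_grid.size == 0:
        raise ConfigurationError("K grid is empty")
    k_grid = np.minimum(k_grid, len(ranked))
    vals = scores.loc[ranked].to_numpy(dtype=float)
    cum = np.cumsum(vals)
    values = np.array([cum[k - 1] / k for k in k_grid])
    return TopKCurve(K=k_grid, values=values, ranking=ranked, label="betweenness")
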