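"""Representative learning and the hierarchical mixture model for gene PPA.

The model: each gene g carries a binary latent association indicator
Z_g ~ Bernoulli(pi_g) with pi_g = sigmoid(b0 + b' x_g), where x_g collects
one-dimensional network features (soft-label LDA reductions of the node
embeddings).  Conditional on Z, the gene-level p-value follows Beta(a, 1)
with a in (0, 1] (spiked near zero) when Z = 1, and Uniform(0, 1) when
Z = 0.  The posterior probability of association (PPA) is
P(Z_g = 1 | p_g, x_g), estimated by EM:

* E-step: PPA_g = pi_g a p_g^(a-1) / (pi_g a p_g^(a-1) + 1 - pi_g)
* M-step: a = sum(PPA) / (-sum(PPA * log p)) (weighted Beta(a, 1) MLE);
  (b0, b) by logistic regression on the soft responses PPA.

The null model (no features, constant prior) is fitted first; its
posteriors are the soft labels driving the LDA reductions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    EmbeddingSet,
    FeatureMatrix,
    GeneScoreTable,
    HierarchicalFit,
)

log = logging.getLogger(__name__)

P_FLOOR = 1e-300
A_MIN = 1e-4


# ---------------------------------------------------------------- null mixture


@dataclass
class NullMixtureFit:
    pi: float
    a: float
    ppa: pd.Series
    loglik_trace: np.ndarray
    n_iter: int


def _beta_a_mle(weights: np.ndarray, log_p: np.ndarray) -> float:
    """Weighted MLE of the Beta(a, 1) shape: a = sum(w) / (-sum(w log p))."""
    denom = -float(weights @ log_p)
    if denom <= 0:
        return 1.0
    return float(np.clip(weights.sum() / denom, A_MIN, 1.0))


def fit_null_mixture(
    pvalues: pd.Series | np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> NullMixtureFit:
    """EM fit of the two-component mixture pi Beta(a,1) + (1 - pi) U(0,1).

    Returns the mixing weight, the alternative shape and the per-gene
    posterior (the soft labels for downstream representative learning).
    ``pi`` is clamped to [1e-6, 1 - 1e-6].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 50:
        raise ConfigurationError("need at least 50 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    log_p = np.log(np.maximum(p, P_FLOOR))

    pi, a = 0.1, 0.5
    trace = []
    for it in range(max_iter):
        alt = a * np.power(p, a - 1.0)
        denom = pi * alt + (1 - pi)
        w = pi * alt / denom
        ll = float(np.log(denom).sum())
        trace.append(ll)
        pi_new = float(np.clip(w.mean(), 1e-6, 1 - 1e-6))
        a_new = _beta_a_mle(w, log_p)
        if it > 0 and abs(trace[-1] - trace[-2]) <= tol * (1 + abs(trace[-2])):
            pi, a = pi_new, a_new
            break
        pi, a = pi_new, a_new
    else:
        raise RuntimeError(
            f"null mixture EM did not converge in {max_iter} iterations "
            f"(last log-likelihoods: {trace[-3:]})"
        )
    if a >= 0.999:
        # Beta(a, 1) with a ~ 1 is indistinguishable from the uniform null,
        # leaving pi unidentifiable; resolve toward the no-signal reading
        pi = 1e-6
    alt = a * np.power(p, a - 1.0)
    ppa = pi * alt / (pi * alt + (1 - pi))
    index = pvalues.index if isinstance(pvalues, pd.Series) else pd.RangeIndex(p.size)
    return NullMixtureFit(
        pi=pi, a=a,
        ppa=pd.Series(ppa, index=index),
        loglik_trace=np.asarray(trace),
        n_iter=len(trace),
    )


# ---------------------------------------------------------------- LDA reduction


def lda_reduce(
    embedding: EmbeddingSet | pd.DataFrame,
    soft_labels: pd.Series,
    ridge: float = 1e-6,
) -> pd.Series:
    """Soft-label linear discriminant reduction of an embedding to one dim.

    Class means and within/between scatter matrices are computed with the
    posterior weights (PPA for class 1, 1 - PPA for class 0); the feature is
    the projection on the leading eigenvector of within^-1 between (the
    within-scatter inverse ridge-regularized), with sign oriented so the
    high-PPA class mean maps higher.
    """
    X = embedding.vectors if isinstance(embedding, EmbeddingSet) else embedding
    w1 = soft_labels.reindex(X.index).to_numpy(dtype=float)
    if np.isnan(w1).any():
        raise ConfigurationError("soft labels missing for some embedded nodes")
    if np.allclose(w1, w1[0]):
        raise ConfigurationError("all soft labels equal: classes are undefined")
    w0 = 1.0 - w1
    A = X.to_numpy(dtype=float)
    m1 = (w1 @ A) / w1.sum()
    m0 = (w0 @ A) / w0.sum()
    diff = m1 - m0
    if np.allclose(diff, 0):
        raise ConfigurationError("identical class means: between-scatter is zero")
    D1 = A - m1
    D0 = A - m0
    Sw = (D1 * w1[:, None]).T @ D1 + (D0 * w0[:, None]).T @ D0
    scale = np.trace(Sw) / Sw.shape[0]
    if scale <= 0:
        scale = 1.0
        log.warning("degenerate within-scatter; ridge dominates")
    Sw_reg = Sw + ridge * scale * np.eye(Sw.shape[0])
    # between-scatter is rank one, so the leading eigenvector of
    # Sw^-1 Sb is Sw^-1 (m1 - m0) up to scale
    v = np.linalg.solve(Sw_reg, diff)
    v = v / np.linalg.norm(v)
    feature = A @ v
    if float(w1 @ feature) / w1.sum() < float(w0 @ feature) / w0.sum():
        feature = -feature
    return pd.Series(feature, index=X.index)


def assemble_features(
    reductions: dict[str, pd.Series],
    gene_universe: list[str],
    policy: str = "zero-fill",
) -> FeatureMatrix:
    """Stack per-network reductions into a standardized gene x network matrix.

    Each column is z-scored over the genes present in that network; genes
    absent from a network receive 0 (the column mean) and are flagged in the
    ``missing`` indicator.
    """
    if not reductions:
        raise ConfigurationError("need at least one network reduction")
    if not gene_universe:
        raise ConfigurationError("gene universe is empty")
    if policy != "zero-fill":
        raise ConfigurationError(f"unknown missing-feature policy {policy!r}")
    cols = {}
    miss = {}
    for name, series in reductions.items():
        aligned = series.reindex(gene_universe)
        missing = aligned.isna()
        present = aligned[~missing]
        sd = present.std(ddof=0)
        z = (present - present.mean()) / (sd if sd > 0 else 1.0)
        aligned.loc[~missing] = z
        aligned = aligned.fillna(0.0)
        cols[name] = aligned
        miss[name] = missing
    return FeatureMatrix(
        features=pd.DataFrame(cols), missing=pd.DataFrame(miss)
    )


# ---------------------------------------------------------------- hierarchical EM


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logistic_m_step(
    X: np.ndarray, soft: np.ndarray, coef: np.ndarray, max_iter: int = 50
) -> np.ndarray:
    """Newton/IRLS for logistic regression on soft responses, with
    step-halving on the Bernoulli log-likelihood."""

    def ll(c: np.ndarray) -> float:
        eta = X @ c
        return float(soft @ eta - np.logaddexp(0.0, eta).sum())

    cur = coef.copy()
    cur_ll = ll(cur)
    for _ in range(max_iter):
        mu = _sigmoid(X @ cur)
        grad = X.T @ (soft - mu)
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Hessian in logistic M-step") from exc
        scale = 1.0
        for _ in range(30):
            cand = cur + scale * step
            cand_ll = ll(cand)
            if cand_ll >= cur_ll - 1e-12:
                break
            scale /= 2
        else:
            raise RuntimeError("logistic M-step diverged despite step-halving")
        if cand_ll - cur_ll < 1e-10 * (1 + abs(cur_ll)):
            return cand
        cur, cur_ll = cand, cand_ll
    return cur


def em_hierarchical(
    pvalues: pd.Series,
    features: FeatureMatrix | None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HierarchicalFit:
    """Fit the hierarchical Beta/Uniform mixture with a logistic prior by EM.

    With ``features=None`` (or an all-zero matrix) the prior collapses to a
    constant and the fit reproduces :func:`fit_null_mixture`.  The
    log-likelihood is guaranteed non-decreasing across iterations.
    """
    p = pvalues.to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    log_p = np.log(np.maximum(p, P_FLOOR))
    n = p.size
    if features is not None:
        F = features.features.reindex(pvalues.index)
        if F.isna().to_numpy().any():
            raise ConfigurationError("features missing for some scored genes")
        Xf = F.to_numpy(dtype=float)
    else:
        Xf = np.zeros((n, 0))
    X = np.hstack([np.ones((n, 1)), Xf])

    # warm start from the unconditional mixture
    null = fit_null_mixture(pvalues)
    a = null.a
    coef = np.zeros(X.shape[1])
    coef[0] = math.log(null.pi / (1 - null.pi))

    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        pi_g = np.clip(_sigmoid(X @ coef), 1e-12, 1 - 1e-12)
        alt = a * np.power(p, a - 1.0)
        denom = pi_g * alt + (1 - pi_g)
        ll = float(np.log(denom).sum())
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) <= tol * (1 + abs(trace[-2])):
            converged = True
            break
        ppa = pi_g * alt / denom
        a = _beta_a_mle(ppa, log_p)
        coef = _logistic_m_step(X, ppa, coef)
    pi_g = np.clip(_sigmoid(X @ coef), 1e-12, 1 - 1e-12)
    alt = a * np.power(p, a - 1.0)
    ppa = pi_g * alt / (pi_g * alt + (1 - pi_g))
    return HierarchicalFit(
        a=a,
        b0=float(coef[0]),
        b=coef[1:].copy(),
        ppa=pd.Series(ppa, index=pvalues.index),
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
    )


# ---------------------------------------------------------------- selection


def prioritize(
    fit: HierarchicalFit,
    scores: GeneScoreTable,
    top_frac: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Retain the top fraction of genes by PPA and flag gene-level significance.

    The top ceil(top_frac * N) genes by descending PPA are selected, ties
    broken by smaller gene p then lexicographic gene id; ``significant``
    additionally requires gene p <= alpha.  Returns the full table sorted by
    rank with ``prioritized`` and ``significant`` flags.
    """
    genes = fit.ppa.index
    if len(genes) == 0:
        raise ConfigurationError("no genes to prioritize")
    gene_p = scores.table["p"].reindex(genes)
    if gene_p.isna().any():
        raise ConfigurationError("gene scores missing for some fitted genes")
    table = pd.DataFrame(
        {"ppa": fit.ppa, "p": gene_p}, index=genes
    )
    table = table.sort_values(
        by=["ppa", "p"],
        ascending=[False, True],
        kind="stable",
    )
    # final deterministic tie-break on gene id
    table["_id"] = table.index
    table = table.sort_values(
        by=["ppa", "p", "_id"], ascending=[False, True, True], kind="stable"
    ).drop(columns="_id")
    n_top = math.ceil(top_frac * len(table))
    table["rank"] = np.arange(1, len(table) + 1)
    table["prioritized"] = table["rank"] <= n_top
    table["significant"] = table["prioritized"] & (table["p"] <= alpha)
    return table


def shared_stats(list_a: set[str], list_b: set[str]) -> dict:
    """Overlap summary of two gene lists.

    ``shared_pct`` is 100 * |A ∩ B| / |A ∪ B|, rounded to one decimal.
    """
    a, b = set(list_a), set(list_b)
    inter = a & b
    union = a | b
    pct = 100.0 * len(inter) / len(union) if union else 0.0
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_shared": len(inter),
        "shared_pct": round(pct, 1),
        "shared": sorted(inter),
    }
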