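"""Gene-level combination of marker pleiotropy p-values.

Each marker p-value is transformed to a chi-square-1 quantile (the squared
normal quantile of its upper tail) and summed within a gene.  Under the null
the sum is distributed as a weighted sum of chi-square-1 variables whose
weights are the eigenvalues of the gene's marker LD (signed correlation)
matrix; the tail probability of that quadratic form is approximated by the
Liu et al. moment-matching method (a noncentral chi-square matched on the
first cumulants and, when feasible, skewness).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ConfigurationError,
    GeneModel,
    GeneScoreTable,
    GenotypeMatrix,
    PleioTable,
)

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # marker p-values of exactly 0 are floored here


def map_snps_to_genes(
    markers: pd.DataFrame,
    genes: list[GeneModel],
    window_bp: int = 0,
) -> dict[str, list[str]]:
    """Assign markers to genes by position.

    A marker belongs to every gene whose interval [start - window_bp,
    end + window_bp] (1-based inclusive) contains its position; genes without
    any marker are omitted from the mapping.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        str(chrom): grp for chrom, grp in markers.groupby("chrom", sort=False)
    }
    mapping: dict[str, list[str]] = {}
    for gene in genes:
        grp = by_chrom.get(gene.chrom)
        if grp is None:
            continue
        lo = gene.start - window_bp
        hi = gene.end + window_bp
        hit = grp.index[(grp["pos"] >= lo) & (grp["pos"] <= hi)]
        if len(hit):
            mapping[gene.gene_id] = list(hit)
    return mapping


def ld_matrix(G: GenotypeMatrix, marker_ids: list[str]) -> np.ndarray:
    """Signed Pearson correlation matrix of the dosage columns."""
    if not marker_ids:
        raise ConfigurationError("need at least one marker")
    sub = G.subset_markers(marker_ids)
    X = np.nan_to_num(sub.dosages, nan=np.nan)
    # mean-impute any residual missingness so the correlation is defined
    if np.isnan(X).any():
        from .assoc import mean_impute

        X = mean_impute(X)
    sd = X.std(axis=0)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ConfigurationError(
            f"zero-variance marker(s) in LD matrix: {[marker_ids[i] for i in zero]}"
        )
    R = np.corrcoef(X, rowvar=False)
    return np.atleast_2d(R)


def liu_pvalue(T: float, eigenvalues: np.ndarray) -> float:
    """Upper-tail probability of Q = sum_j lambda_j chi2_1 at T.

    Moment-matching approximation: the distribution of Q is matched to a
    (non)central chi-square on mean, variance and — when the skewness
    relation permits — the third cumulant; otherwise the kurtosis-corrected
    central match is used.  Negative eigenvalues are clipped to zero.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if (lam < 0).any():
        log.warning("liu_pvalue: clipping %d negative eigenvalues", int((lam < 0).sum()))
        lam = np.clip(lam, 0, None)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ConfigurationError("all eigenvalues are zero")
    if T < 0:
        raise ConfigurationError("statistic must be non-negative")

    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    mu_x = dof + delta
    sigma_x = np.sqrt(2 * (dof + 2 * delta))
    x = (T - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        p = stats.ncx2.sf(x, df=dof, nc=delta)
    else:
        p = stats.chi2.sf(x, df=dof)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def gene_level_pvalues(
    pleio: PleioTable,
    mapping: dict[str, list[str]],
    G: GenotypeMatrix,
    genes: list[GeneModel] | None = None,
) -> GeneScoreTable:
    """Combine marker pleiotropy p-values into one p-value per gene.

    T_g = sum over the gene's markers of the chi-square-1 upper quantile at
    each marker p; the null distribution of T_g takes the eigenvalues of the
    gene's signed LD matrix as weights, and the gene p is the Liu tail at
    T_g.  Single-marker genes pass the marker p through unchanged.
    """
    meta = {g.gene_id: g for g in (genes or [])}
    marker_p = pleio.table["p"]
    rows = []
    eig: dict[str, np.ndarray] = {}
    for gene_id, marker_ids in mapping.items():
        present = [m for m in marker_ids if m in marker_p.index]
        if not present:
            continue
        p = marker_p.loc[present].to_numpy(dtype=float)
        if (p <= 0).any():
            log.warning("gene %s: flooring %d zero p-values", gene_id, int((p <= 0).sum()))
            p = np.maximum(p, P_FLOOR)
        T = float(stats.chi2.isf(p, df=1).sum())
        if len(present) == 1:
            gene_p = float(p[0])
            lam = np.array([1.0])
        else:
            R = ld_matrix(G, present)
            lam = np.linalg.eigvalsh(R)[::-1]
            gene_p = liu_pvalue(T, lam)
        eig[gene_id] = lam
        gm = meta.get(gene_id)
        rows.append(
            {
                "gene": gene_id,
                "symbol": gm.symbol if gm else "",
                "chrom": gm.chrom if gm else "",
                "n_snps": len(present),
                "T": T,
                "p": gene_p,
            }
        )
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["symbol", "chrom", "n_snps", "T", "p"]
    )
    return GeneScoreTable(table=table, eigenvalues=eig)
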