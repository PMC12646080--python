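"""Over-representation analyses and gene x term incidence matrices.

Gene-set enrichment is the one-sided hypergeometric (Fisher upper-tail)
test of a query list against a background universe, with Benjamini-Hochberg
control at a 5% false discovery rate by default.  QTL annotation links a
gene to every QTL interval intersecting a 100-kb window upstream and
downstream of the gene body; QTL-trait enrichment then applies the same
hypergeometric machinery to the per-trait annotation counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    ConfigurationError,
    GeneModel,
    QTLRecord,
    TermIncidence,
    TermSetCollection,
)

log = logging.getLogger(__name__)


def hypergeom_enrich(
    query: set[str],
    terms: TermSetCollection,
    background: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Columns: ``k`` (overlap), ``K`` (term size in background), ``n`` (query
    size), ``N`` (background size), ``p`` = P(X >= k), BH ``q`` and an
    ``enriched`` flag at q <= fdr.  Symbols are matched case-insensitively.
    """
    query_u = {g.upper() for g in query}
    background_u = {g.upper() for g in background}
    if not query_u or not background_u:
        raise ConfigurationError("query and background must be non-empty")
    if not query_u <= background_u:
        raise ConfigurationError("query must be a subset of the background")
    N = len(background_u)
    n = len(query_u)
    rows = []
    for term, members in terms.sets.items():
        members_bg = members & background_u
        K = len(members_bg)
        if K == 0:
            continue
        k = len(members_bg & query_u)
        # upper tail including k itself: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "source": terms.source,
                "description": terms.descriptions.get(term, ""),
                "k": k, "K": K, "n": n, "N": N,
                "p": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "source", "description", "k", "K", "n", "N", "p", "q", "enriched"]
        )
    table = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = qvals
    table["enriched"] = table["q"] <= fdr
    return table.sort_values("q", kind="stable").reset_index(drop=True)


def annotate_qtls(
    genes: list[GeneModel],
    qtls: list[QTLRecord],
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """Gene x QTL pairs whose intervals intersect within ``window_bp``.

    A pair is emitted when the QTL interval overlaps [gene.start - window,
    gene.end + window] on the same chromosome (window clamped at 1).
    """
    rows = []
    by_chrom: dict[str, list[QTLRecord]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append(q)
    for gene in genes:
        lo = max(1, gene.start - window_bp)
        hi = gene.end + window_bp
        for q in by_chrom.get(gene.chrom, []):
            if q.start <= hi and q.end >= lo:
                rows.append(
                    {
                        "gene": gene.gene_id,
                        "symbol": gene.symbol,
                        "qtl_trait": q.trait,
                        "qtl_class": q.trait_class,
                        "chrom": q.chrom,
                        "qtl_start": q.start,
                        "qtl_end": q.end,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene", "symbol", "qtl_trait", "qtl_class", "chrom",
                 "qtl_start", "qtl_end"],
    )


def qtl_enrich(
    query_annotation: pd.DataFrame,
    background_annotation: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-QTL-trait hypergeometric enrichment of annotated query genes.

    Both tables come from :func:`annotate_qtls` run with the same window;
    the unit of counting is the gene (a gene annotated to a trait by several
    intervals counts once).  Traits present in the query but absent from the
    background are skipped with a warning.
    """
    if query_annotation.empty:
        return pd.DataFrame(
            columns=["qtl_trait", "qtl_class", "k", "K", "n", "N", "p", "q", "enriched"]
        )
    bg_genes = set(background_annotation["gene"])
    q_genes = set(query_annotation["gene"])
    N = len(bg_genes)
    n = len(q_genes)
    bg_by_trait = background_annotation.groupby("qtl_trait")["gene"].agg(set)
    classes = query_annotation.set_index("qtl_trait")["qtl_class"].to_dict()
    rows = []
    for trait, genes_q in query_annotation.groupby("qtl_trait")["gene"].agg(set).items():
        if trait not in bg_by_trait.index:
            log.warning("QTL trait %r absent from background annotation; skipped", trait)
            continue
        K = len(bg_by_trait[trait])
        k = len(genes_q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"qtl_trait": trait, "qtl_class": classes.get(trait, ""),
             "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["qtl_trait", "qtl_class", "k", "K", "n", "N", "p", "q", "enriched"]
        )
    table = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = qvals
    table["enriched"] = table["q"] <= fdr
    return table.sort_values("q", kind="stable").reset_index(drop=True)


def build_incidence(
    genes: list[str],
    enriched: pd.DataFrame,
    terms: TermSetCollection | None = None,
    annotation: pd.DataFrame | None = None,
) -> TermIncidence:
    """Binary gene x enriched-term incidence matrix.

    Membership comes either from ``terms`` (gene symbols, for GO/pathway
    collections; the ``term`` column of ``enriched`` selects the columns) or
    from a QTL ``annotation`` table (the ``qtl_trait`` column).  Genes
    belonging to no enriched term are left out of the matrix and listed in
    ``unannotated``.
    """
    if enriched.empty:
        raise ConfigurationError("enriched table is empty")
    flagged = enriched[enriched["enriched"]] if "enriched" in enriched else enriched
    if flagged.empty:
        raise ConfigurationError("no term passed the FDR threshold")
    membership: dict[str, set[str]] = {}
    qcol: dict[str, float] = {}
    if terms is not None:
        for _, row in flagged.iterrows():
            term = row["term"]
            membership[term] = {g.upper() for g in terms.sets.get(term, set())}
            qcol[term] = float(row.get("q", np.nan))
        genes_norm = {g: g.upper() for g in genes}
    elif annotation is not None:
        for _, row in flagged.iterrows():
            trait = row["qtl_trait"]
            membership[trait] = set(
                annotation.loc[annotation["qtl_trait"] == trait, "gene"]
            )
            qcol[trait] = float(row.get("q", np.nan))
        genes_norm = {g: g for g in genes}
    else:
        raise ConfigurationError("provide either a term collection or a QTL annotation")

    data = {}
    for term, members in membership.items():
        data[term] = [1 if genes_norm[g] in members else 0 for g in genes]
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    matrix = matrix.loc[:, matrix.sum(axis=0) > 0]
    annotated = matrix.sum(axis=1) > 0
    unannotated = list(matrix.index[~annotated])
    matrix = matrix.loc[annotated]
    return TermIncidence(
        matrix=matrix,
        qvalues=pd.Series({t: qcol[t] for t in matrix.columns}),
        unannotated=unannotated,
    )
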