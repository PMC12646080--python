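"""End-to-end orchestration: QC -> GWAS -> pleiotropy -> gene scores ->
co-expression modules -> enrichment -> embeddings -> hierarchical EM ->
prioritized gene lists.

Every stage writes its TSV/JSON artifacts into the output directory along
with a JSON-lines log (stage, parameters, counts, wall time), the resolved
configuration and a manifest tying outputs to input checksums and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, coexpr, embed, enrich, genescore, prioritize as pr
from . import io as pio
from .types import ConfigurationError, WalkConfig, WeightedAdjacency

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run; unknown keys are rejected."""

    # inputs
    genotypes: str = ""
    genotype_format: str | None = None
    traits: str = ""
    covariates: str | None = None
    genes: str = ""
    genes_format: str | None = None
    expression: str = ""
    expression_is_fpkm: bool = True
    gene_lengths: str | None = None
    gmt: str = ""
    qtls: str | None = None
    out_dir: str = "results"
    # association
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    adjust_phenotypes: bool = True
    v_ridge: float | None = None
    # gene scores
    gene_window_bp: int = 0
    # co-expression
    min_fpkm: float = 0.2
    soft_power: int | None = None
    target_fit: float = 0.8
    min_module_size: int = 30
    kmeans_iters: int = 20
    cut_height_frac: float = 0.95
    # enrichment
    enrich_fdr: float = 0.05
    qtl_window_bp: int = 100_000
    # embedding
    n_walks: int = 10
    walk_length: int = 80
    return_weight: float = 0.25
    inout_weight: float = 1.0
    dims: int = 32
    window: int = 32
    epochs: int = 20
    # hierarchical model
    em_tol: float = 1e-6
    em_max_iter: int = 500
    top_frac: float = 0.01
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    out_dir: Path
    prioritized: pd.DataFrame
    gene_scores: "pd.DataFrame"
    fit: "object"
    modules: "object"
    stages: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def record(self, stage: str, t0: float, **counts) -> None:
        entry = {
            "stage": stage,
            "wall_s": round(time.perf_counter() - t0, 3),
            **counts,
        }
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")
        log.info("stage %s done: %s", stage, counts)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage on the configured inputs.

    A stage failure raises with a stage-scoped message; artifacts written by
    earlier stages remain in the output directory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1, sort_keys=True))
    slog = _StageLog(out / "log.jsonl")
    stages: list[str] = []

    def stage(name):
        stages.append(name)
        return time.perf_counter()

    try:
        t0 = stage("load")
        G = pio.read_genotypes(cfg.genotypes, cfg.genotype_format)
        panel = pio.read_traits_tsv(cfg.traits, cfg.covariates)
        genes = pio.read_gene_models(cfg.genes, cfg.genes_format)
        terms = pio.read_gmt(cfg.gmt)
        qtls = pio.read_qtl_bed(cfg.qtls) if cfg.qtls else []
        expr = pio.read_expression_tsv(
            cfg.expression, cfg.expression_is_fpkm, cfg.gene_lengths
        )
        slog.record("load", t0, n_samples=G.n_samples, n_markers=G.n_markers,
                    n_genes=len(genes), n_terms=len(terms.sets), n_qtls=len(qtls))

        t0 = stage("qc")
        G, qc_report = assoc.qc_genotypes(G, cfg.maf_min, cfg.call_rate_min)
        (out / "qc_report.json").write_text(json.dumps(dataclasses.asdict(qc_report)))
        slog.record("qc", t0, **dataclasses.asdict(qc_report))

        t0 = stage("association")
        if cfg.adjust_phenotypes and panel.covariates is not None:
            grm = assoc.compute_grm(G)
            adjusted = {}
            for trait in panel.trait_names:
                adj, _fit = assoc.adjust_phenotype(
                    panel.traits[trait], panel.covariates, grm
                )
                adjusted[trait] = adj
            panel = dataclasses.replace(
                panel,
                traits=pd.DataFrame(adjusted, index=panel.traits.index),
                covariates=None,
            )
        stats_ = assoc.mlma_loco(G, panel)
        gwas = pd.concat(
            {k: getattr(stats_, k) for k in ("beta", "se", "t", "p")}, axis=1
        )
        gwas.columns = [f"{trait}_{k}" for k, trait in gwas.columns]
        gwas = G.markers.join(gwas)
        gwas.to_csv(out / "gwas.tsv", sep="\t", index_label="id")
        slog.record("association", t0, n_markers=G.n_markers,
                    n_traits=panel.n_traits)

        t0 = stage("pleiotropy")
        V = assoc.trait_correlation_matrix(stats_, ridge=cfg.v_ridge)
        pleio = assoc.pleiotropy_statistic(stats_, V)
        pleio.table.join(G.markers).to_csv(out / "pleiotropy.tsv", sep="\t",
                                           index_label="id")
        V.to_csv(out / "trait_correlation.tsv", sep="\t")
        slog.record("pleiotropy", t0, n_markers=len(pleio.table))

        t0 = stage("gene_scores")
        mapping = genescore.map_snps_to_genes(G.markers, genes, cfg.gene_window_bp)
        scores = genescore.gene_level_pvalues(pleio, mapping, G, genes)
        scores.table.to_csv(out / "gene_scores.tsv", sep="\t", index_label="gene")
        slog.record("gene_scores", t0, n_genes_scored=len(scores.table))

        t0 = stage("coexpression")
        if not expr.is_fpkm:
            expr = coexpr.fpkm_normalize(expr)
        expr, n_low = coexpr.filter_low_expression(expr, cfg.min_fpkm)
        if cfg.soft_power is None:
            beta, _fit_table = coexpr.pick_soft_threshold(
                expr, target_fit=cfg.target_fit
            )
        else:
            beta = cfg.soft_power
        adjacency = coexpr.signed_adjacency(expr, beta)
        tom = coexpr.compute_tom(adjacency)
        modules, mod_report = coexpr.detect_modules(
            adjacency, tom, expr,
            min_module_size=cfg.min_module_size,
            kmeans_iters=cfg.kmeans_iters,
            cut_height_frac=cfg.cut_height_frac,
            seed=cfg.seed,
        )
        modules.labels.to_frame("module").to_csv(out / "modules.tsv", sep="\t")
        coexpr.adjacency_edge_list(adjacency, min_weight=0.01).to_csv(
            out / "adjacency_edges.tsv", sep="\t", index=False
        )
        slog.record("coexpression", t0, n_genes=len(modules.labels),
                    n_low_removed=n_low, soft_power=beta,
                    n_modules=len(modules.modules()))

        t0 = stage("enrichment")
        symbol_of = {g.gene_id: (g.symbol or "").upper() for g in genes}
        n_no_symbol = sum(1 for s in symbol_of.values() if not s)
        if n_no_symbol:
            log.warning("%d genes lack a symbol and leave the term networks",
                        n_no_symbol)
        wgcn_ids = list(modules.labels.index)
        wgcn_symbols = {symbol_of.get(g, g.upper()) or g.upper() for g in wgcn_ids}
        enriched_frames = []
        for module in modules.modules():
            mod_symbols = {
                symbol_of.get(g, g.upper()) or g.upper()
                for g in modules.genes_in(module)
            }
            table = enrich.hypergeom_enrich(
                mod_symbols, terms, wgcn_symbols, fdr=cfg.enrich_fdr
            )
            table["module"] = module
            enriched_frames.append(table)
        go_enriched = pd.concat(enriched_frames, ignore_index=True)
        go_enriched.to_csv(out / "term_enrichment.tsv", sep="\t", index=False)

        scored_genes = [g for g in genes if g.gene_id in scores.table.index]
        qtl_annotation = enrich.annotate_qtls(scored_genes, qtls, cfg.qtl_window_bp)
        qtl_annotation.to_csv(out / "qtl_annotation.tsv", sep="\t", index=False)
        module_gene_ids = set(wgcn_ids)
        query_annot = qtl_annotation[qtl_annotation["gene"].isin(module_gene_ids)]
        qtl_enriched = enrich.qtl_enrich(query_annot, qtl_annotation,
                                         fdr=cfg.enrich_fdr)
        qtl_enriched.to_csv(out / "qtl_enrichment.tsv", sep="\t", index=False)
        slog.record("enrichment", t0,
                    n_go_enriched=int(go_enriched["enriched"].sum()),
                    n_qtl_enriched=int(qtl_enriched["enriched"].sum())
                    if len(qtl_enriched) else 0,
                    n_genes_no_symbol=n_no_symbol)

        t0 = stage("networks")
        networks: dict[str, object] = {}
        node_to_gene: dict[str, dict] = {}
        for module in modules.modules():
            ids = modules.genes_in(module)
            if len(ids) < 3:
                continue
            sub = WeightedAdjacency(
                weights=adjacency.weights.loc[ids, ids], beta=adjacency.beta
            )
            name = f"module_{module}"
            networks[name] = embed.build_walk_graph(sub)
            node_to_gene[name] = {g: g for g in ids}

        dedup = go_enriched.drop_duplicates("term")
        if bool(dedup["enriched"].any()):
            symbol_universe = sorted(wgcn_symbols)
            go_inc = enrich.build_incidence(symbol_universe, dedup, terms=terms)
            networks["go_terms"] = embed.build_walk_graph(go_inc)
            sym_to_id: dict[str, str] = {}
            for gid in wgcn_ids:
                sym = symbol_of.get(gid, gid.upper()) or gid.upper()
                sym_to_id.setdefault(sym, gid)
            node_to_gene["go_terms"] = {
                s: sym_to_id[s] for s in go_inc.matrix.index if s in sym_to_id
            }
        if len(qtl_enriched) and bool(qtl_enriched["enriched"].any()):
            qtl_universe = sorted({g.gene_id for g in scored_genes})
            qtl_inc = enrich.build_incidence(
                qtl_universe, qtl_enriched, annotation=qtl_annotation
            )
            networks["qtl"] = embed.build_walk_graph(qtl_inc)
            node_to_gene["qtl"] = {g: g for g in qtl_inc.matrix.index}
        slog.record("networks", t0, n_networks=len(networks))

        t0 = stage("embedding")
        wcfg = WalkConfig(
            n_walks=cfg.n_walks, walk_length=cfg.walk_length,
            return_weight=cfg.return_weight, inout_weight=cfg.inout_weight,
            seed=cfg.seed,
        )
        embeddings = {}
        for name, graph in networks.items():
            walks = embed.biased_random_walks(graph, wcfg)
            emb = embed.skipgram_embed(
                walks, nodes=list(graph.nodes), dims=cfg.dims,
                window=cfg.window, epochs=cfg.epochs, seed=cfg.seed,
            )
            embeddings[name] = emb
            emb.vectors.to_csv(out / f"embedding_{name}.tsv", sep="\t")
        slog.record("embedding", t0, n_networks=len(embeddings))

        t0 = stage("diagnostics")
        gene_p = scores.table["p"]
        ranking_ids = list(gene_p.sort_values(kind="stable").index)
        curves = []
        for module in modules.modules():
            ids = [g for g in ranking_ids if modules.labels.get(g) == module]
            if len(ids) < 2:
                continue
            sub = WeightedAdjacency(
                weights=adjacency.weights.loc[ids, ids], beta=adjacency.beta
            )
            curve = embed.wed_topk(sub, ids)
            df = curve.to_frame()
            df["network"] = f"module_{module}_WED"
            curves.append(df)
        for name in ("go_terms", "qtl"):
            if name not in networks:
                continue
            scores_b = embed.betweenness(networks[name])
            rev: dict[str, str] = {}
            for node, gid in node_to_gene[name].items():
                rev.setdefault(gid, node)
            ranked_nodes = [rev[gid] for gid in ranking_ids if gid in rev]
            if not ranked_nodes:
                continue
            curve = embed.mean_betweenness_topk(scores_b, ranked_nodes)
            df = curve.to_frame()
            df["network"] = f"{name}_betweenness"
            curves.append(df)
        if curves:
            pd.concat(curves, ignore_index=True).to_csv(
                out / "topk_curves.tsv", sep="\t", index=False
            )
        slog.record("diagnostics", t0, n_curves=len(curves))

        t0 = stage("hierarchical_model")
        null = pr.fit_null_mixture(gene_p)
        reductions = {}
        for name, emb in embeddings.items():
            mapping_nodes = node_to_gene[name]
            gene_nodes = [n for n in emb.vectors.index if n in mapping_nodes]
            if len(gene_nodes) < 10:
                continue
            sub_emb = emb.vectors.loc[gene_nodes]
            labels = pd.Series(
                {n: null.ppa.get(mapping_nodes[n], np.nan) for n in gene_nodes}
            ).dropna()
            if labels.empty or np.allclose(labels, labels.iloc[0]):
                continue
            sub_emb = sub_emb.loc[labels.index]
            feat = pr.lda_reduce(sub_emb, labels)
            feat.index = [mapping_nodes[n] for n in feat.index]
            feat = feat[~feat.index.duplicated()]
            reductions[name] = feat
        universe = list(gene_p.index)
        if reductions:
            features = pr.assemble_features(reductions, universe)
        else:
            features = None
            log.warning("no usable network reductions; fitting the null-prior model")
        fit = pr.em_hierarchical(gene_p.loc[universe], features,
                                 tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        result = pr.prioritize(fit, scores, cfg.top_frac, cfg.alpha)
        result.to_csv(out / "ppa.tsv", sep="\t", index_label="gene")
        (out / "fit.json").write_text(json.dumps({
            "a": fit.a, "b0": fit.b0, "b": list(fit.b),
            "null_pi": null.pi, "null_a": null.a,
            "converged": fit.converged, "n_iter": fit.n_iter,
            "loglik_final": float(fit.loglik_trace[-1]),
            "features": list(reductions),
        }, indent=1))
        slog.record("hierarchical_model", t0,
                    n_genes=len(universe),
                    n_prioritized=int(result["prioritized"].sum()),
                    n_significant=int(result["significant"].sum()))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stages[-1]!r}: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "inputs": {
            key: _sha256(path)
            for key, path in (
                ("genotypes", cfg.genotypes), ("traits", cfg.traits),
                ("genes", cfg.genes), ("gmt", cfg.gmt),
                ("expression", cfg.expression), ("qtls", cfg.qtls),
                ("covariates", cfg.covariates),
            )
            if path
        },
        # log.jsonl carries wall times and is excluded so reruns with the
        # same config and seed produce identical manifests
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(Path(out).iterdir())
            if p.is_file() and p.name not in ("manifest.json", "log.jsonl")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        out_dir=out, prioritized=result, gene_scores=scores.table,
        fit=fit, modules=modules, stages=stages,
    )
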