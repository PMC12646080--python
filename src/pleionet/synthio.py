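"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates the data classes the analysis consumes — LD-blocked
diploid genotypes, multiple correlated traits driven by partially shared
(pleiotropic) causal loci, a modular gene-expression matrix, and gene-set /
QTL annotation tracks enriched near the causal genes — together with
ground-truth labels so every downstream stage can be scored for recovery.

Linkage disequilibrium is produced by a per-block latent Gaussian copula:
haplotypes within an LD block are thresholded AR(1) Gaussians, so pairwise
genotype r^2 decays geometrically with marker distance inside a block and is
zero (in expectation) across blocks.  All randomness flows through one
``numpy.random.Generator`` derived from ``SimConfig.seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ConfigurationError,
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    QTLRecord,
    TermSetCollection,
    TraitPanel,
)

MARKER_SPACING_BP = 1_000  # physical distance between adjacent simulated markers


@dataclass
class SimTruth:
    """Ground-truth labels produced alongside simulated data.

    ``causal_markers`` maps marker id -> {trait name: effect size}; a marker
    is pleiotropic when it carries effects on >= 2 traits.  ``module_labels``
    partition the simulated expression gene universe.  ``enriched_terms``
    lists term ids planted with membership bias toward pleiotropic genes.
    """

    causal_markers: dict[str, dict[str, float]] = field(default_factory=dict)
    pleiotropic_genes: list[str] = field(default_factory=list)
    module_labels: dict[str, int] = field(default_factory=dict)
    enriched_terms: list[str] = field(default_factory=list)

    def pleiotropic_markers(self) -> list[str]:
        return [m for m, eff in self.causal_markers.items() if len(eff) >= 2]

    def merged_with(self, other: "SimTruth") -> "SimTruth":
        return SimTruth(
            causal_markers={**self.causal_markers, **other.causal_markers},
            pleiotropic_genes=sorted(
                set(self.pleiotropic_genes) | set(other.pleiotropic_genes)
            ),
            module_labels={**self.module_labels, **other.module_labels},
            enriched_terms=sorted(
                set(self.enriched_terms) | set(other.enriched_terms)
            ),
        )

    def to_dict(self) -> dict:
        return {
            "causal_markers": self.causal_markers,
            "pleiotropic_genes": self.pleiotropic_genes,
            "module_labels": self.module_labels,
            "enriched_terms": self.enriched_terms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            causal_markers={
                m: dict(eff) for m, eff in d.get("causal_markers", {}).items()
            },
            pleiotropic_genes=list(d.get("pleiotropic_genes", [])),
            module_labels={g: int(v) for g, v in d.get("module_labels", {}).items()},
            enriched_terms=list(d.get("enriched_terms", [])),
        )


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    ``ld_rho`` is the AR(1) correlation of the latent haplotype copula within
    an LD block; ``frac_pleiotropic`` is the fraction of causal markers whose
    effect is shared across every trait (the rest are trait-specific).
    ``trait_cor`` is the target residual correlation matrix (defaults to
    identity).
    """

    n_samples: int = 500
    n_markers: int = 1000
    n_chrom: int = 2
    n_traits: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.9
    h2: float = 0.5
    trait_cor: np.ndarray | None = None
    n_causal: int = 20
    frac_pleiotropic: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_markers, self.n_chrom, self.n_traits) <= 0:
            raise ConfigurationError("all dimensions must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.h2 < 1):
            raise ConfigurationError("h2 must be in [0, 1)")
        if not (0 <= self.frac_pleiotropic <= 1):
            raise ConfigurationError("frac_pleiotropic must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not (0 <= self.ld_rho < 1):
            raise ConfigurationError("ld_rho must be in [0, 1)")
        if self.trait_cor is not None:
            R = np.asarray(self.trait_cor, dtype=float)
            if R.shape != (self.n_traits, self.n_traits):
                raise ConfigurationError("trait_cor shape must be traits x traits")
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ConfigurationError(
                    "trait_cor must be symmetric with unit diagonal"
                )
            if np.linalg.eigvalsh(R).min() <= 0:
                raise ConfigurationError("trait_cor must be positive-definite")

    def resolved_trait_cor(self) -> np.ndarray:
        if self.trait_cor is None:
            return np.eye(self.n_traits)
        return np.asarray(self.trait_cor, dtype=float)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if d["trait_cor"] is not None:
            d["trait_cor"] = np.asarray(d["trait_cor"]).tolist()
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("trait_cor") is not None:
            d["trait_cor"] = np.asarray(d["trait_cor"], dtype=float)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


def _ar1_chol(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw LD-blocked diploid dosages.

    Two latent AR(1) Gaussian haplotypes per individual per block are
    thresholded at the normal quantile of each marker's MAF; the dosage is
    the sum of the two haplotype alleles, giving Hardy-Weinberg genotype
    frequencies and within-block LD that decays with distance.
    """
    rng = np.random.default_rng(cfg.seed)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)
    thresholds = stats.norm.ppf(mafs)

    # markers are split as evenly as possible over chromosomes
    per_chrom = np.full(cfg.n_chrom, cfg.n_markers // cfg.n_chrom)
    per_chrom[: cfg.n_markers % cfg.n_chrom] += 1

    dosages = np.empty((cfg.n_samples, cfg.n_markers), dtype=float)
    chroms: list[str] = []
    positions: list[int] = []
    start = 0
    for c, m_c in enumerate(per_chrom):
        chroms.extend([f"chr{c + 1}"] * m_c)
        positions.extend(
            (np.arange(m_c) + 1) * MARKER_SPACING_BP
        )
        offset = start
        while offset < start + m_c:
            block = min(cfg.ld_block_size, start + m_c - offset)
            L = _ar1_chol(block, cfg.ld_rho)
            z1 = rng.standard_normal((cfg.n_samples, block)) @ L.T
            z2 = rng.standard_normal((cfg.n_samples, block)) @ L.T
            thr = thresholds[offset : offset + block]
            dosages[:, offset : offset + block] = (z1 < thr).astype(float) + (
                z2 < thr
            ).astype(float)
            offset += block
        start += m_c

    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    markers = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"snp{i + 1}" for i in range(cfg.n_markers)], name="id"),
    )
    return GenotypeMatrix(dosages=dosages, markers=markers, samples=[
        f"s{i + 1}" for i in range(cfg.n_samples)
    ])


def simulate_gene_models(
    cfg: SimConfig, markers_per_gene: int = 5
) -> list[GeneModel]:
    """Tile gene intervals over the simulated marker map.

    Consecutive runs of ``markers_per_gene`` markers on a chromosome become
    one gene spanning their positions, so every marker falls inside exactly
    one gene.
    """
    G = simulate_genotypes(SimConfig(**{**cfg.to_dict(), "missing_rate": 0.0}))
    genes: list[GeneModel] = []
    gid = 0
    for chrom, grp in G.markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        for i in range(0, len(pos), markers_per_gene):
            chunk = pos[i : i + markers_per_gene]
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid}",
                    symbol=f"GENE{gid}",
                    chrom=str(chrom),
                    start=int(chunk[0]) - MARKER_SPACING_BP // 2,
                    end=int(chunk[-1]) + MARKER_SPACING_BP // 2 - 1,
                )
            )
    return genes


def simulate_traits(
    G: GenotypeMatrix,
    cfg: SimConfig,
    genes: list[GeneModel] | None = None,
) -> tuple[TraitPanel, SimTruth]:
    """Generate correlated traits driven by partially shared causal markers.

    A fraction ``frac_pleiotropic`` of the causal markers carry an effect on
    every trait; the remainder are assigned round-robin to single traits.
    Residual noise is multivariate normal with correlation ``trait_cor`` and
    is scaled per trait so the realized heritability matches ``h2``.  When
    ``genes`` is given, genes containing a shared-effect marker are recorded
    as the pleiotropic truth set.
    """
    if G.n_markers == 0 or G.n_samples == 0:
        raise ConfigurationError("genotype matrix must be non-empty")
    if cfg.n_traits < 2:
        raise ConfigurationError("at least 2 traits required")
    rng = np.random.default_rng(cfg.seed + 1)
    R = cfg.resolved_trait_cor()

    n_causal = min(cfg.n_causal, G.n_markers)
    causal_idx = rng.choice(G.n_markers, size=n_causal, replace=False)
    n_shared = int(round(cfg.frac_pleiotropic * n_causal))
    shared = causal_idx[:n_shared]
    specific = causal_idx[n_shared:]

    trait_names = [f"trait{t + 1}" for t in range(cfg.n_traits)]
    marker_ids = np.asarray(G.marker_ids)
    effects = np.zeros((G.n_markers, cfg.n_traits))
    truth = SimTruth()
    for j in shared:
        per_trait = rng.standard_normal(cfg.n_traits)
        effects[j, :] = per_trait
        truth.causal_markers[marker_ids[j]] = {
            trait_names[t]: float(per_trait[t]) for t in range(cfg.n_traits)
        }
    for k, j in enumerate(specific):
        t = k % cfg.n_traits
        eff = rng.standard_normal()
        effects[j, t] = eff
        truth.causal_markers[marker_ids[j]] = {trait_names[t]: float(eff)}

    X = np.nan_to_num(G.dosages, nan=0.0)
    X = X - X.mean(axis=0, keepdims=True)
    genetic = X @ effects if cfg.h2 > 0 else np.zeros((G.n_samples, cfg.n_traits))

    noise = rng.multivariate_normal(
        np.zeros(cfg.n_traits), R, size=G.n_samples, method="cholesky"
    )
    values = np.empty_like(genetic)
    for t in range(cfg.n_traits):
        g = genetic[:, t]
        vg = g.var()
        if cfg.h2 > 0 and vg > 0:
            ve_target = vg * (1 - cfg.h2) / cfg.h2
            values[:, t] = g + noise[:, t] * np.sqrt(ve_target)
        else:
            values[:, t] = noise[:, t]

    panel = TraitPanel(
        traits=pd.DataFrame(values, index=G.samples, columns=trait_names)
    )

    if genes is not None:
        shared_ids = set(marker_ids[shared])
        pos_by_chrom = {
            chrom: grp for chrom, grp in G.markers.groupby("chrom", sort=False)
        }
        pleio: set[str] = set()
        for gene in genes:
            grp = pos_by_chrom.get(gene.chrom)
            if grp is None:
                continue
            inside = grp.index[(grp["pos"] >= gene.start) & (grp["pos"] <= gene.end)]
            if shared_ids.intersection(inside):
                pleio.add(gene.gene_id)
        truth.pleiotropic_genes = sorted(pleio)
    return panel, truth


def simulate_expression(
    genes: list[GeneModel],
    module_spec: dict[int, int],
    n_samples: int,
    within_cor: float = 0.8,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate an FPKM-scale matrix with planted co-expression modules.

    Genes assigned to a module share a latent sample factor: on the latent
    Gaussian scale the pairwise within-module correlation equals
    ``within_cor``; values are exponentiated to a non-negative FPKM-like
    scale.  Unassigned genes are independent noise.
    """
    if not (0 < within_cor < 1):
        raise ConfigurationError("within_cor must be in (0, 1)")
    if sum(module_spec.values()) > len(genes):
        raise ConfigurationError("module sizes exceed the gene universe")
    rng = np.random.default_rng(seed)

    gene_ids = [g.gene_id for g in genes]
    n_genes = len(genes)
    z = rng.standard_normal((n_genes, n_samples))
    truth = SimTruth()
    row = 0
    for module, count in sorted(module_spec.items()):
        factor = rng.standard_normal(n_samples)
        lam = np.sqrt(within_cor)
        for _ in range(count):
            z[row] = lam * factor + np.sqrt(1 - within_cor) * z[row]
            truth.module_labels[gene_ids[row]] = module
            row += 1

    base = rng.uniform(0.5, 4.0, size=n_genes)  # log-scale abundance spread
    fpkm = np.exp(base[:, None] + z)
    expr = ExpressionMatrix(
        values=pd.DataFrame(
            fpkm,
            index=pd.Index(gene_ids, name="gene"),
            columns=[f"s{i + 1}" for i in range(n_samples)],
        ),
        is_fpkm=True,
    )
    return expr, truth


def simulate_annotation(
    genes: list[GeneModel],
    truth: SimTruth,
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 50),
    bias: float = 5.0,
    n_planted: int | None = None,
    qtl_count: int = 20,
    qtl_causal_fraction: float = 0.5,
    qtl_window_bp: int = 100_000,
    seed: int = 0,
) -> tuple[TermSetCollection, list[QTLRecord], SimTruth]:
    """Plant gene-set terms and QTL intervals around the causal genes.

    The first ``n_planted`` terms (default: a quarter) sample their members
    with probability multiplier ``bias`` for pleiotropic genes; the rest
    sample uniformly.  A fraction ``qtl_causal_fraction`` of QTL intervals
    is centred on pleiotropic genes (within ``qtl_window_bp``); the rest are
    placed uniformly over the gene map.
    """
    if bias < 1:
        raise ConfigurationError("bias must be >= 1")
    lo, hi = term_size_range
    if hi > len(genes):
        raise ConfigurationError("term sizes exceed the gene universe")
    rng = np.random.default_rng(seed)
    if n_planted is None:
        n_planted = max(1, n_terms // 4) if bias > 1 else 0

    symbols = np.array([g.symbol or g.gene_id for g in genes])
    pleio_set = set(truth.pleiotropic_genes)
    is_pleio = np.array([g.gene_id in pleio_set for g in genes], dtype=float)

    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    planted: list[str] = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        term = f"TERM{t + 1:03d}"
        if t < n_planted:
            w = 1.0 + (bias - 1.0) * is_pleio
            planted.append(term)
            descriptions[term] = "planted near pleiotropic genes"
        else:
            w = np.ones(len(genes))
            descriptions[term] = "background term"
        members = rng.choice(
            symbols, size=size, replace=False, p=w / w.sum()
        )
        sets[term] = set(members)
    terms = TermSetCollection(sets=sets, descriptions=descriptions, source="GO")

    by_id = {g.gene_id: g for g in genes}
    pleio_genes = [by_id[g] for g in truth.pleiotropic_genes if g in by_id]
    qtl_traits = ["milk yield", "fat percentage", "somatic cell score", "stature"]
    qtl_classes = {"milk yield": "milk", "fat percentage": "milk",
                   "somatic cell score": "health", "stature": "exterior"}
    qtls: list[QTLRecord] = []
    n_on_causal = int(round(qtl_causal_fraction * qtl_count)) if pleio_genes else 0
    for q in range(qtl_count):
        trait = qtl_traits[q % len(qtl_traits)]
        if q < n_on_causal:
            g = pleio_genes[int(rng.integers(len(pleio_genes)))]
            centre = (g.start + g.end) // 2 + int(
                rng.integers(-qtl_window_bp // 2, qtl_window_bp // 2 + 1)
            )
            chrom = g.chrom
        else:
            g = genes[int(rng.integers(len(genes)))]
            chrom = g.chrom
            centre = int(rng.integers(g.start, g.end + 1))
        centre = max(1, centre)
        half = int(rng.integers(5_000, 50_000))
        qtls.append(
            QTLRecord(
                trait=trait,
                trait_class=qtl_classes[trait],
                chrom=chrom,
                start=max(1, centre - half),
                end=centre + half,
            )
        )
    out_truth = SimTruth(
        pleiotropic_genes=list(truth.pleiotropic_genes),
        enriched_terms=planted,
    )
    return terms, qtls, out_truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    dir_path: str | Path,
    genotypes: GenotypeMatrix,
    panel: TraitPanel,
    expression: ExpressionMatrix,
    genes: list[GeneModel],
    terms: TermSetCollection,
    qtls: list[QTLRecord],
    truth: SimTruth,
    cfg: SimConfig,
) -> dict[str, str]:
    """Serialize a complete simulated study to plain-text interchange files.

    Writes VCF (genotypes), TSV (traits, expression), BED (genes, QTLs), GMT
    (terms) and JSON (truth + config); returns a manifest mapping file name
    to SHA-256 checksum, also written as ``manifest.json``.
    """
    from . import io as pio

    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_vcf(out / "genotypes.vcf", genotypes)
    panel.traits.to_csv(out / "traits.tsv", sep="\t", index_label="sample")
    if panel.covariates is not None:
        panel.covariates.to_csv(out / "covariates.tsv", sep="\t", index_label="sample")
    expression.values.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    pio.write_gene_bed(out / "genes.bed", genes)
    pio.write_qtl_bed(out / "qtls.bed", qtls)
    pio.write_gmt(out / "terms.gmt", terms)
    (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1, sort_keys=True))

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
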