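"""Readers and writers for the interchange formats the pipeline speaks.

Internal coordinates are uniformly 1-based inclusive; BED input (0-based,
half-open) is converted on read and back on write.  Genotypes travel as
VCF 4.2 with GT fields (multi-allelic sites are rejected — the dosage
coding 0/1/2 is biallelic by construction) or as a documented TSV dialect
with one marker per row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthio import SimConfig, SimTruth
from .types import (
    ConfigurationError,
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    QTLRecord,
    TermSetCollection,
    TraitPanel,
)


# ---------------------------------------------------------------- genotypes


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF 4.2 or the TSV dosage dialect.

    The format is inferred from the extension when not given.  VCF GT fields
    become alternate-allele dosages (0/1/2, missing -> NaN); multi-allelic
    records are rejected with the offending locus named.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ConfigurationError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    for i, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            raise ConfigurationError(
                f"multi-allelic site at {variant.CHROM}:{variant.POS} "
                f"(record {i}): ALT={','.join(variant.ALT)}"
            )
        dos = np.empty(len(samples))
        for s, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            dos[s] = float(sum(alleles)) if len(alleles) == len(gt) - 1 else np.nan
        rows.append(dos)
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        meta.append((vid, variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
    if not rows:
        raise ConfigurationError(f"no records in {path}")
    markers = pd.DataFrame(
        meta, columns=["id", "chrom", "pos", "ref", "alt"]
    ).set_index("id")
    return GenotypeMatrix(
        dosages=np.asarray(rows).T, markers=markers, samples=samples
    )


def write_vcf(path: str | Path, G: GenotypeMatrix) -> None:
    """Write a minimal VCF 4.2 with GT fields from dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(G.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, (mid, row) in enumerate(G.markers.iterrows()):
            calls = [
                "./." if np.isnan(d) else gt_map[int(round(d))]
                for d in G.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{mid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    """TSV dialect: columns id, chrom, pos, ref, alt, then one per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"genotype TSV lacks columns {missing}")
    samples = [c for c in df.columns if c not in required]
    markers = df[required].set_index("id")
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages=dosages, markers=markers, samples=samples)


def write_genotypes_tsv(path: str | Path, G: GenotypeMatrix) -> None:
    df = G.markers.reset_index()
    for s_idx, sample in enumerate(G.samples):
        df[sample] = G.dosages[s_idx]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- gene models


def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene intervals from BED (0-based half-open) or GFF3 ``gene`` rows."""
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if format == "bed":
        return _read_gene_bed(path)
    if format == "gff3":
        return _read_gene_gff3(path)
    raise ConfigurationError(f"unknown gene-model format {format!r}")


def _read_gene_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ConfigurationError(f"{path}:{ln}: BED needs >= 4 columns")
            chrom, start0, end0, name = fields[:4]
            strand = fields[5] if len(fields) > 5 else "+"
            symbol = fields[6] if len(fields) > 6 else name
            start = int(start0) + 1
            end = int(end0)
            if end < start:
                raise ConfigurationError(
                    f"{path}:{ln}: empty/negative interval after conversion"
                )
            genes.append(
                GeneModel(
                    gene_id=name, symbol=symbol, chrom=chrom,
                    start=start, end=end, strand=strand,
                )
            )
    return genes


def write_gene_bed(path: str | Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{g.symbol}\n"
            )


def _read_gene_gff3(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ConfigurationError(f"{path}:{ln}: GFF3 needs 9 columns")
            if fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"gene_at_{fields[0]}:{fields[3]}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=attrs.get("Name", ""),
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                )
            )
    return genes


# ---------------------------------------------------------------- QTL tracks


def read_qtl_bed(path: str | Path) -> list[QTLRecord]:
    """BED-like QTL track: chrom, start (0-based), end, trait, trait class."""
    qtls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ConfigurationError(f"{path}:{ln}: QTL BED needs 5 columns")
            qtls.append(
                QTLRecord(
                    chrom=fields[0],
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                    trait=fields[3],
                    trait_class=fields[4],
                )
            )
    return qtls


def write_qtl_bed(path: str | Path, qtls: list[QTLRecord]) -> None:
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(f"{q.chrom}\t{q.start - 1}\t{q.end}\t{q.trait}\t{q.trait_class}\n")


# ---------------------------------------------------------------- GMT


def read_gmt(path: str | Path, source: str = "GO") -> TermSetCollection:
    """Tab-separated gene sets: term, description, member symbols."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(
                    f"{path}:{ln}: GMT line needs term, description and >= 1 gene"
                )
            term, desc, *members = fields
            if term in sets:
                raise ConfigurationError(f"{path}:{ln}: duplicate term id {term!r}")
            members = {m for m in members if m}
            if not members:
                raise ConfigurationError(f"{path}:{ln}: term {term!r} has no members")
            sets[term] = members
            descriptions[term] = desc
    return TermSetCollection(sets=sets, descriptions=descriptions, source=source)


def write_gmt(path: str | Path, terms: TermSetCollection) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms.sets):
            members = "\t".join(sorted(terms.sets[term]))
            fh.write(f"{term}\t{terms.descriptions.get(term, '')}\t{members}\n")


# ---------------------------------------------------------------- tables


def read_traits_tsv(
    path: str | Path, covariates_path: str | Path | None = None
) -> TraitPanel:
    traits = pd.read_csv(path, sep="\t", index_col="sample")
    traits.index.name = None
    covariates = None
    if covariates_path is not None:
        covariates = pd.read_csv(covariates_path, sep="\t", index_col="sample")
        covariates.index.name = None
    return TraitPanel(traits=traits, covariates=covariates)


def read_expression_tsv(
    path: str | Path,
    is_fpkm: bool = True,
    gene_lengths_path: str | Path | None = None,
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene")
    lengths = None
    if gene_lengths_path is not None:
        lengths = pd.read_csv(
            gene_lengths_path, sep="\t", index_col="gene"
        ).iloc[:, 0]
    return ExpressionMatrix(values=values, is_fpkm=is_fpkm, gene_lengths=lengths)


def read_truth(path: str | Path) -> SimTruth:
    return SimTruth.from_dict(json.loads(Path(path).read_text()))


def read_sim_config(path: str | Path) -> SimConfig:
    return SimConfig.from_dict(json.loads(Path(path).read_text()))


def read_fixture_bundle(dir_path: str | Path) -> dict:
    """Read back everything :func:`pleionet.synthio.write_fixture_bundle` wrote."""
    d = Path(dir_path)
    out = {
        "genotypes": read_genotypes(d / "genotypes.vcf", format="vcf"),
        "panel": read_traits_tsv(
            d / "traits.tsv",
            (d / "covariates.tsv") if (d / "covariates.tsv").exists() else None,
        ),
        "expression": read_expression_tsv(d / "expression.tsv", is_fpkm=True),
        "genes": read_gene_models(d / "genes.bed", format="bed"),
        "terms": read_gmt(d / "terms.gmt"),
        "qtls": read_qtl_bed(d / "qtls.bed"),
        "truth": read_truth(d / "truth.json"),
        "config": read_sim_config(d / "config.json"),
    }
    manifest_path = d / "manifest.json"
    if manifest_path.exists():
        out["manifest"] = json.loads(manifest_path.read_text())
    return out
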