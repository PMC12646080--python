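import numpy as np
import pandas as pd
import pytest

from pleionet.synthio import SimConfig, simulate_genotypes, simulate_gene_models
from pleionet.types import GeneModel, GenotypeMatrix


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_samples=300, n_markers=400, n_chrom=2, n_traits=3,
        n_causal=12, h2=0.5, frac_pleiotropic=0.5, seed=42,
    )


@pytest.fixture(scope="session")
def small_genotypes(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_genes(small_cfg):
    return simulate_gene_models(small_cfg)


def make_genotypes(dosages: np.ndarray, chroms=None, positions=None) -> GenotypeMatrix:
    """Hand-built genotype fixture helper."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["chr1"] * m,
            "pos": positions if positions is not None else list(range(1, m + 1)),
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"m{i + 1}" for i in range(m)], name="id"),
    )
    return GenotypeMatrix(
        dosages=dosages, markers=markers, samples=[f"s{i + 1}" for i in range(n)]
    )


def make_genes(spec: list[tuple[str, str, int, int]]) -> list[GeneModel]:
    return [
        GeneModel(gene_id=g, chrom=c, start=s, end=e, symbol=g.upper())
        for g, c, s, e in spec
    ]
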