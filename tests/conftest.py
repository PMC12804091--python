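import numpy as np
import pytest

from hotxpect.catalog_io import GeneModel
from hotxpect.synthetic_data import SimulationConfig, simulate_sequences


def random_gene(rng: np.random.Generator, n_codons: int, name: str = "TOY") -> GeneModel:
    """Random stop-free gene with flanks, for property tests."""
    stop = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in stop:
            codons.append(codon)
    flanks = rng.choice(list("ACGT"), size=2)
    return GeneModel(name, "+", flanks[0] + "".join(codons) + flanks[1])


def random_local_spectrum(rng: np.random.Generator, gene: GeneModel):
    """Random channel distribution supported on the gene's contexts."""
    from hotxpect.spectrum import CHANNEL_CONTEXT_INDEX, LocalSpectrum, context_composition

    comp = context_composition(gene)
    weights = rng.random(96)
    weights[comp.counts[CHANNEL_CONTEXT_INDEX] == 0] = 0.0
    return LocalSpectrum(probs=weights / weights.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_gene():
    # ATG GGA TAT CAC TGG with flanks c...g; no internal stop
    return GeneModel("TOY", "+", "CATGGGATATCACTGGG")


@pytest.fixture
def small_cfg():
    return SimulationConfig(
        seed=7, n_samples=10, snvs_per_sample=80, exome_length=3000,
        focal_gene_length_codons=30,
    )


@pytest.fixture
def small_world(small_cfg):
    exome, gene = simulate_sequences(small_cfg)
    return small_cfg, exome, gene
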