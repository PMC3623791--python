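"""Shared fixtures: random genomes, planted-junction loci, a trained model."""
import numpy as np
import pytest

from spliceseek.aligner import build_index
from spliceseek.io_formats import Genome
from spliceseek.junction_model import train_model
from spliceseek.patterned import PatternParams
from spliceseek.simulate import SimConfig, simulate_genome

BASES = np.array(list("ACGT"))


def random_sequence(n: int, rng) -> str:
    return "".join(BASES[rng.integers(0, 4, n)].tolist())


def random_genome(n: int, seed: int, name: str = "chr1") -> Genome:
    return Genome({name: random_sequence(n, np.random.default_rng(seed))})


def planted_junction_genome(
    seed: int = 3,
    exon1: int = 400,
    intron: int = 86,
    exon2: int = 400,
    donor: str = "GT",
    acceptor: str = "AG",
    pad: int = 1500,
):
    """Random genome with one exon-intron-exon gene; returns the genome, the
    intron interval [donor_end, acceptor_start) and the spliced transcript."""
    rng = np.random.default_rng(seed)
    seq = list(random_sequence(pad + exon1 + intron + exon2 + pad, rng))
    donor_end = pad + exon1
    acceptor_start = donor_end + intron
    seq[donor_end : donor_end + 2] = list(donor)
    seq[acceptor_start - 2 : acceptor_start] = list(acceptor)
    genome = Genome({"chr1": "".join(seq)})
    transcript = (
        genome.sequences["chr1"][pad : pad + exon1]
        + genome.sequences["chr1"][acceptor_start : acceptor_start + exon2]
    )
    return genome, (donor_end, acceptor_start), transcript


TRAIN_CFG = SimConfig(genome_length=1_200_000, n_genes=150, seed=101)


@pytest.fixture(scope="session")
def trained_model():
    genome, _, truth = simulate_genome(TRAIN_CFG)
    model, _ = train_model(genome, truth.junctions, seed=101, max_intron=20_000)
    return model


@pytest.fixture(scope="session")
def small_genome():
    return random_genome(10_000, 5)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index(small_genome, 8)


@pytest.fixture
def params():
    return PatternParams(max_intron=20_000)
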