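import numpy as np
import pytest

from carnafold import carna, synthio


@pytest.fixture(scope="session")
def genome():
    """Small two-chromosome synthetic genome with planted structure."""
    spec = synthio.SyntheticGenomeSpec(n_chroms=2, chrom_length=2**17, seed=1)
    return synthio.make_genome(spec)


@pytest.fixture(scope="session")
def grid(genome):
    return genome.grid()


@pytest.fixture(scope="session")
def genes(genome):
    return carna.GeneModel.from_table(genome.genes)


@pytest.fixture(scope="session")
def rna_dna_fixture(genome, tmp_path_factory):
    """RNA-DNA pairs file + truth table (cis fraction 0.6, 20k reads)."""
    out = tmp_path_factory.mktemp("rd")
    spec = synthio.SyntheticContactSpec(n_reads=20_000, cis_fraction=0.6)
    path, truth = synthio.make_rna_dna_pairs(spec, genome, seed=3,
                                             out=out / "rd.pairs",
                                             truth_out=out / "truth.tsv")
    return path, truth


@pytest.fixture(scope="session")
def contacts(rna_dna_fixture):
    path, _ = rna_dna_fixture
    return carna.parse_rna_dna_pairs(path)


@pytest.fixture(scope="session")
def dna_dna_pairs(genome, tmp_path_factory):
    out = tmp_path_factory.mktemp("dd") / "dd.pairs"
    synthio.make_dna_dna_pairs(genome.structure, genome.chromsizes, 60_000,
                               seed=2, out=out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
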