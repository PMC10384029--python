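import numpy as np
import pytest

from cubkit.genetic_code import load_code
from cubkit.sequence_io import CdsRecord, count_codons


@pytest.fixture(scope="session")
def code():
    return load_code(1)


@pytest.fixture(scope="session")
def ciliate_code():
    return load_code(6)


@pytest.fixture(scope="session")
def random_gene(code):
    """Factory: a random QC-passing gene of n analyzed codons."""

    def make(n=200, seed=0, gene_id="rand"):
        rng = np.random.default_rng(seed)
        body = "".join(rng.choice(code.analyzed_codons, size=n))
        return CdsRecord(gene_id, "ATG" + body + "TAA")

    return make


@pytest.fixture(scope="session")
def random_counts(code, random_gene):
    """Factory: codon counts of a random QC-passing gene."""

    def make(n=200, seed=0, gene_id="rand"):
        return count_codons(random_gene(n, seed, gene_id), code)

    return make
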