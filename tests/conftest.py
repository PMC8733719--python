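import numpy as np
import pytest
from hypothesis import settings

from paircut import Genome, GeneSpec, GuideSpec, simulate_genome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASES = "ACGT"


def random_sequence(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


@pytest.fixture(scope="session")
def toy_sim():
    """A 6 kb contig with a 3-exon gene and two planted guides."""
    gene = GeneSpec(
        "contig1", 1000,
        exon_lengths=[300, 400, 300], intron_lengths=[250, 250],
        gene_id="geneA",
    )
    return simulate_genome(
        n_contigs=1,
        contig_length=6000,
        genes=[gene],
        guides=[
            GuideSpec("contig1", 1400, strand="+"),
            GuideSpec("contig1", 2300, strand="-"),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_genome(toy_sim):
    return toy_sim.genome


def make_genome(**records: str) -> Genome:
    g = Genome()
    for name, seq in records.items():
        g.add(name, seq)
    return g
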