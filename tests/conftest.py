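import pytest

from genomeaudit.assembly import GenomeAssembly
from genomeaudit.simulate import generate_genome, plant_genes


@pytest.fixture(scope="session")
def small_genome() -> GenomeAssembly:
    """Two-replicon 180 kb genome with bounded repeats (anchors unambiguous)."""
    return generate_genome(
        [120_000, 60_000], 0.5, seed=101, assembly_id="truth", max_repeat=19
    )


@pytest.fixture(scope="session")
def coding_genome():
    """120 kb genome carrying 15 planted CDS genes on both strands."""
    genome = generate_genome([120_000], 0.5, seed=202, assembly_id="coding",
                             max_repeat=19)
    return plant_genes(genome, 15, seed=203)


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly(
        "toy",
        {
            "c1": "ATGC" * 10,
            "c2": "GGCC" * 5,
        },
    )
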