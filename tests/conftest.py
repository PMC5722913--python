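import pytest

import elongrate as eg
from elongrate.genome import GeneRecord, SyntheticGenome


@pytest.fixture
def toy_operon_genome() -> SyntheticGenome:
    """Three-gene plus-strand operon with round coordinates."""
    genes = [
        GeneRecord("gA", 1, 300, "+", "op1", 0),
        GeneRecord("gB", 351, 650, "+", "op1", 1),
        GeneRecord("gC", 701, 1000, "+", "op1", 2),
    ]
    return SyntheticGenome(genes=genes, genome_length=1200)


@pytest.fixture
def genome_small() -> SyntheticGenome:
    return eg.generate_genome(40, operon_size_dist=(1, 4), length_dist=(300, 3000), seed=11)


@pytest.fixture
def truth_small(genome_small) -> eg.SyntheticTruth:
    return eg.generate_truth(genome_small, seed=5)


def operon_cohort(n_operons: int, seed: int, speed_range=(5.0, 60.0)):
    """3-gene operon cohort with one true speed per operon."""
    from elongrate.synthetic import generate_operon_cohort

    return generate_operon_cohort(n_operons, speed_range=speed_range, seed=seed)
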