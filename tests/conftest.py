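import numpy as np
import pytest

from uasis import FixtureSpec, build_index, generate_genome, plant_snps

SMALL_SPEC = FixtureSpec(genome_length=20_000, n_snps=100, seed=7, indel_fraction=0.2)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_truth_and_store(small_genome):
    return plant_snps(small_genome, SMALL_SPEC)


@pytest.fixture(scope="session")
def small_truth(small_truth_and_store):
    return small_truth_and_store[0]


@pytest.fixture(scope="session")
def small_store(small_truth_and_store):
    return small_truth_and_store[1]


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index(small_genome)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
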