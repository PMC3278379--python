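import random

import numpy as np
import pytest

from orthoselect.synthdata import SimulationConfig, generate


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-gene benchmark at low divergence with duplicates and
    contamination, shared across tests that only read it."""
    config = SimulationConfig(
        n_genes=30, codon_length=(100, 250), branch_subs=0.005,
        dup_rate=0.4, ambiguity_rate=0.6, novel_fraction=0.2, seed=11)
    return generate(config)


def random_cds(rng, n_codons):
    from tests.oracles import CODE
    sense = sorted(c for c, aa in CODE.items() if aa != "*")
    return "ATG" + "".join(rng.choice(sense) for _ in range(n_codons - 1))
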