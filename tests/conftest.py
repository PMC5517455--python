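import numpy as np
import pytest

import slphtyper as sl


@pytest.fixture(scope="session")
def synth():
    """Default synthetic reference: 3 groups x 10 STs with planted markers."""
    db, markers = sl.synthetic_reference_db(sl.SynthDBSpec(seed=42))
    return db, markers


@pytest.fixture(scope="session")
def synth_db(synth):
    return synth[0]


@pytest.fixture(scope="session")
def synth_markers(synth):
    return synth[1]


@pytest.fixture(scope="session")
def tiny():
    """Small synthetic reference (2 groups x 2 STs, short alleles) for oracles."""
    spec = sl.SynthDBSpec(n_groups=2, sts_per_group=2,
                          length_range=(420, 480), seed=7)
    return sl.synthetic_reference_db(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
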