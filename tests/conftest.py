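import numpy as np
import pytest

from asrfam.seqio import SequenceRecord
from asrfam.synthetic_data import (
    SyntheticConfig,
    generate_family_genome,
    generate_paper_shaped_family,
)


@pytest.fixture(scope="session")
def paper_shaped():
    """33-gene six-group synthetic family shaped like the wheat survey."""
    return generate_paper_shaped_family(7)


@pytest.fixture(scope="session")
def small_genome():
    cfg = SyntheticConfig(seed=11, n_triads=2, tandem_array_sizes=(3,), n_decoys=20)
    return cfg, generate_family_genome(cfg)


@pytest.fixture(scope="session")
def family_table():
    from asrfam.seqio import load_family_table

    return load_family_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture()
def make_protein(rng):
    def _make(n, rid="p"):
        return SequenceRecord(rid, random_protein(rng, n))

    return _make
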