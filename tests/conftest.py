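import numpy as np
import pytest

from abtriage.numbering import reference_chain
from abtriage.synthetic_fixtures import RepertoireSpec, generate_repertoire


@pytest.fixture(scope="session")
def heavy_ref():
    return reference_chain("heavy_consensus")


@pytest.fixture(scope="session")
def kappa_ref():
    return reference_chain("kappa_consensus")


@pytest.fixture(scope="session")
def lambda_ref():
    return reference_chain("lambda_consensus")


@pytest.fixture(scope="session")
def small_repertoire():
    """30 numberable paired records, CDR-H3 capped to fit the grid."""
    return generate_repertoire(RepertoireSpec(n=30, seed=11, cdr_h3_max=18))


@pytest.fixture(scope="session")
def tight_clinical():
    """A low-mutation 'clinical-like' reference set with narrow CDR-H3."""
    return generate_repertoire(RepertoireSpec(
        n=20, seed=12, mutation_rate=0.01, cdr_h3_sd=2.0, cdr_h3_max=16,
        status="clinical"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
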