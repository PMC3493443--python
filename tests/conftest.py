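import numpy as np
import pytest

from foxsurvey import SimulationParams, make_survey_fixture, simulate_family
from foxsurvey.pairwise import DEFAULT_SCHEME, GLOBAL_SCHEME
from foxsurvey.seq_io import SequenceRecord


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def global_scheme():
    return GLOBAL_SCHEME


@pytest.fixture(scope="session")
def small_family():
    """A 3-subfamily, 3-taxa family used across module tests."""
    return simulate_family(SimulationParams(n_subfamilies=3, taxa_per_subfamily=3, seed=11))


@pytest.fixture(scope="session")
def survey_fixture(tmp_path_factory):
    """A small on-disk survey fixture (proteomes + panel + truth)."""
    out = tmp_path_factory.mktemp("fixture")
    params = SimulationParams(n_subfamilies=3, taxa_per_subfamily=3, seed=11)
    return make_survey_fixture(params, out)


def random_protein(rng: np.random.Generator, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    letters = list(alphabet)
    return "".join(rng.choice(letters, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def record(name: str, residues: str) -> SequenceRecord:
    return SequenceRecord(id=name, residues=residues)
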