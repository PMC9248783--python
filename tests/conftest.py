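import numpy as np
import pytest

from meltid import synthdata
from meltid.meltio import MeltDataset, SampleSeries


@pytest.fixture
def small_dataset():
    """Two wells on a 3-point grid."""
    grid = np.array([65.0, 65.1, 65.2])
    return MeltDataset(
        grid,
        [
            SampleSeries("A1", np.array([100.0, 90.0, 70.0])),
            SampleSeries("A2", np.array([50.0, 50.0, 50.0])),
        ],
    )


@pytest.fixture(scope="session")
def eight_species_fixture():
    return synthdata.make_fixture("eight_species", seed=11)


@pytest.fixture(scope="session")
def ambiguity_fixture():
    return synthdata.make_fixture("caliginosa_longa_ambiguity", seed=11)


@pytest.fixture(scope="session")
def chlorotica_fixture():
    return synthdata.make_fixture("chlorotica_haplotypes", seed=11)
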