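import numpy as np
import pandas as pd
import pytest

from otunet.filtering import filter_otus
from otunet.synthetic_data import SimulationDesign, simulate_study
from otunet.tables_io import OtuTable


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {"group": ["A", "A", "B", "B"], "tank": ["t1", "t1", "t2", "t2"]},
        index=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def toy_table(toy_meta) -> OtuTable:
    counts = pd.DataFrame(
        {
            "otu1": [10, 12, 0, 1],
            "otu2": [5, 4, 20, 18],
            "otu3": [0, 0, 3, 5],
        },
        index=toy_meta.index,
    )
    return OtuTable(counts, toy_meta)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (45 samples x 200 OTUs, depth 10,000)."""
    return simulate_study(SimulationDesign(), seed=0)


@pytest.fixture(scope="session")
def filtered_study(study):
    table, truth = study
    filtered, _ = filter_otus(table)
    return filtered, truth


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast end-to-end tests (60 OTUs)."""
    design = SimulationDesign(
        n_otus=60,
        n_stable=4,
        n_per_archetype=3,
        n_positive_pairs=4,
        n_negative_pairs=2,
    )
    return simulate_study(design, seed=7)
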