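import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mareco.synthetic_data import (NeutralSimSpec, StructuredSimSpec,
                                   hub_annotations, hub_taxon_ids,
                                   simulate_neutral_table,
                                   simulate_structured_table,
                                   two_habitat_study)
from mareco.tables_io import OtuTable

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> OtuTable:
    counts = pd.DataFrame(
        {"s1": [5, 3, 2], "s2": [0, 6, 4], "s3": [1, 0, 9], "s4": [2, 2, 2]},
        index=["taxA", "taxB", "taxC"])
    groups = pd.Series({"s1": "sediment", "s2": "sediment",
                        "s3": "seawater", "s4": "seawater"})
    return OtuTable(counts, groups)


@pytest.fixture(scope="session")
def neutral_table() -> OtuTable:
    return simulate_neutral_table(NeutralSimSpec(
        n_taxa=150, n_samples=60, reads_per_sample=800, migration=0.1,
        seed=11))


@pytest.fixture(scope="session")
def structured_sim():
    spec = StructuredSimSpec(seed=1)
    table, truth = simulate_structured_table(spec)
    return spec, table, truth, hub_annotations(spec), hub_taxon_ids(spec)


@pytest.fixture(scope="session")
def habitat_study():
    return two_habitat_study(seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
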