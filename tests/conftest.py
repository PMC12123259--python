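import numpy as np
import pandas as pd
import pytest

from rewirenet import dataio, pipeline, synthdata
from rewirenet.dataio import RESOURCE, TraitTable
from rewirenet.synthdata import SynthConfig


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A fast desk-scale ecosystem for unit tests."""
    return SynthConfig(seed=42, n_resource=25, n_consumer=15, grid_nx=12, grid_ny=12, n_sites=15)


@pytest.fixture(scope="session")
def small_eco(small_config):
    return synthdata.simulate(small_config)


@pytest.fixture(scope="session")
def study_config() -> SynthConfig:
    """The reference study system: 60 x 40 species, 30 sites, 20 x 20 grid."""
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def study(study_config):
    """Full pipeline run (model fit, metanetwork, capacities, map); shared
    across tests because the fit is the expensive stage."""
    return pipeline.run_study(study_config, run_cv=False)


@pytest.fixture()
def mixed_trait_table() -> TraitTable:
    data = pd.DataFrame(
        {
            "taxon_group": ["g1", "g1", "g2", "g2"],
            "size": [1.0, 3.0, 7.0, 11.0],
            "mass": [0.5, 0.7, 0.6, 1.5],
            "color": ["red", "red", "white", "yellow"],
        },
        index=pd.Index(["a", "b", "c", "d"], name="species_id"),
    )
    schema = {
        "size": {"kind": "numeric", "units": "mm"},
        "mass": {"kind": "numeric", "units": "g"},
        "color": {"kind": "categorical", "levels": ["red", "white", "yellow"]},
    }
    return TraitTable(data, RESOURCE, schema)
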