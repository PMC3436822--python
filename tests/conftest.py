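import numpy as np
import pytest

from rotaflex.pipeline import PipelineConfig
from rotaflex.rotamer import load_rotamer_library
from rotaflex.structio import ChemistryTables
from rotaflex.synthetic import SyntheticPlan, generate_pair


@pytest.fixture(scope="session")
def tables():
    return ChemistryTables.load()


@pytest.fixture(scope="session")
def library():
    return load_rotamer_library()


@pytest.fixture(scope="session")
def clean_pair():
    """A default synthetic pocket pair with no plants (all residues rigid)."""
    return generate_pair(SyntheticPlan(seed=1))


@pytest.fixture(scope="session")
def light_config():
    """Rotamer-only pipeline configuration for large ensembles."""
    return PipelineConfig(validate=False, compute_sasa=False,
                          compute_hbonds=False, compute_steric=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
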