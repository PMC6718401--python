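import numpy as np
import pytest
from hypothesis import settings

from msiburst import SimulationConfig, make_genome

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome():
    """A 200 kb annotated genome shared by read-only tests."""
    return make_genome(length=200_000, exon_fraction=0.015, n_microsatellites=30, seed=11)


@pytest.fixture()
def deficient_config():
    return SimulationConfig(regime="mmr_deficient", protocol="standard")


@pytest.fixture()
def proficient_config():
    return SimulationConfig(regime="mmr_proficient", protocol="standard")
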