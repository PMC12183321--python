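import numpy as np
import pytest

from glucopheno.io import (
    bundle_from_cohort,
    build_analysis_table,
    compute_metabolic_profiles,
)
from glucopheno.kinetics import parameters_for
from glucopheno.simulate import CohortSimulator, SimulationConfig


@pytest.fixture(scope="session")
def kinetic_params():
    return parameters_for("normal")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_participants=60, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return CohortSimulator(small_config).run()


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    return bundle_from_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_profiles(small_bundle):
    return compute_metabolic_profiles(small_bundle)


@pytest.fixture(scope="session")
def small_table(small_bundle, small_profiles):
    return build_analysis_table(small_bundle, small_profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
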