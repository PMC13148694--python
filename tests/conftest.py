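import numpy as np
import pytest

import actcalib as ac


@pytest.fixture(scope="session")
def truth():
    return ac.TruthParameters()


@pytest.fixture(scope="session")
def cohort56():
    return ac.generate_cohort(34, 22, seed=1)


@pytest.fixture(scope="session")
def obs56(cohort56, truth):
    """One 56-participant observation table at default study conditions."""
    return ac.simulate_observation_table(cohort56, truth, seed=1)


@pytest.fixture(scope="session")
def fit56(obs56):
    return ac.fit_calibration(obs56)


@pytest.fixture(scope="session")
def equations56(fit56):
    return ac.stratum_equations(fit56)


@pytest.fixture(scope="session")
def published_eqs():
    return ac.published_equations()


@pytest.fixture(scope="session")
def raw_dataset(tmp_path_factory):
    """Small raw-signal cohort dataset written to disk (4 participants)."""
    out = tmp_path_factory.mktemp("dataset")
    truth = ac.TruthParameters(seed=3)
    cohort = ac.generate_cohort(2, 2, seed=3)
    manifest = ac.write_cohort_dataset(cohort, truth, out)
    return out, cohort, truth, manifest
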