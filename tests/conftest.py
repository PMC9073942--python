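"""Shared fixtures: the expensive replica panels are session-scoped so the
end-to-end studies are simulated once and reused across tests."""

import numpy as np
import pytest

from surfvac.workflows import (
    barrier_work_study,
    double_well_fes_study,
    mechanism_study,
)

STUDY_SEED = 1


@pytest.fixture(scope="session")
def dw_study():
    """30 well-tempered replicas on the 5 kT double well + MFI reconstruction."""
    return double_well_fes_study(STUDY_SEED, n_replicas=30)


@pytest.fixture(scope="session")
def work_ladder():
    """Bias-work estimates on the 3/5/8 kT barrier ladder, 30 seeds each."""
    return barrier_work_study(STUDY_SEED, n_seeds=30)


@pytest.fixture(scope="session")
def mech_panel_default():
    return mechanism_study(STUDY_SEED, n_replicas=30, a_flip=7.0)


@pytest.fixture(scope="session")
def mech_panel_deep():
    """Same 30 seeds with the flipped basin deepened by 4 kT."""
    return mechanism_study(STUDY_SEED, n_replicas=30, a_flip=11.0)


@pytest.fixture(scope="session")
def mech_panel_shallow():
    """Same 30 seeds with the flipped basin raised by 4 kT."""
    return mechanism_study(STUDY_SEED, n_replicas=30, a_flip=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
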