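import numpy as np
import pytest

from mtshell import fixture


@pytest.fixture(scope="session")
def mt_config():
    """Orthotropic microtubule in cytoplasm with nonlocal scale (illustrative)."""
    return fixture("microtubule")


@pytest.fixture(scope="session")
def mt_groups(mt_config):
    return mt_config.groups()


@pytest.fixture(scope="session")
def iso_groups():
    """Isotropic local shell: every pencil eigenvalue is positive for the
    searched modes, so quotient lower-bound arguments apply cleanly."""
    return fixture("isotropic").groups()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
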