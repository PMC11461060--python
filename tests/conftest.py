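import numpy as np
import pytest

from paleodent import synthetic


@pytest.fixture(scope="session")
def design():
    """The default study design (locality × species structure)."""
    return synthetic.default_design(seed=0)


@pytest.fixture(scope="session")
def exact_hypoplasia(design):
    """Deterministic hypoplasia table realising the design prevalences."""
    return synthetic.gen_hypoplasia(design, exact=True)


@pytest.fixture(scope="session")
def isotropic_surface():
    return synthetic.gen_surface("isotropic_gaussian", 256, seed=2)


@pytest.fixture(scope="session")
def grooved_surface():
    return synthetic.gen_surface("sinusoid_grooves", 256, seed=1)
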