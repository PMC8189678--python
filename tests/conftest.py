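import numpy as np
import pytest

from rnakit.fixtures import HelixSpec, make_helix_chain


@pytest.fixture(scope="session")
def helix_spec() -> HelixSpec:
    """Noise-free A-form-like helix: C3'-endo pucker (P=18, nu_max=40)."""
    return HelixSpec(n_residues=6, sequence="ACGUAC")


@pytest.fixture(scope="session")
def helix_chain(helix_spec):
    return make_helix_chain(helix_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20200917)
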