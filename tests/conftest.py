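import numpy as np
import pytest

from supercharge import DesignOptions, default_model
from supercharge.fixtures import (
    FixtureSpec,
    make_bundle,
    make_hbond_motif,
    make_structure,
)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def helix16():
    """Mixed-sequence helix: candidates of every polar/charged class."""
    return make_structure(FixtureSpec("ANQEKDLSTNQRVKEA", "ideal_helix"))


@pytest.fixture(scope="session")
def helix8():
    return make_structure(FixtureSpec("ANQAKDLA", "ideal_helix"))


@pytest.fixture(scope="session")
def strand12():
    return make_structure(FixtureSpec("TNQVEDKSANQL", "ideal_strand"))


@pytest.fixture(scope="session")
def bundle():
    """Two packed helices: the only fixture with genuinely buried residues."""
    return make_bundle()


@pytest.fixture(scope="session")
def loop_motif():
    return make_hbond_motif("sidechain_to_backbone_loop")


@pytest.fixture(scope="session")
def nq_motif():
    return make_hbond_motif("NQ_donor_acceptor")


@pytest.fixture
def lys_options():
    return DesignOptions(include_lys=True)


def rigid_transform(seed: int):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(scale=15.0, size=3)
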