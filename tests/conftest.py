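import numpy as np
import pytest

from rxnpath.iohub import FixtureSpec, make_fixture
from rxnpath.potentials import Structure, UParams


@pytest.fixture(scope="session")
def double_well_bundle():
    return make_fixture(FixtureSpec("double_well"))


@pytest.fixture(scope="session")
def triatomic_bundle():
    return make_fixture(FixtureSpec("triatomic_exchange"))


@pytest.fixture(scope="session")
def pseudo_bundle():
    return make_fixture(FixtureSpec("pseudo_cycloaddition"))


@pytest.fixture(scope="session")
def chiral_bundle():
    return make_fixture(FixtureSpec("chiral_pair"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_structure(rng, natoms=5, min_sep=0.8):
    """A random non-clashing carbon cluster."""
    while True:
        coords = rng.uniform(-2.5, 2.5, size=(natoms, 3))
        s = Structure(["C"] * natoms, coords)
        if s.min_distance() > min_sep:
            return s


@pytest.fixture()
def uparams():
    return UParams()
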