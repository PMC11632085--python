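import numpy as np
import pytest

from boostcd.constants import HC_EV_NM
from boostcd.orientations import sample_orientations
from boostcd.synthetic import preset_polarizabilities
from boostcd.tmatrix import build_tmatrix_stack


@pytest.fixture(scope="session")
def chiral_single_pol():
    return preset_polarizabilities("chiral-single")


@pytest.fixture(scope="session")
def chiral_single_stack(chiral_single_pol):
    return build_tmatrix_stack(chiral_single_pol)


@pytest.fixture(scope="session")
def achiral_iso_stack():
    return build_tmatrix_stack(preset_polarizabilities("achiral-iso"))


@pytest.fixture(scope="session")
def orientations_50():
    return sample_orientations(50, seed=11)


@pytest.fixture(scope="session")
def lab_wavelengths_rest(chiral_single_pol):
    """Rest-frame grid wavelengths (nm) of the chiral-single preset."""
    return HC_EV_NM / chiral_single_pol.energies


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_polarizability_tensors(rng, n=4, scale=1e-40):
    """Random complex tensor stacks on a small increasing grid."""
    energies = np.linspace(2.0, 3.0, n)

    def block():
        return scale * (
            rng.standard_normal((n, 3, 3)) + 1j * rng.standard_normal((n, 3, 3))
        )

    return energies, block(), block(), block(), block()
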