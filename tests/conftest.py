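import numpy as np
import pytest

from pippes import Geometry, PesModel, enumerate_pip_basis, parse_symmetry
from pippes.symmetry import build_pair_group
from pippes.synthetic import MorseSumPotential, sample_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def basis_a3():
    return enumerate_pip_basis("A3", 3)


@pytest.fixture(scope="session")
def basis_a5b2_order3():
    return enumerate_pip_basis("A5B2", 3)


@pytest.fixture(scope="session")
def group_a5b2():
    return build_pair_group(parse_symmetry("A5B2"))


@pytest.fixture
def model_a3(basis_a3):
    """Random-coefficient A3 PES model (smooth, fully invariant)."""
    c = np.random.default_rng(7).normal(size=basis_a3.size)
    return PesModel(basis=basis_a3, coefficients=c)


@pytest.fixture
def model_a5b2(basis_a5b2_order3):
    c = np.random.default_rng(11).normal(size=basis_a5b2_order3.size)
    return PesModel(basis=basis_a5b2_order3, coefficients=c)


def random_geometry(sym, rng, spread=2.0, offset=3.0):
    """Well-separated random geometry matching a symmetry's class layout."""
    if isinstance(sym, str):
        sym = parse_symmetry(sym)
    elements = []
    for label, cnt in zip(("H", "O", "C"), [c for _, c in sym.classes]):
        elements.extend([label] * cnt)
    coords = rng.normal(scale=spread, size=(sym.n_atoms, 3))
    coords += offset * np.arange(sym.n_atoms)[:, None] * np.eye(3)[0]
    return Geometry(elements=elements, coords=coords)


@pytest.fixture(scope="session")
def morse_a2b1():
    """Water-like triatomic Morse-sum toy potential."""
    return MorseSumPotential(
        "A2B1", params={"AA": (0.02, 1.0, 2.8), "AB": (0.18, 1.2, 1.8)}
    )


@pytest.fixture(scope="session")
def dataset_a2b1(morse_a2b1):
    return sample_dataset(morse_a2b1, 400, 60000.0, seed=3)


@pytest.fixture(scope="session")
def morse_diatomic():
    """Single-pair Morse potential: De = 0.1 Eh, a = 1 1/bohr, re = 2 bohr."""
    return MorseSumPotential("A1B1", params={"AB": (0.1, 1.0, 2.0)},
                             elements=("H", "O"))
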