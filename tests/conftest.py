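import numpy as np
import pytest

from gyrmotion.structure_io import Atom, Structure
from gyrmotion.synthetic_data import (
    DimerSpec,
    Motion,
    SyntheticSpec,
    make_dimer_fixture,
    make_toy_site,
    make_two_domain_structure,
)


def rand_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def single_atom_structure(element="C", coord=(0.0, 0.0, 0.0)) -> Structure:
    return Structure(
        "single",
        [Atom("A", 1, "UNK", element, element, np.array(coord, float), is_hetero=True)],
    )


@pytest.fixture(scope="session")
def toy_site():
    return make_toy_site()


@pytest.fixture(scope="session")
def two_domain_clean():
    """Noise-free 12-degree motion pair with ground truth."""
    spec = SyntheticSpec(seed=42, motion=Motion(kappa_deg=12.0))
    return make_two_domain_structure(spec)


@pytest.fixture(scope="session")
def exact_dimer():
    spec = SyntheticSpec(seed=7, dimer=DimerSpec())
    return make_dimer_fixture(spec)


@pytest.fixture(scope="session")
def cell_dimer_offset():
    """Dimer whose dyad is shifted +0.04 fractional off the x = 1/4 position."""
    spec = SyntheticSpec(
        seed=11,
        cell=(80.0, 130.0, 90.0, 90.0, 90.0, 90.0),
        space_group="P 21 21 2",
        dimer=DimerSpec(frac_offset_x=0.04),
    )
    return make_dimer_fixture(spec)
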