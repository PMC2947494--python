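import numpy as np
import pytest

import memslab as m
from memslab.structure import Atom, Structure


@pytest.fixture(scope="session")
def helix() -> Structure:
    """The ideal 27-residue transmembrane helix (Arg at position 14)."""
    return m.build_helix()


@pytest.fixture
def single_ion() -> Structure:
    """A +1 e potassium-like ion of radius 2 Å at the origin."""
    return Structure([Atom(1, "K", "ION", 1, np.zeros(3), 1.0, 2.0)], label="K+")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20181218)


def random_structure(rng: np.random.Generator, n: int, box: float = 20.0) -> Structure:
    atoms = [
        Atom(
            serial=i + 1,
            name=f"A{i%9}",
            residue_name="RES",
            residue_number=i // 4 + 1,
            position=rng.uniform(-box / 2, box / 2, 3),
            charge=float(np.round(rng.uniform(-1, 1), 4)),
            radius=float(np.round(rng.uniform(0.5, 2.5), 4)),
        )
        for i in range(n)
    ]
    return Structure(atoms, label="random")
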