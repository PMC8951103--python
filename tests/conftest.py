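import numpy as np
import pytest

from fragshare.complex_io import Atom, Molecule
from fragshare.fixtures import FixtureSpec, make_toy_complex
from fragshare.scoring import get_builtin_params


@pytest.fixture(scope="session")
def vina_params():
    return get_builtin_params("builtin_vina")


@pytest.fixture(scope="session")
def vinardo_params():
    return get_builtin_params("builtin_vinardo")


@pytest.fixture()
def toy():
    """Default 8-carbon / 2-fragment / 4-probe toy complex with oracle scores."""
    geometry, scheme, expected = make_toy_complex(FixtureSpec())
    return geometry, scheme, expected


def chain_molecule(n=6, spacing=1.54, element="C", chain_id="L"):
    """Bare carbon chain along x with explicit bonds."""
    atoms = [
        Atom(serial=i + 1, name=f"{element}{i+1}", element=element,
             coords=np.array([i * spacing, 0.0, 0.0]), record="HETATM",
             res_name="LIG", res_seq=1, chain_id=chain_id)
        for i in range(n)
    ]
    bonds = [(i, i + 1, 1) for i in range(n - 1)]
    return Molecule(atoms=atoms, bonds=bonds, provenance="test chain")
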