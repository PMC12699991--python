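import numpy as np
import pytest

from vinascreen.formats import Atom, Bond, Molecule


def make_atom(element, x=0.0, y=0.0, z=0.0, serial=1, name=None, **kw):
    return Atom(
        serial=serial, name=name or f"{element}{serial}", residue_name="LIG",
        chain="A", residue_number=1, x=x, y=y, z=z, element=element, **kw,
    )


def alkane(n_carbons):
    """Explicit-hydrogen n-alkane with schematic geometry."""
    atoms = [make_atom("C", x=1.5 * k, serial=k + 1) for k in range(n_carbons)]
    bonds = [Bond(k - 1, k, 1) for k in range(1, n_carbons)]
    h = 0
    for k in range(n_carbons):
        n_heavy = (k > 0) + (k < n_carbons - 1)
        for j in range(4 - n_heavy):
            h += 1
            atoms.append(make_atom("H", x=1.5 * k + 0.3 * j, y=1.0 + 0.1 * j,
                                   serial=n_carbons + h))
            bonds.append(Bond(k, len(atoms) - 1, 1))
    return Molecule(atoms=atoms, bonds=bonds, name=f"alkane{n_carbons}")


def ethanol():
    """CH3-CH2-OH with explicit hydrogens (atom order: C, C, O, then Hs)."""
    atoms = [
        make_atom("C", 0.0, serial=1), make_atom("C", 1.5, serial=2),
        make_atom("O", 2.9, serial=3),
    ]
    bonds = [Bond(0, 1, 1), Bond(1, 2, 1)]
    coords = [(0.0, 1.0), (-0.5, -0.9), (0.5, -0.9), (1.5, 1.0), (2.0, -0.9), (3.4, 0.9)]
    parents = [0, 0, 0, 1, 1, 2]
    for k, (dx, dy) in enumerate(coords):
        atoms.append(make_atom("H", x=atoms[parents[k]].x + dx * 0.3, y=dy,
                               serial=4 + k))
        bonds.append(Bond(parents[k], len(atoms) - 1, 1))
    return Molecule(atoms=atoms, bonds=bonds, name="ethanol")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ethanol_molecule():
    return ethanol()


@pytest.fixture
def butane_molecule():
    return alkane(4)
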