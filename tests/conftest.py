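import numpy as np
import pytest

from cidock.molecules import Molecule
from cidock.synthgen import make_toy_ligand


@pytest.fixture
def chain_ligand() -> Molecule:
    """8-heavy-atom asymmetric chain (trivial automorphism group)."""
    return make_toy_ligand(8, with_symmetry=False, seed=3)


@pytest.fixture
def benzene() -> Molecule:
    """Ideal aromatic six-ring: automorphism group of order 12."""
    coords = np.array([[1.39 * np.cos(np.pi * i / 3), 1.39 * np.sin(np.pi * i / 3), 0.0]
                       for i in range(6)])
    bonds = [(i, (i + 1) % 6, "ar") for i in range(6)]
    return Molecule("benzene", ["C"] * 6, coords, bonds)


def permute_molecule(mol: Molecule, perm: list[int]) -> Molecule:
    """Reorder atoms by ``perm`` (new index k holds old atom perm[k])."""
    inv = {old: new for new, old in enumerate(perm)}
    return Molecule(mol.name, [mol.elements[p] for p in perm], mol.coords[perm],
                    [(inv[i], inv[j], o) for i, j, o in mol.bonds],
                    [mol.charges[p] for p in perm], mol.is_receptor)
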