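"""Shared fixtures: synthetic scaffolds and small toy complexes."""

import numpy as np
import pytest
import biotite.structure as struc

from protomerscope import ScaffoldSpec, make_dimer, make_protomer
from protomerscope.structure import set_coordinates64, structure_from_atoms


@pytest.fixture
def holo_spec():
    """Dimer-compatible holo regime: αC-in, formed salt bridge, DFG-out,
    stable ligand–Glu501 h-bond."""
    return ScaffoldSpec(
        alpha_c_position=18.3, ke_distance=2.8, dfg_dihedral=290.0,
        ligand_glu501_distance=2.9,
    )


@pytest.fixture
def holo_protomer(holo_spec):
    return make_protomer(holo_spec)


@pytest.fixture
def symmetric_dimer(holo_spec):
    return make_dimer(holo_spec, holo_spec)


def toy_structure(protein_atoms, ligand_atoms=(), chain="A"):
    """Build a KinaseStructure from explicit atom tuples.

    protein_atoms: (res_id, res_name, atom_name, element, xyz)
    ligand_atoms: same, flagged HETATM (resname defaults to entry's res_name).
    """
    records = [(*a, False) for a in protein_atoms] + [(*a, True) for a in ligand_atoms]
    n = len(records)
    atoms = struc.AtomArray(n)
    atoms.chain_id = np.array([chain] * n)
    atoms.res_id = np.array([r[0] for r in records])
    atoms.res_name = np.array([r[1] for r in records])
    atoms.atom_name = np.array([r[2] for r in records])
    atoms.element = np.array([r[3] for r in records])
    atoms.hetero = np.array([r[5] for r in records])
    set_coordinates64(atoms, np.array([r[4] for r in records], dtype=float))
    return structure_from_atoms(atoms, source="synthetic:toy")


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
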