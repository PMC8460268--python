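import numpy as np
import pytest

from coaclash.structure_io import AtomRecord, StructureModel
from coaclash.synthetic_data import (
    make_cavity_fixture,
    make_hinge_fixture,
    make_toy_coa,
    make_tunnel_fixture,
)

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def make_chain(sequence, res_start=1, chain="A", origin=(0.0, 0.0, 0.0),
               full_backbone=False, structure_id="toy_chain"):
    """A synthetic chain with one Cα per residue laid along +x (3.8 Å rise),
    optionally with the full N/CA/C/O backbone and a CB for non-glycine."""
    atoms = []
    serial = 1
    ox, oy, oz = origin
    for i, letter in enumerate(sequence):
        res_name = _AA3[letter]
        res_seq = res_start + i
        x = ox + 3.8 * i
        positions = [("CA", "C", (x, oy, oz))]
        if full_backbone:
            positions = [
                ("N", "N", (x - 0.9, oy + 0.8, oz)),
                ("CA", "C", (x, oy, oz)),
                ("C", "C", (x + 1.0, oy + 0.6, oz)),
                ("O", "O", (x + 1.0, oy + 1.8, oz)),
            ]
            if letter != "G":
                positions.append(("CB", "C", (x, oy - 1.4, oz + 0.6)))
        for name, element, xyz in positions:
            atoms.append(
                AtomRecord(serial, name, element, res_name, res_seq, chain,
                           np.array(xyz, dtype=float))
            )
            serial += 1
    return StructureModel(structure_id, atoms)


@pytest.fixture(scope="session")
def toy_split():
    return make_toy_coa()


@pytest.fixture(scope="session")
def tunnel():
    return make_tunnel_fixture(seed=0)


@pytest.fixture(scope="session")
def hinge():
    return make_hinge_fixture(n_atoms=60, hinge_angle=30.0, seed=0)


@pytest.fixture(scope="session")
def sphere_cavity():
    return make_cavity_fixture("sphere", inner_radius=6.0, seed=0)


@pytest.fixture(scope="session")
def cylinder_cavity():
    return make_cavity_fixture("cylinder", inner_radius=4.0, length=18.0, seed=0)
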