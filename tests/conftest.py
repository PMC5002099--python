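import numpy as np
import pytest

from varstruct.structlib import (
    AtomRecord,
    ChainModel,
    Residue,
    ResidueID,
    Structure,
)


def make_atom(serial, name, element, xyz, occupancy=1.0):
    return AtomRecord(serial, name, element, "", np.asarray(xyz, float), occupancy)


def single_atom_structure(element="C", xyz=(0.0, 0.0, 0.0)):
    res = Residue(ResidueID("A", 1), "ALA", [make_atom(1, "C1", element, xyz)], "A")
    return Structure({"A": ChainModel("A", "A", [res])})


def atoms_structure(spec):
    """Build a structure from [(res_seq, name, element, xyz), ...]; one chain."""
    by_res: dict[int, Residue] = {}
    serial = 0
    for res_seq, name, element, xyz in spec:
        serial += 1
        res = by_res.setdefault(
            res_seq, Residue(ResidueID("A", res_seq), "UNK", [], "X")
        )
        res.atoms.append(make_atom(serial, name, element, xyz))
    residues = [by_res[k] for k in sorted(by_res)]
    return Structure({"A": ChainModel("A", "X" * len(residues), residues)})


@pytest.fixture(scope="session")
def helix12():
    from varstruct.fixtures import make_helix_structure

    return make_helix_structure("ACDEFGHIKLMN")


@pytest.fixture(scope="session")
def polyala_helix():
    from varstruct.fixtures import make_helix_structure

    return make_helix_structure("AAAAAAAAAAAA")


@pytest.fixture(scope="session")
def packed_pair():
    """Two parallel poly-Ala helices; wild-type interface is clash-free, a
    larger side chain at A8 is not."""
    from varstruct.fixtures import make_helix_pair_structure

    return make_helix_pair_structure("A" * 14, "A" * 14, separation=9.0)
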