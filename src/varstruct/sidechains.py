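"""Side-chain geometry templates and a compact rotamer library.

Each residue type is described by an ordered list of internal-coordinate
records ``(atom, A, B, C, bond, angle, torsion)``: the atom is placed at the
stated bond length from C, bond angle B-C-A(tom) and torsion A-B-C-atom
(NeRF construction; every reference atom precedes the placed atom).  The
torsion is either a fixed value in degrees or ``("chi", k, offset)`` meaning
chi_k + offset -- branch atoms (e.g. Val CG2) ride on the same chi as their
sibling with a fixed offset.  CB is special-cased: it is placed from N, CA,
C with ideal tetrahedral L-amino-acid geometry.

Bond lengths and angles are ideal-geometry values (Engh/Huber-style).  Ring
closure for His/Phe/Tyr/Trp and the proline ring is approximate: rings are
built atom-by-atom with fixed torsions, which reproduces planar rings well
but does not enforce exact closure; proline mutations always carry a
warning.

The rotamer library is deliberately compact and backbone-independent: every
chi draws from the canonical gauche-/trans/gauche+ wells (-60, 180, +60),
the classic staggered minima.  Real rotamer engines use far richer,
backbone-dependent statistics; this library is sufficient for steric-choice
modelling on a fixed backbone but is documented as reduced-fidelity.
"""

from __future__ import annotations

from itertools import product

Chi = tuple  # ("chi", k, offset_deg)


def chi(k: int, offset: float = 0.0) -> Chi:
    return ("chi", k, offset)


#: residue -> ordered internal-coordinate records for side-chain atoms past CB.
#: record: (atom, A, B, C, bond_len, bond_angle, torsion)
SIDE_CHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, chi(1))],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.8, chi(1))],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.433, 109.6, chi(1)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, chi(1, -120.0)),
    ],
    "VAL": [
        ("CG1", "N", "CA", "CB", 1.521, 110.5, chi(1)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, chi(1, 120.0)),
    ],
    "ILE": [
        ("CG1", "N", "CA", "CB", 1.530, 110.4, chi(1)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, chi(1, -120.0)),
        ("CD1", "CA", "CB", "CG1", 1.513, 113.9, chi(2)),
    ],
    "LEU": [
        ("CG", "N", "CA", "CB", 1.530, 116.3, chi(1)),
        ("CD1", "CA", "CB", "CG", 1.521, 110.7, chi(2)),
        ("CD2", "CA", "CB", "CG", 1.521, 110.7, chi(2, 120.0)),
    ],
    "PRO": [
        ("CG", "N", "CA", "CB", 1.492, 104.5, chi(1)),
        ("CD", "CA", "CB", "CG", 1.503, 106.1, chi(2)),
    ],
    "MET": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, chi(1)),
        ("SD", "CA", "CB", "CG", 1.803, 112.7, chi(2)),
        ("CE", "CB", "CG", "SD", 1.791, 100.9, chi(3)),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, chi(1)),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, chi(2)),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, chi(2, 180.0)),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, chi(1)),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, chi(2)),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, chi(2, 180.0)),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, chi(1)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, chi(2)),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, chi(3)),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, chi(3, 180.0)),
    ],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, chi(1)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, chi(2)),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, chi(3)),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, chi(3, 180.0)),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, chi(1)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, chi(2)),
        ("CE", "CB", "CG", "CD", 1.520, 111.3, chi(3)),
        ("NZ", "CG", "CD", "CE", 1.489, 111.9, chi(4)),
    ],
    "ARG": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, chi(1)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, chi(2)),
        ("NE", "CB", "CG", "CD", 1.461, 112.0, chi(3)),
        ("CZ", "CG", "CD", "NE", 1.329, 124.2, chi(4)),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", "N", "CA", "CB", 1.497, 113.8, chi(1)),
        ("ND1", "CA", "CB", "CG", 1.378, 122.7, chi(2)),
        ("CD2", "CA", "CB", "CG", 1.356, 131.1, chi(2, 180.0)),
        ("CE1", "CB", "CG", "ND1", 1.321, 109.2, 180.0),
        ("NE2", "CB", "CG", "CD2", 1.374, 107.2, 180.0),
    ],
    "PHE": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, chi(1)),
        ("CD1", "CA", "CB", "CG", 1.384, 120.7, chi(2)),
        ("CD2", "CA", "CB", "CG", 1.384, 120.7, chi(2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.382, 120.7, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 120.7, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "N", "CA", "CB", 1.512, 113.9, chi(1)),
        ("CD1", "CA", "CB", "CG", 1.389, 120.8, chi(2)),
        ("CD2", "CA", "CB", "CG", 1.389, 120.8, chi(2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.382, 121.2, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.382, 121.2, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.378, 119.6, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", "N", "CA", "CB", 1.498, 113.6, chi(1)),
        ("CD1", "CA", "CB", "CG", 1.365, 126.9, chi(2)),
        ("CD2", "CA", "CB", "CG", 1.433, 126.6, chi(2, 180.0)),
        ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
        ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
        ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
        ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
        ("CH2", "CE2", "CZ2", "CZ3", 1.368, 121.5, 0.0),
    ],
}

def _chi_count(records: list[tuple]) -> int:
    ks = [r[6][1] for r in records if isinstance(r[6], tuple) and r[6][0] == "chi"]
    return max(ks, default=0)


#: number of variable chi angles per residue type
CHI_COUNTS: dict[str, int] = {
    name: _chi_count(recs) for name, recs in SIDE_CHAIN_TEMPLATES.items()
}


def element_of(atom_name: str) -> str:
    """Element symbol from a (heavy) atom name, e.g. 'OG1' -> 'O'."""
    return atom_name.strip()[0]


def atom_depths(aa: str) -> dict[str, int]:
    """Covalent bond count from CA to each side-chain atom (CB = 1).

    Template records name their bonded parent (the third reference atom), so
    depths follow directly; ring-closure bonds (aromatics, proline) are not
    shortcuts here -- proline's N-CD bond is handled by the caller.
    """
    depth = {"CB": 1}
    for rec in SIDE_CHAIN_TEMPLATES[aa.upper()]:
        depth[rec[0]] = depth[rec[3]] + 1
    return depth


_STAGGERED = (-60.0, 180.0, 60.0)


def default_rotamer_library() -> dict[str, list[tuple[float, ...]]]:
    """Backbone-independent rotamers: staggered wells for every chi.

    Proline gets its two approximate ring puckers instead of free chis.
    """
    lib: dict[str, list[tuple[float, ...]]] = {}
    for name in SIDE_CHAIN_TEMPLATES:
        if name == "PRO":
            lib[name] = [(25.0, -35.0), (-25.0, 35.0)]
            continue
        n_chi = CHI_COUNTS[name]
        if n_chi == 0:
            lib[name] = [()]
        else:
            lib[name] = [tuple(c) for c in product(_STAGGERED, repeat=n_chi)]
    return lib
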