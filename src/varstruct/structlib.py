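"""PDB structures and the SEQRES-index -> ATOM-residue numbering map.

A crystal structure's SEQRES record lists the full polymer sequence while the
ATOM records only cover residues with resolved coordinates, numbered by the
author in a scheme that need not be sequential, positive, or gap-free.
Mapping a sequence position onto the coordinates therefore requires aligning
the SEQRES sequence against the sequence of resolved residues; SEQRES indices
with no coordinates are *unresolved* (disordered loops, missing domains).

Parsing is delegated to :mod:`gemmi`; this module exposes a small residue/atom
model tailored to the downstream contact and mutation analyses.  Only the
first MODEL of multi-model files is used; waters and non-polymer HETATM
groups are excluded from chains; altloc groups are collapsed to the highest
occupancy conformer (ties broken alphabetically); MSE and other MODRES-listed
residues map to their standard parent in the one-letter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import (
    EmptyStructureError,
    MappingFailureError,
    ParseError,
    RangeError,
)


class _Unresolved:
    """Singleton marker for a SEQRES index with no coordinates."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNRESOLVED"

    def __bool__(self):
        return False


UNRESOLVED = _Unresolved()

#: three-letter -> one-letter for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True, order=True)
class ResidueID:
    """Author residue identifier: chain, residue number, insertion code."""

    chain: str
    res_seq: int
    icode: str = ""

    def __str__(self):
        return f"{self.chain}{self.res_seq}{self.icode}".strip()


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    altloc: str
    xyz: np.ndarray
    occupancy: float = 1.0
    is_hydrogen: bool = False

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ParseError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    rid: ResidueID
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    one_letter: str = "X"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class ChainModel:
    chain_id: str
    seqres: str  # one-letter, X for unmapped nonstandard residues
    residues: list[Residue] = field(default_factory=list)  # resolved, file order

    def resolved_sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Structure:
    chains: dict[str, ChainModel] = field(default_factory=dict)
    name: str = ""

    def iter_residues(self):
        for ch in self.chains.values():
            yield from ch.residues

    def iter_atoms(self):
        for res in self.iter_residues():
            for a in res.atoms:
                yield res, a

    def get_residue(self, rid: ResidueID) -> Residue | None:
        ch = self.chains.get(rid.chain)
        if ch is None:
            return None
        for r in ch.residues:
            if r.rid == rid:
                return r
        return None


def _one_letter(res_name: str, modres: dict[str, str]) -> str:
    """One-letter code for a residue name, resolving MODRES parents; X if unknown."""
    name = res_name.upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    if name in modres:
        return THREE_TO_ONE.get(modres[name], "X")
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        code = info.one_letter_code.upper()
        if code.strip() and code in ONE_TO_THREE:
            return code
    return "X"


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, tie -> first altloc."""
    by_name: dict[str, AtomRecord] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, _neg_altloc(a.altloc)) > (prev.occupancy, _neg_altloc(prev.altloc)):
            by_name[a.name] = a
    return list(by_name.values())


def _neg_altloc(altloc: str):
    # sort key so that among equal occupancies the alphabetically first wins
    return tuple(-ord(c) for c in (altloc or "~"))


def parse_structure(pdb_text: str, name: str = "") -> Structure:
    """Parse PDB v3.3 fixed-column text into a :class:`Structure`.

    Waters and non-polymer HETATM groups are dropped; hydrogens are retained
    but flagged; altloc groups are collapsed (highest occupancy, tie ->
    alphabetically first); the first MODEL only.
    """
    modres: dict[str, str] = {}
    for ln, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith("MODRES"):
            try:
                modres[line[12:15].strip().upper()] = line[24:27].strip().upper()
            except Exception as exc:  # pragma: no cover - fixed slicing rarely fails
                raise ParseError(f"bad MODRES record: {exc}", line=ln) from exc
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(str(exc)) from exc
    seqres_by_chain: dict[str, list[str]] = {
        e.name: list(e.full_sequence) for e in st.entities if e.full_sequence
    }
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError("no coordinate records found")
    model = st[0]
    out = Structure(name=name or st.name)
    n_atoms = 0
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.entity_type != gemmi.EntityType.Polymer:
                continue
            if res.name == "HOH":
                continue
            one = _one_letter(res.name, modres)
            if not (res.het_flag == "A" or one != "X" or res.name.upper() in modres):
                # non-polymeric/unknown HETATM ligand that slipped through
                continue
            atoms = [
                AtomRecord(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name.upper(),
                    altloc="" if a.altloc in ("", "\x00", " ") else a.altloc,
                    xyz=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    is_hydrogen=a.element.is_hydrogen,
                )
                for a in res
            ]
            atoms = _collapse_altlocs(atoms)
            rid = ResidueID(ch.name, res.seqid.num, (res.seqid.icode or "").strip())
            residues.append(Residue(rid, res.name.upper(), atoms, one))
            n_atoms += len(atoms)
        if not residues:
            continue
        names = seqres_by_chain.get(ch.name)
        if names:
            seqres = "".join(_one_letter(nm, modres) for nm in names)
        else:
            # no SEQRES record: fall back to the resolved sequence
            seqres = "".join(r.one_letter for r in residues)
        out.chains[ch.name] = ChainModel(ch.name, seqres, residues)
    if n_atoms == 0:
        raise EmptyStructureError("no ATOM records for polymer residues")
    return out


# ---------------------------------------------------------------------------
# SEQRES <-> ATOM mapping
# ---------------------------------------------------------------------------

@dataclass
class SeqresAtomMap:
    """Per-chain map from 1-based SEQRES index to author ResidueID.

    ``entries[i-1]`` is the ResidueID resolved for SEQRES position ``i`` or
    the :data:`UNRESOLVED` marker.  ``n_mismatches`` counts aligned columns
    whose one-letter codes disagree (tolerated up to the mismatch budget).
    """

    chain_id: str
    entries: list  # ResidueID | UNRESOLVED, length == len(seqres)
    n_mismatches: int = 0

    def __len__(self):
        return len(self.entries)

    def resolved_ids(self):
        return [e for e in self.entries if e is not UNRESOLVED]

    def reverse(self) -> dict[ResidueID, int]:
        """ResidueID -> 1-based SEQRES index."""
        return {
            e: i + 1 for i, e in enumerate(self.entries) if e is not UNRESOLVED
        }


def _mapping_aligner() -> PairwiseAligner:
    """Global aligner: match +1, mismatch -10, gap -1; X matches anything at 0."""
    letters = "ACDEFGHIKLMNPQRSTVWYX"
    mat = substitution_matrices.Array(alphabet=letters, dims=2)
    for a in letters:
        for b in letters:
            if a == "X" or b == "X":
                mat[a, b] = 0.0
            elif a == b:
                mat[a, b] = 1.0
            else:
                mat[a, b] = -10.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def build_seqres_atom_map(
    chain: ChainModel, mismatch_budget: float = 0.05
) -> SeqresAtomMap:
    """Align the SEQRES sequence against the resolved-residue sequence.

    Gaps are strongly preferred over mismatches, so numbering gaps (missing
    loops, truncated termini) become UNRESOLVED stretches while the resolved
    residues keep their file order.  More than ``mismatch_budget`` mismatched
    aligned columns raises :class:`MappingFailureError`.
    """
    if not chain.seqres or not chain.residues:
        raise MappingFailureError(
            f"chain {chain.chain_id}: empty SEQRES or no resolved residues"
        )
    resolved = chain.resolved_sequence()
    aligner = _mapping_aligner()
    aln = aligner.align(chain.seqres, resolved)[0]
    entries: list = [UNRESOLVED] * len(chain.seqres)
    n_aligned = 0
    n_mismatch = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for k in range(qe - qs):
            si, ri = qs + k, ss + k
            entries[si] = chain.residues[ri].rid
            n_aligned += 1
            a, b = chain.seqres[si], resolved[ri]
            if a != b and a != "X" and b != "X":
                n_mismatch += 1
    if n_aligned < len(resolved):
        raise MappingFailureError(
            f"chain {chain.chain_id}: {len(resolved) - n_aligned} resolved residues "
            "could not be assigned a SEQRES position"
        )
    if n_aligned and n_mismatch / n_aligned > mismatch_budget:
        raise MappingFailureError(
            f"chain {chain.chain_id}: {n_mismatch}/{n_aligned} aligned columns mismatch "
            f"(budget {mismatch_budget:.0%})"
        )
    return SeqresAtomMap(chain.chain_id, entries, n_mismatch)


def resolve_seqres_index(smap: SeqresAtomMap, idx: int):
    """ResidueID at 1-based SEQRES index ``idx``; UNRESOLVED is a value."""
    if not 1 <= idx <= len(smap.entries):
        raise RangeError(f"SEQRES index {idx} outside 1..{len(smap.entries)}")
    return smap.entries[idx - 1]


# ---------------------------------------------------------------------------
# PDB output (for mutant models and fixtures)
# ---------------------------------------------------------------------------

def write_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` back to PDB text (SEQRES + ATOM + TER)."""
    lines: list[str] = []
    for ch in structure.chains.values():
        names = [ONE_TO_THREE.get(c, "UNK") for c in ch.seqres]
        for i in range(0, len(names), 13):
            chunk = names[i : i + 13]
            lines.append(
                f"SEQRES {i // 13 + 1:3d} {ch.chain_id:1s} {len(names):4d}  "
                + " ".join(f"{n:>3s}" for n in chunk)
            )
    serial = 0
    for ch in structure.chains.values():
        for res in ch.residues:
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.xyz
                lines.append(
                    f"ATOM  {serial:5d} {name}{a.altloc or ' '}{res.res_name:>3s} "
                    f"{ch.chain_id:1s}{res.rid.res_seq:4d}{res.rid.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
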