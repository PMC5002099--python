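"""Fixed-backbone side-chain replacement with a rotamer library.

The mutant side chain is rebuilt from ideal internal coordinates
(:mod:`varstruct.sidechains`) for every rotamer in the library; each
candidate is scored by a soft steric-overlap penalty against the rest of the
structure and the lowest-scoring rotamer wins (ties -> lowest rotamer
index).  The backbone never moves -- a deliberate mirror of fixed-backbone
side-chain engines, with the same caveat: when the substitution forces
backbone rearrangement (typically a larger side chain in the core) the model
is strained, and the resulting clashes are reported rather than relaxed
away.

Proline is special: its ring is closed through the backbone nitrogen, which
a chi-based construction only approximates, so any mutation from or to
proline attaches a warning to the result.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import (
    ClashRecord,
    RadiiTable,
    bonded_within,
    detect_clashes,
    infer_bonds,
)
from .errors import IncompleteBackboneError, UnknownResidueError, VarstructError
from .geometry import place_atom, place_cb
from .sidechains import (
    CHI_COUNTS,
    SIDE_CHAIN_TEMPLATES,
    atom_depths,
    default_rotamer_library,
    element_of,
)
from .structlib import (
    ONE_TO_THREE,
    AtomRecord,
    Residue,
    ResidueID,
    Structure,
    build_seqres_atom_map,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def build_side_chain(
    backbone: dict[str, np.ndarray],
    aa_type: str,
    chi_tuple: tuple[float, ...],
    templates: dict[str, list[tuple]] | None = None,
) -> list[tuple[str, str, np.ndarray]]:
    """Construct side-chain atom coordinates (CB onward) on a fixed backbone.

    ``backbone`` must contain N, CA and C.  Returns ``(name, element, xyz)``
    records; empty for glycine.  The chi tuple length must match the
    residue's chi count.
    """
    templates = templates or SIDE_CHAIN_TEMPLATES
    aa = aa_type.upper()
    if aa not in templates:
        raise UnknownResidueError(f"no side-chain template for {aa_type!r}")
    for req in ("N", "CA", "C"):
        if req not in backbone:
            raise IncompleteBackboneError(f"backbone atom {req} missing")
    n_chi = CHI_COUNTS[aa]
    if len(chi_tuple) != n_chi:
        raise VarstructError(
            f"{aa} needs {n_chi} chi angles, got {len(chi_tuple)}"
        )
    if aa == "GLY":
        return []
    pos: dict[str, np.ndarray] = {
        "N": np.asarray(backbone["N"], float),
        "CA": np.asarray(backbone["CA"], float),
        "C": np.asarray(backbone["C"], float),
    }
    out: list[tuple[str, str, np.ndarray]] = []
    cb = place_cb(pos["N"], pos["CA"], pos["C"])
    pos["CB"] = cb
    out.append(("CB", "C", cb))
    for name, a, b, c, bond, angle, tor in templates[aa]:
        if isinstance(tor, tuple) and tor[0] == "chi":
            torsion = chi_tuple[tor[1] - 1] + tor[2]
        else:
            torsion = float(tor)
        xyz = place_atom(pos[a], pos[b], pos[c], bond, angle, torsion)
        pos[name] = xyz
        out.append((name, element_of(name), xyz))
    return out


class StericEnvironment:
    """Precomputed environment for scoring candidate side chains at one site.

    The environment is every heavy atom of the structure except the target
    residue's own side chain (its backbone N/CA/C/O stay in).  Exclusion of
    covalently close pairs uses exact template bond depths: a candidate atom
    at depth ``d`` from CA is within three bonds of exactly the environment
    atoms within ``3 - d`` bonds of the target CA (plus, for proline, atoms
    near the backbone N through the ring's N-CD bond).
    """

    def __init__(
        self,
        structure: Structure,
        target: ResidueID,
        aa3: str,
        radii: RadiiTable | None = None,
    ):
        self.radii = radii or RadiiTable()
        self.target = target
        res = structure.get_residue(target)
        if res is None:
            raise UnknownResidueError(f"residue {target} not in structure")
        env = []
        for r, a in structure.iter_atoms():
            if a.is_hydrogen:
                continue
            if r.rid == target and a.name not in BACKBONE_ATOMS:
                continue  # old side chain of the mutated residue
            env.append(((r.rid, a.name), a))
        self.keys = [k for k, _a in env]
        self.coords = np.array([a.xyz for _k, a in env])
        self.vdw = np.array([self.radii.vdw(a.element) for _k, a in env])
        graph = infer_bonds(structure)
        self.depths = atom_depths(aa3)
        self._near_ca = {
            k: self._index_set(bonded_within(graph, (target, "CA"), k))
            for k in (0, 1, 2)
        }
        self._near_n = {
            k: self._index_set(bonded_within(graph, (target, "N"), k))
            for k in (0, 1, 2)
        }
        self.is_pro = aa3.upper() == "PRO"

    def _index_set(self, keyset) -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self.keys) if k in keyset], dtype=int
        )

    def excluded_indices(self, atom_name: str) -> np.ndarray:
        d = self.depths.get(atom_name, 99)
        idx = self._near_ca[3 - d] if d <= 3 else np.empty(0, dtype=int)
        if self.is_pro:
            # ring closure CD-N: depth to N through the ring
            dn = {"CD": 1, "CG": 2, "CB": 3}.get(atom_name)
            if dn is not None and dn <= 3:
                idx = np.union1d(idx, self._near_n[3 - dn])
        return idx


def steric_score(
    structure: Structure,
    candidate_atoms: list[tuple[str, str, np.ndarray]],
    target: ResidueID,
    radii: RadiiTable | None = None,
    env: StericEnvironment | None = None,
    aa3: str | None = None,
) -> float:
    """Soft steric-overlap penalty of candidate side-chain atoms.

    ``sum over pairs of max(0, vdw_i + vdw_j - d_ij)^2`` over (candidate,
    environment) heavy-atom pairs, excluding intra-side-chain pairs and pairs
    separated by three or fewer covalent bonds.
    """
    if not candidate_atoms:
        return 0.0
    if env is None:
        aa = aa3 or _guess_aa(candidate_atoms)
        env = StericEnvironment(structure, target, aa, radii)
    score = 0.0
    for name, element, xyz in candidate_atoms:
        vi = env.radii.vdw(element)
        d = np.linalg.norm(env.coords - np.asarray(xyz), axis=1)
        overlap = vi + env.vdw - d
        excl = env.excluded_indices(name)
        if len(excl):
            overlap[excl] = 0.0
        pos = overlap > 0
        if pos.any():
            score += float(np.sum(overlap[pos] ** 2))
    return score


def _guess_aa(candidate_atoms) -> str:
    names = {n for n, _e, _x in candidate_atoms}
    for aa, records in SIDE_CHAIN_TEMPLATES.items():
        if {r[0] for r in records} | {"CB"} == names:
            return aa
    return "ALA"


@dataclass
class MutationResult:
    structure: Structure
    target: ResidueID
    new_res_name: str
    rotamer_index: int
    chi: tuple[float, ...]
    score: float
    clashes: list[ClashRecord]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target": str(self.target),
            "new_res_name": self.new_res_name,
            "rotamer_index": self.rotamer_index,
            "chi": list(self.chi),
            "steric_score": self.score,
            "clashes": [
                {
                    "partner": str(c.partner),
                    "res_name": c.partner_res_name,
                    "min_distance": round(c.min_distance, 3),
                    "vdw_sum": round(c.vdw_sum, 3),
                    "atom_pair": list(c.atom_pair),
                }
                for c in self.clashes
            ],
            "warnings": self.warnings,
        }


def _strip_side_chain(res: Residue) -> None:
    res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]


def mutate_residue(
    structure: Structure,
    target: ResidueID,
    new_aa: str,
    rotlib: dict[str, list[tuple[float, ...]]] | None = None,
    templates: dict[str, list[tuple]] | None = None,
    radii: RadiiTable | None = None,
    clash_tolerance: float = 0.4,
) -> MutationResult:
    """Replace the target residue's side chain with the best rotamer of ``new_aa``.

    The input structure is left untouched; the result holds a deep copy with
    only the target's side-chain atoms (and residue name / SEQRES letter)
    changed.  Every rotamer is built and steric-scored; the minimum wins,
    ties by lowest rotamer index.
    """
    rotlib = rotlib or default_rotamer_library()
    templates = templates or SIDE_CHAIN_TEMPLATES
    radii = radii or RadiiTable()
    new_aa = new_aa.upper()
    aa3 = new_aa if len(new_aa) == 3 else ONE_TO_THREE.get(new_aa, "")
    if aa3 not in templates:
        raise UnknownResidueError(f"unknown residue type {new_aa!r}")

    res = structure.get_residue(target)
    if res is None:
        raise UnknownResidueError(f"residue {target} not in structure")
    backbone = {}
    for name in ("N", "CA", "C"):
        atom = res.atom(name)
        if atom is None:
            raise IncompleteBackboneError(f"{target} lacks backbone atom {name}")
        backbone[name] = atom.xyz

    warns: list[str] = []
    if aa3 == "PRO" or res.res_name == "PRO":
        warns.append(
            "proline involved: ring closure is approximate and backbone "
            "N-CD bonding is not modelled"
        )

    env = StericEnvironment(structure, target, aa3, radii)
    best_idx, best_chi, best_score, best_atoms = -1, (), np.inf, []
    rotamers = rotlib.get(aa3, [()])
    for idx, chi_tuple in enumerate(rotamers):
        cand = build_side_chain(backbone, aa3, tuple(chi_tuple), templates)
        s = steric_score(structure, cand, target, env=env)
        if s < best_score:
            best_idx, best_chi, best_score, best_atoms = idx, tuple(chi_tuple), s, cand
    if best_idx < 0:  # pragma: no cover - rotlib invariant guarantees >=1 entry
        raise VarstructError(f"no rotamers for {aa3}")

    # locate the target's SEQRES index before mutation (while seqres and the
    # resolved sequence still agree), so the chain stays self-consistent
    seqres_idx = None
    src_chain = structure.chains.get(target.chain)
    if src_chain is not None:
        try:
            for i, rid in enumerate(build_seqres_atom_map(src_chain).entries):
                if rid == target:
                    seqres_idx = i
                    break
        except Exception:
            seqres_idx = None

    mutant = copy.deepcopy(structure)
    mres = mutant.get_residue(target)
    _strip_side_chain(mres)
    mres.res_name = aa3
    mres.one_letter = {v: k for k, v in ONE_TO_THREE.items()}.get(aa3, "X")
    max_serial = max(a.serial for _r, a in mutant.iter_atoms())
    for k, (name, element, xyz) in enumerate(best_atoms):
        mres.atoms.append(
            AtomRecord(
                serial=max_serial + 1 + k,
                name=name,
                element=element,
                altloc="",
                xyz=np.array(xyz, dtype=float),
                occupancy=1.0,
            )
        )
    if seqres_idx is not None:
        ch = mutant.chains[target.chain]
        ch.seqres = ch.seqres[:seqres_idx] + mres.one_letter + ch.seqres[seqres_idx + 1 :]
    clashes = detect_clashes(mutant, target, tolerance=clash_tolerance, radii=radii)
    if warns:
        for w in warns:
            warnings.warn(w, stacklevel=2)
    return MutationResult(
        structure=mutant,
        target=target,
        new_res_name=aa3,
        rotamer_index=best_idx,
        chi=best_chi,
        score=best_score,
        clashes=clashes,
        warnings=warns,
    )


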