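"""Contact surface areas, solvent-accessible surface and steric clashes.

Every heavy atom carries a probe-expanded sphere of radius ``R = r_vdw +
r_probe``.  Each point of that sphere surface is assigned either to a
neighboring atom -- the neighbor whose expanded sphere contains the point and
that is nearest in *power distance* ``|p - c_j|^2 - R_j^2`` -- or, if no
neighbor sphere contains it, to the solvent.  The area allocated to neighbor
``j`` is the contact surface area of the pair measured on atom ``i``'s
sphere, and the solvent share is the atom's SASA, so by construction

    sasa_i + sum_j contact_ij = 4 pi R_i^2 .

The assignment is evaluated numerically on a quasi-uniform Fibonacci lattice
(deterministic; the lattice pole is aligned with the nearest neighbor, which
makes the dominant contact boundary a lattice parallel and sharpens the area
estimate).  Atom-level partitions aggregate into residue-level contact
tables with minimal inter-atomic distances and clash flags.

Clash detection is independent of the partition: two atoms clash when their
center distance falls below the sum of their van der Waals radii minus a
tolerance (default 0.4 A), excluding pairs separated by three or fewer
covalent bonds (bonds inferred from distances and covalent radii).
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, UnknownResidueError, VarstructError
from .structlib import AtomRecord, Residue, ResidueID, Structure

#: Bondi-style van der Waals radii (A)
DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
#: covalent radii (A) for distance-based bond inference
COVALENT_RADII = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "P": 1.10, "H": 0.32}
_BOND_SLACK = 0.45  # bonded if d < r_cov_i + r_cov_j + slack


@dataclass
class RadiiTable:
    """Van der Waals radii by element plus the solvent probe radius."""

    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW))
    probe_radius: float = 1.4
    default_radius: float = 1.70

    def __post_init__(self):
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise VarstructError(f"vdW radius for {el} out of range: {r}")
        if self.probe_radius < 0:
            raise VarstructError("probe radius must be >= 0")

    def vdw(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default_radius)

    def expanded(self, element: str) -> float:
        return self.vdw(element) + self.probe_radius


AtomKey = tuple  # (ResidueID, atom_name)


@dataclass
class AtomSurfacePartition:
    """Partition of one atom's expanded sphere into neighbor arcs + solvent."""

    key: AtomKey
    radius: float  # expanded radius R
    total_area: float  # 4 pi R^2
    sasa: float
    contacts: dict[AtomKey, float]  # neighbor -> area on this atom's sphere


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +z to ``axis`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _flat_atoms(structure: Structure):
    """(residue, atom) pairs for all heavy atoms, with stable serial order."""
    out = []
    for res, atom in structure.iter_atoms():
        if not atom.is_hydrogen:
            out.append((res, atom))
    return out


def partition_atom_surfaces(
    structure: Structure,
    radii: RadiiTable | None = None,
    n_points: int = 24000,
) -> dict[AtomKey, AtomSurfacePartition]:
    """Partition every heavy atom's expanded sphere surface.

    Returns a dict keyed by ``(ResidueID, atom_name)``.  Raises
    :class:`DegenerateGeometryError` on (near-)coincident atom centers.
    """
    radii = radii or RadiiTable()
    atoms = _flat_atoms(structure)
    if not atoms:
        raise VarstructError("structure has no heavy atoms")
    coords = np.array([a.xyz for _, a in atoms])
    rexp = np.array([radii.expanded(a.element) for _, a in atoms])
    serials = np.array([a.serial for _, a in atoms])
    keys = [(res.rid, a.name) for res, a in atoms]

    tree = cKDTree(coords)
    base_sphere = _fibonacci_sphere(n_points)
    point_w = 1.0 / n_points

    out: dict[AtomKey, AtomSurfacePartition] = {}
    rmax = rexp.max()
    for i in range(len(atoms)):
        R = rexp[i]
        total = 4.0 * np.pi * R * R
        nbr = [j for j in tree.query_ball_point(coords[i], R + rmax) if j != i]
        nbr = [j for j in nbr if np.linalg.norm(coords[j] - coords[i]) < R + rexp[j]]
        if nbr:
            d = np.linalg.norm(coords[nbr] - coords[i], axis=1)
            if (d < 0.01).any():
                k = nbr[int(np.argmin(d))]
                raise DegenerateGeometryError(
                    f"atoms {keys[i]} and {keys[k]} are {d.min():.3f} A apart"
                )
            # stable tie-break: lower serial wins argmin below
            order = np.argsort(serials[nbr], kind="stable")
            nbr = [nbr[k] for k in order]
        if not nbr:
            out[keys[i]] = AtomSurfacePartition(keys[i], R, total, total, {})
            continue
        ncoords = coords[nbr]
        # orient lattice pole towards the nearest neighbor
        dvec = ncoords - coords[i]
        dists = np.linalg.norm(dvec, axis=1)
        rot = _rotation_to(dvec[int(np.argmin(dists))] / dists.min())
        pts = coords[i] + (base_sphere @ rot.T) * R
        # power distance of each point to each neighbor sphere
        diff = pts[:, None, :] - ncoords[None, :, :]
        power = np.einsum("pnk,pnk->pn", diff, diff) - (rexp[nbr] ** 2)[None, :]
        inside = power < 0.0
        covered = inside.any(axis=1)
        power_masked = np.where(inside, power, np.inf)
        owner = np.argmin(power_masked, axis=1)  # first min = lowest serial
        areas: dict[AtomKey, float] = {}
        counts = np.bincount(owner[covered], minlength=len(nbr))
        for jn, cnt in enumerate(counts):
            if cnt:
                areas[keys[nbr[jn]]] = float(cnt) * point_w * total
        sasa = float((~covered).sum()) * point_w * total
        out[keys[i]] = AtomSurfacePartition(keys[i], R, total, sasa, areas)
    return out


# ---------------------------------------------------------------------------
# residue-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class ResidueContactRow:
    partner: ResidueID
    partner_res_name: str
    contact_area: float  # A^2, summed over target-atom spheres
    min_distance: float  # A, minimal inter-atomic center distance
    clash: bool
    annotations: list = field(default_factory=list)


@dataclass
class ResidueContactTable:
    target: ResidueID
    target_res_name: str
    target_sasa: float  # A^2, summed over the target's atoms
    rows: list[ResidueContactRow]

    def partner_map(self) -> dict[ResidueID, ResidueContactRow]:
        return {r.partner: r for r in self.rows}


def _require_residue(structure: Structure, rid: ResidueID) -> Residue:
    res = structure.get_residue(rid)
    if res is None:
        raise UnknownResidueError(f"residue {rid} not found in structure")
    return res


def residue_contact_table(
    partitions: dict[AtomKey, AtomSurfacePartition],
    structure: Structure,
    target: ResidueID,
    radii: RadiiTable | None = None,
    clash_tolerance: float = 0.4,
) -> ResidueContactTable:
    """Aggregate atom partitions into one row per contacting partner residue.

    A partner is listed when the summed atom-atom contact area is positive or
    some atom pair sits below the clash threshold; rows are sorted by contact
    area descending.  Intra-residue contacts are excluded.
    """
    radii = radii or RadiiTable()
    target_res = _require_residue(structure, target)
    area_by_partner: dict[ResidueID, float] = defaultdict(float)
    sasa = 0.0
    for atom in target_res.heavy_atoms():
        part = partitions.get((target, atom.name))
        if part is None:
            continue
        sasa += part.sasa
        for (rid, _aname), area in part.contacts.items():
            if rid != target:
                area_by_partner[rid] += area

    # distances + clash detection against every nearby residue
    tcoords = np.array([a.xyz for a in target_res.heavy_atoms()])
    tvdw = np.array([radii.vdw(a.element) for a in target_res.heavy_atoms()])
    excluded = _bonded_exclusion_set(structure, target)
    tnames = [a.name for a in target_res.heavy_atoms()]
    info: dict[ResidueID, tuple[str, float, bool]] = {}
    for ch in structure.chains.values():
        for res in ch.residues:
            if res.rid == target:
                continue
            pcoords = np.array([a.xyz for a in res.heavy_atoms()])
            if len(pcoords) == 0:
                continue
            pvdw = np.array([radii.vdw(a.element) for a in res.heavy_atoms()])
            d = np.linalg.norm(tcoords[:, None] - pcoords[None, :], axis=2)
            mind = float(d.min())
            thr = tvdw[:, None] + pvdw[None, :] - clash_tolerance
            clash_pairs = d < thr
            for (ti, pj) in zip(*np.nonzero(clash_pairs)):
                pair = frozenset(
                    [(target, tnames[ti]), (res.rid, res.heavy_atoms()[pj].name)]
                )
                if pair in excluded:
                    clash_pairs[ti, pj] = False
            clash = bool(clash_pairs.any())
            if area_by_partner.get(res.rid, 0.0) > 0.0 or clash:
                info[res.rid] = (res.res_name, mind, clash)

    rows = [
        ResidueContactRow(
            partner=rid,
            partner_res_name=info[rid][0],
            contact_area=area_by_partner.get(rid, 0.0),
            min_distance=info[rid][1],
            clash=info[rid][2],
        )
        for rid in info
    ]
    rows.sort(key=lambda r: (-r.contact_area, r.partner))
    return ResidueContactTable(target, target_res.res_name, sasa, rows)


@dataclass
class AtomContactRow:
    atom_a: str
    atom_b: str
    contact_area: float  # measured on atom_a's sphere
    distance: float


def atom_contact_detail(
    partitions: dict[AtomKey, AtomSurfacePartition],
    structure: Structure,
    res_a: ResidueID,
    res_b: ResidueID,
) -> list[AtomContactRow]:
    """Atom-pair contact areas between two residues (areas on res_a spheres)."""
    ra = _require_residue(structure, res_a)
    rb = _require_residue(structure, res_b)
    batoms = {a.name: a for a in rb.heavy_atoms()}
    rows: list[AtomContactRow] = []
    for atom in ra.heavy_atoms():
        part = partitions.get((res_a, atom.name))
        if part is None:
            continue
        for (rid, bname), area in part.contacts.items():
            if rid == res_b and area > 0.0:
                d = float(np.linalg.norm(atom.xyz - batoms[bname].xyz))
                rows.append(AtomContactRow(atom.name, bname, area, d))
    rows.sort(key=lambda r: (-r.contact_area, r.atom_a, r.atom_b))
    return rows


# ---------------------------------------------------------------------------
# covalent-bond inference and clash detection
# ---------------------------------------------------------------------------

def infer_bonds(structure: Structure) -> dict[AtomKey, set[AtomKey]]:
    """Distance-based covalent bond graph over all atoms (incl. hydrogens)."""
    entries = [(res.rid, a) for res, a in structure.iter_atoms()]
    coords = np.array([a.xyz for _, a in entries])
    keys = [(rid, a.name) for rid, a in entries]
    rcov = np.array(
        [COVALENT_RADII.get(a.element.upper(), 0.77) for _, a in entries]
    )
    tree = cKDTree(coords)
    graph: dict[AtomKey, set[AtomKey]] = defaultdict(set)
    pairs = tree.query_pairs(2.0 * rcov.max() + _BOND_SLACK)
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if d < rcov[i] + rcov[j] + _BOND_SLACK:
            graph[keys[i]].add(keys[j])
            graph[keys[j]].add(keys[i])
    return graph


def bonded_within(
    graph: dict[AtomKey, set[AtomKey]], start: AtomKey, max_bonds: int = 3
) -> set[AtomKey]:
    """Atoms reachable from ``start`` in at most ``max_bonds`` bonds."""
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        node, depth = frontier.popleft()
        if depth == max_bonds:
            continue
        for nxt in graph.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, depth + 1))
    return seen


def _bonded_exclusion_set(structure: Structure, target: ResidueID) -> set[frozenset]:
    """Pairs (as frozensets of AtomKeys) separated by <= 3 covalent bonds."""
    graph = infer_bonds(structure)
    res = structure.get_residue(target)
    excluded: set[frozenset] = set()
    for atom in res.atoms:
        start = (target, atom.name)
        for other in bonded_within(graph, start, 3):
            if other != start:
                excluded.add(frozenset([start, other]))
    return excluded


@dataclass
class ClashRecord:
    partner: ResidueID
    partner_res_name: str
    min_distance: float  # distance of the most-overlapping clashing pair
    vdw_sum: float  # vdW radius sum of that pair
    atom_pair: tuple[str, str]


def detect_clashes(
    structure: Structure,
    target: ResidueID,
    tolerance: float = 0.4,
    radii: RadiiTable | None = None,
) -> list[ClashRecord]:
    """Residues with an atom closer to the target than vdW sum - tolerance.

    Pairs separated by three or fewer covalent bonds (peptide neighbors,
    1-3/1-4 pairs) are excluded.  Sorted by overlap severity.
    """
    radii = radii or RadiiTable()
    target_res = _require_residue(structure, target)
    excluded = _bonded_exclusion_set(structure, target)
    tatoms = target_res.heavy_atoms()
    best: dict[ResidueID, ClashRecord] = {}
    for ch in structure.chains.values():
        for res in ch.residues:
            if res.rid == target:
                continue
            for pa in res.heavy_atoms():
                for ta in tatoms:
                    if frozenset([(target, ta.name), (res.rid, pa.name)]) in excluded:
                        continue
                    d = float(np.linalg.norm(ta.xyz - pa.xyz))
                    vdw_sum = radii.vdw(ta.element) + radii.vdw(pa.element)
                    if d < vdw_sum - tolerance:
                        prev = best.get(res.rid)
                        overlap = vdw_sum - d
                        if prev is None or overlap > prev.vdw_sum - prev.min_distance:
                            best[res.rid] = ClashRecord(
                                res.rid, res.res_name, d, vdw_sum, (ta.name, pa.name)
                            )
    return sorted(best.values(), key=lambda c: -(c.vdw_sum - c.min_distance))


# ---------------------------------------------------------------------------
# wild-type vs mutant comparison
# ---------------------------------------------------------------------------

@dataclass
class ContactDelta:
    partner: ResidueID
    partner_res_name: str
    wt_area: float
    mut_area: float
    wt_min_distance: float | None
    mut_min_distance: float | None
    gained: bool
    lost: bool
    wt_clash: bool
    mut_clash: bool


@dataclass
class ContactComparison:
    target: ResidueID
    wt_sasa: float
    mut_sasa: float
    deltas: list[ContactDelta]


def compare_wt_mut(
    wt_table: ResidueContactTable, mut_table: ResidueContactTable
) -> ContactComparison:
    """Diff two contact tables for the same residue on wt and mutant models."""
    if wt_table.target != mut_table.target:
        raise VarstructError(
            f"tables target different residues: {wt_table.target} vs {mut_table.target}"
        )
    wt = wt_table.partner_map()
    mut = mut_table.partner_map()
    deltas: list[ContactDelta] = []
    for rid in sorted(set(wt) | set(mut)):
        w, m = wt.get(rid), mut.get(rid)
        deltas.append(
            ContactDelta(
                partner=rid,
                partner_res_name=(w or m).partner_res_name,
                wt_area=w.contact_area if w else 0.0,
                mut_area=m.contact_area if m else 0.0,
                wt_min_distance=w.min_distance if w else None,
                mut_min_distance=m.min_distance if m else None,
                gained=w is None and m is not None,
                lost=m is None and w is not None,
                wt_clash=bool(w and w.clash),
                mut_clash=bool(m and m.clash),
            )
        )
    deltas.sort(key=lambda d: -(abs(d.mut_area - d.wt_area)))
    return ContactComparison(wt_table.target, wt_table.target_sasa, mut_table.target_sasa, deltas)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def contact_table_to_tsv(table: ResidueContactTable) -> str:
    lines = ["partner\tres_name\tcontact_area_A2\tmin_distance_A\tclash\tannotations"]
    for r in table.rows:
        ann = ",".join(str(a) for a in r.annotations)
        lines.append(
            f"{r.partner}\t{r.partner_res_name}\t{r.contact_area:.2f}\t"
            f"{r.min_distance:.2f}\t{int(r.clash)}\t{ann}"
        )
    return "\n".join(lines) + "\n"


def clashes_to_tsv(clashes: list[ClashRecord]) -> str:
    lines = ["partner\tres_name\tmin_distance_A\tvdw_sum_A\tatom_pair"]
    for c in clashes:
        lines.append(
            f"{c.partner}\t{c.partner_res_name}\t{c.min_distance:.2f}\t"
            f"{c.vdw_sum:.2f}\t{c.atom_pair[0]}-{c.atom_pair[1]}"
        )
    return "\n".join(lines) + "\n"
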