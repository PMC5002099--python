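"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available
(naive DP, exhaustive enumeration, dot sampling, regex translation) and stay
independent of the library code paths they check.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_B62_IDX = {c: i for i, c in enumerate(_B62.alphabet)}


def sw_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Quadratic-space affine-gap Smith-Waterman score (Gotoh), naive loops."""
    n, m = len(a), len(b)
    NEG = -(10**8)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = int(_B62[_B62_IDX[a[i - 1]], _B62_IDX[b[j - 1]]])
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def sphere_cap_sampling_oracle(
    center_a, radius_a, center_b, radius_b, n_points: int = 100_000, seed: int = 0
) -> float:
    """Buried area of sphere A inside sphere B by stratified dot sampling.

    Dots are stratified along the inter-center axis (one random dot per
    equal-area band, random azimuth), so the cap-fraction estimate is exact
    to within one dot's area.
    """
    rng = np.random.default_rng(seed)
    axis = np.asarray(center_b, float) - np.asarray(center_a, float)
    axis /= np.linalg.norm(axis)
    # orthonormal frame around the axis
    tmp = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    k = np.arange(n_points)
    z = -1.0 + (k + rng.random(n_points)) * (2.0 / n_points)  # stratified cos(theta)
    phi = rng.random(n_points) * 2.0 * np.pi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = (
        np.asarray(center_a, float)
        + radius_a * (np.outer(z, axis) + np.outer(r * np.cos(phi), e1) + np.outer(r * np.sin(phi), e2))
    )
    inside = np.sum((pts - np.asarray(center_b)) ** 2, axis=1) < radius_b**2
    return inside.mean() * 4.0 * np.pi * radius_a**2


def prosite_to_regex(pattern: str) -> str:
    """Mechanical translation of the Prosite grammar subset to a regex."""
    out = []
    body = pattern
    if body.startswith("<"):
        out.append("^")
        body = body[1:]
    anchored_end = body.endswith(">")
    if anchored_end:
        body = body[:-1]
    for tok in body.split("-"):
        m = re.fullmatch(r"(.+?)(?:\((\d+)(?:,(\d+))?\))?", tok)
        core, n, mx = m.group(1), m.group(2), m.group(3)
        if core == "x":
            piece = "."
        elif core.startswith("["):
            piece = core
        elif core.startswith("{"):
            piece = "[^" + core[1:-1] + "]"
        else:
            piece = core
        if n and mx:
            piece += f"{{{n},{mx}}}"
        elif n:
            piece += f"{{{n}}}"
        out.append(piece)
    if anchored_end:
        out.append("$")
    return "".join(out)


def regex_motif_matches(sequence: str, pattern: str) -> list[tuple[int, int]]:
    """Leftmost non-overlapping matches via the regex translation, 1-based."""
    rx = re.compile(prosite_to_regex(pattern))
    return [
        (m.start() + 1, m.end())
        for m in rx.finditer(sequence)
        if m.end() > m.start()
    ]


def translation_diff_oracle(wild_cds: str, mutant_cds: str):
    """(protein_position, ref_aa, alt_aa) by translating both full sequences.

    Returns None for synonymous changes.  Uses Biopython's translator as the
    independent genetic-code source.
    """
    from Bio.Seq import Seq

    wt = str(Seq(wild_cds).translate())
    mt = str(Seq(mutant_cds).translate())
    assert len(wt) == len(mt)
    diffs = [(i + 1, a, b) for i, (a, b) in enumerate(zip(wt, mt)) if a != b]
    if not diffs:
        return None
    assert len(diffs) == 1
    return diffs[0]


def naive_steric_score(structure, candidate_atoms, target_rid, vdw_table=None):
    """All-pairs steric penalty with its own bond bookkeeping.

    Environment bonds: d < rcov_i + rcov_j + 0.45 over the structure's atoms;
    candidate side-chain bonds follow the known chemical topology (CB to the
    target CA, every other atom to its template parent) rather than distance,
    since a clashing placement must not be mistaken for a covalent bond.
    Excluded pairs are those within 3 bonds; the environment excludes the
    target residue's own (old) side chain.
    """
    from varstruct.sidechains import SIDE_CHAIN_TEMPLATES

    vdw = vdw_table or {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
    rcov = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "P": 1.10, "H": 0.32}

    nodes = []  # (key, element, xyz)
    for res, a in structure.iter_atoms():
        if res.rid == target_rid and a.name not in ("N", "CA", "C", "O"):
            continue
        nodes.append(((res.rid, a.name), a.element, a.xyz))
    cand_nodes = [((target_rid, n), el, xyz) for n, el, xyz in candidate_atoms]
    allnodes = nodes + cand_nodes

    adj = {k: set() for k, _e, _x in allnodes}
    for i, (ki, ei, xi) in enumerate(nodes):
        for kj, ej, xj in nodes[i + 1 :]:
            if np.linalg.norm(np.asarray(xi) - np.asarray(xj)) < rcov.get(ei, 0.77) + rcov.get(ej, 0.77) + 0.45:
                adj[ki].add(kj)
                adj[kj].add(ki)
    parent = {"CB": "CA"}
    cand_names = {k[1] for k, _e, _x in cand_nodes}
    for recs in SIDE_CHAIN_TEMPLATES.values():
        names = {r[0] for r in recs} | {"CB"}
        if names == cand_names:
            for r in recs:
                parent[r[0]] = r[3]
            break
    for k, _e, _x in cand_nodes:
        p = (target_rid, parent[k[1]])
        adj[k].add(p)
        adj.setdefault(p, set()).add(k)

    def within(start, k):
        seen = {start}
        frontier = [start]
        for _ in range(k):
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if nb not in seen:
                        seen.add(nb)
                        nxt.append(nb)
            frontier = nxt
        return seen

    cand_keys = {k for k, _e, _x in cand_nodes}
    score = 0.0
    for kc, ec, xc in cand_nodes:
        excl = within(kc, 3)
        for ke, ee, xe in nodes:
            if ke in cand_keys or ke in excl:
                continue
            if ee.upper() == "H":
                continue
            d = float(np.linalg.norm(np.asarray(xc) - np.asarray(xe)))
            ov = vdw.get(ec.upper(), 1.70) + vdw.get(ee.upper(), 1.70) - d
            if ov > 0:
                score += ov * ov
    return score
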