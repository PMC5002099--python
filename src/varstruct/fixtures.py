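"""Synthetic fixtures: ideal helices, toy genomes/transcripts, toy libraries.

Everything downstream of real data (PDB entries, transcript annotation,
variant dumps) can be emulated at toy scale by these generators, which makes
the full pipeline testable offline.  All generators are deterministic under
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError
from .geometry import place_atom, place_cb
from .genecoord import TranscriptModel, reverse_complement
from .structlib import (
    ONE_TO_THREE,
    AtomRecord,
    ChainModel,
    Residue,
    ResidueID,
    Structure,
    write_pdb,
)

# ideal peptide geometry
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O coordinates for a homoconformational backbone."""
    res: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    # C at the ideal N-CA-C angle; dummy reference off the N-CA axis
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, _B_CA_C, _A_N_CA_C, 0.0)
    for i in range(n_res):
        res.append({"N": n, "CA": ca, "C": c})
        n_next = place_atom(n, ca, c, _B_C_N, _A_CA_C_N, psi)
        ca_next = place_atom(ca, c, n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = place_atom(c, n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        n, ca, c = n_next, ca_next, c_next
    for i, r in enumerate(res):
        # carbonyl O anti to the following N (psi + 180)
        r["O"] = place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return res


def _screw_params(phi: float, psi: float) -> tuple[float, float]:
    """(rise, twist) per residue of the helix generated by (phi, psi)."""
    bb = _build_backbone(4, phi, psi)
    p = [r["CA"] for r in bb]
    v1, v2, v3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]

    def frame(a, b):
        e1 = a / np.linalg.norm(a)
        e2 = b - np.dot(b, e1) * e1
        e2 /= np.linalg.norm(e2)
        return np.stack([e1, e2, np.cross(e1, e2)], axis=1)

    rot = frame(v2, v3) @ frame(v1, v2).T
    angle = np.degrees(np.arccos(np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)))
    w, v = np.linalg.eig(rot)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    rise = abs(float(np.dot(v2, axis)))
    return rise, angle


@lru_cache(maxsize=8)
def _solve_phipsi(rise: float, twist: float) -> tuple[float, float]:
    """Best-fit (phi, psi) for the requested screw parameters.

    With ideal bond lengths/angles the attainable (rise, twist) surface does
    not contain every nominal pair exactly (the canonical 1.5 A / 100 deg is
    approached to within a few hundredths of an angstrom); a least-squares
    fit keeps the generator well-defined for any sensible request.
    """

    def fun(x):
        r, t = _screw_params(x[0], x[1])
        return (r - rise, t - twist)

    sol = least_squares(fun, x0=(-57.0, -47.0), xtol=1e-10, ftol=1e-12)
    return float(sol.x[0]), float(sol.x[1])


def make_helix_structure(
    sequence: str,
    rise: float = 1.5,
    twist: float = 100.0,
    chain_id: str = "A",
    first_res_seq: int = 1,
    deleted: tuple[int, int] | None = None,
    origin: np.ndarray | None = None,
) -> Structure:
    """Ideal alpha-helix with full backbone + CB (poly-Ala-style geometry).

    ``deleted=(i, j)`` drops residues i..j (1-based SEQRES indices) from the
    coordinates while keeping them in SEQRES -- the unresolved-loop fixture.
    ``first_res_seq`` offsets the author numbering, emulating structures
    whose ATOM numbering differs from the SEQRES index.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise InputError("helix needs at least 3 residues")
    for c in sequence:
        if c not in ONE_TO_THREE:
            raise InputError(f"invalid residue letter {c!r}")
    phi, psi = _solve_phipsi(rise, twist)
    bb = _build_backbone(len(sequence), phi, psi)
    shift = origin if origin is not None else np.zeros(3)
    residues: list[Residue] = []
    serial = 0
    for i, (letter, r) in enumerate(zip(sequence, bb), start=1):
        if deleted and deleted[0] <= i <= deleted[1]:
            continue
        rid = ResidueID(chain_id, first_res_seq + i - 1)
        res = Residue(rid, ONE_TO_THREE[letter], [], letter)
        names = ["N", "CA", "C", "O"]
        coords = [r["N"], r["CA"], r["C"], r["O"]]
        if letter != "G":
            names.append("CB")
            coords.append(place_cb(r["N"], r["CA"], r["C"]))
        for nm, xyz in zip(names, coords):
            serial += 1
            res.atoms.append(
                AtomRecord(serial, nm, nm[0], "", np.asarray(xyz) + shift, 1.0)
            )
        residues.append(res)
    st = Structure({chain_id: ChainModel(chain_id, sequence, residues)}, name="helix")
    return st


def make_helix_fixture(
    sequence: str,
    rise: float = 1.5,
    twist: float = 100.0,
    chain_id: str = "A",
    first_res_seq: int = 1,
    deleted: tuple[int, int] | None = None,
) -> str:
    """PDB text of :func:`make_helix_structure` (SEQRES + ATOM records)."""
    return write_pdb(
        make_helix_structure(sequence, rise, twist, chain_id, first_res_seq, deleted)
    )


def make_helix_pair_structure(
    seq_a: str,
    seq_b: str,
    separation: float = 8.0,
    rise: float = 1.5,
    twist: float = 100.0,
) -> Structure:
    """Two parallel helices in one structure (chains A and B).

    Chain B is the same ideal helix translated ``separation`` angstroms along
    x -- a crude packed interface for clash/contact scenarios.
    """
    a = make_helix_structure(seq_a, rise, twist, chain_id="A")
    b = make_helix_structure(
        seq_b, rise, twist, chain_id="B", origin=np.array([separation, 0.0, 0.0])
    )
    serial = max(at.serial for _r, at in a.iter_atoms())
    for res in b.chains["B"].residues:
        for at in res.atoms:
            serial += 1
            at.serial = serial
    return Structure({"A": a.chains["A"], "B": b.chains["B"]}, name="helix-pair")


# ---------------------------------------------------------------------------
# toy genomes and transcripts
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = None


def _non_stop_codons():
    global _NON_STOP_CODONS
    if _NON_STOP_CODONS is None:
        from .genecoord import GENETIC_CODE

        _NON_STOP_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
    return _NON_STOP_CODONS


@dataclass
class ToyTranscript:
    """A toy transcript embedded in a toy genome slice, with its oracle map."""

    tm: TranscriptModel
    chrom_seq: str  # full toy chromosome, position 1 = chrom_seq[0]
    cds_pos_of_genomic: dict[int, int]  # genomic pos -> 1-based CDS pos (by construction)

    def genome_fasta(self) -> str:
        return f">{self.tm.chrom}\n{self.chrom_seq}\n"

    def cds_fasta(self) -> str:
        return f">{self.tm.transcript_id}\n{self.tm.cds_sequence}\n"

    def table_row(self) -> str:
        exons = ",".join(f"{s}-{e}" for s, e in self.tm.cds_exons)
        t = self.tm
        return f"{t.transcript_id}\t{t.gene}\t{t.chrom}\t{t.build}\t{t.strand}\t{exons}"


def make_toy_transcript(
    n_exons: int = 3,
    strand: str = "+",
    seed: int = 0,
    n_codons: int | None = None,
    chrom: str = "chrT",
    build: str = "toy",
    transcript_id: str | None = None,
    with_stop: bool = True,
) -> ToyTranscript:
    """Random toy transcript + genome slice, deterministic under ``seed``.

    The CDS starts with ATG, contains no internal stop codon and (by
    default) ends with a stop; exon boundaries and intron/flank lengths are
    random.  ``cds_pos_of_genomic`` is recorded while the genome is
    assembled, giving an enumeration oracle independent of the coordinate
    arithmetic.
    """
    if n_exons < 1:
        raise InputError("need at least one exon")
    rng = np.random.default_rng(seed)
    n_codons = n_codons or int(rng.integers(20, 61))
    codons = _non_stop_codons()
    body = [codons[k] for k in rng.integers(0, len(codons), n_codons - 2)]
    cds = "ATG" + "".join(body) + ("TAA" if with_stop else codons[int(rng.integers(0, len(codons)))])
    L = len(cds)

    # split CDS into n_exons non-empty chunks
    if n_exons == 1:
        cuts: list[int] = []
    else:
        cuts = sorted(rng.choice(np.arange(1, L), size=n_exons - 1, replace=False))
    chunks = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [L])]

    flank = int(rng.integers(10, 41))
    introns = [int(rng.integers(5, 21)) for _ in range(n_exons - 1)]
    bases = "ACGT"

    def random_seq(n):
        return "".join(bases[k] for k in rng.integers(0, 4, n))

    genome_parts: list[str] = [random_seq(flank)]
    pos = flank  # 0-based end of assembled genome
    exon_intervals_asc: list[tuple[int, int]] = []
    oracle: dict[int, int] = {}

    # genomic chunk order: ascending for +, reversed for -
    order = list(range(n_exons)) if strand == "+" else list(range(n_exons - 1, -1, -1))
    cds_offsets = np.cumsum([0] + [len(c) for c in chunks])
    for k, chunk_idx in enumerate(order):
        chunk = chunks[chunk_idx]
        gstart = pos + 1  # 1-based
        if strand == "+":
            genome_parts.append(chunk)
            for j in range(len(chunk)):
                oracle[gstart + j] = int(cds_offsets[chunk_idx]) + j + 1
        else:
            genome_parts.append(reverse_complement(chunk))
            # chunk base j (CDS order) sits at genomic gend - j
            gend = gstart + len(chunk) - 1
            for j in range(len(chunk)):
                oracle[gend - j] = int(cds_offsets[chunk_idx]) + j + 1
        pos += len(chunk)
        exon_intervals_asc.append((gstart, pos))
        if k < n_exons - 1:
            intr = introns[k]
            genome_parts.append(random_seq(intr))
            pos += intr
    genome_parts.append(random_seq(int(rng.integers(10, 41))))
    chrom_seq = "".join(genome_parts)

    exons = exon_intervals_asc if strand == "+" else exon_intervals_asc[::-1]
    tid = transcript_id or f"TOY{seed:04d}.{strand == '-' and 'm' or 'p'}{n_exons}"
    tm = TranscriptModel(
        transcript_id=tid,
        gene=f"GENE{seed}",
        chrom=chrom,
        build=build,
        strand=strand,
        cds_exons=exons,
        cds_sequence=cds,
    )
    return ToyTranscript(tm, chrom_seq, oracle)
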