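"""Find and exploit structure hits for a query protein sequence.

A query protein is searched against a library of SEQRES-derived sequences
(experimental structures and theoretical models alike) with Smith-Waterman
local alignment -- local rather than global because structures typically
cover single domains of the query.  Alignment hits double as coordinate
bridges: a query residue index maps through the alignment columns to a
subject SEQRES index, which the SEQRES->ATOM map then converts to an author
residue number in the coordinate file.

Scoring defaults follow protein BLAST (BLOSUM62, gap open 11 / extend 1,
i.e. a gap of length k costs 11 + k).  Traceback is deterministic: on ties
prefer the diagonal move, then the move consuming a query residue, then the
move consuming a subject residue; the start cell is the first maximal cell
in row-major order.  Identity is reported over non-gap aligned columns and
coverage as aligned-query-span / query length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError
from .structlib import UNRESOLVED, SeqresAtomMap

EXPERIMENTAL = "experimental"
THEORETICAL = "theoretical-model"


class _Marker:
    def __init__(self, label):
        self.label = label

    def __repr__(self):
        return self.label

    def __bool__(self):
        return False


#: query position outside the aligned span
NOT_COVERED = _Marker("NOT_COVERED")
#: query position aligned against a gap in the subject
GAP = _Marker("GAP")


@dataclass(frozen=True)
class StructureSeqRecord:
    """One library entry: a structure chain's SEQRES-derived sequence."""

    id: str  # e.g. "4u7p_A"
    sequence: str
    source: str = EXPERIMENTAL  # experimental | theoretical-model
    metadata: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"library record {self.id} has empty sequence")


@dataclass
class AlignmentParams:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11  # gap of length k costs gap_open + k * gap_extend
    gap_extend: int = 1


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: int
    identity_pct: float
    query_span: tuple[int, int]  # 1-based inclusive
    subject_span: tuple[int, int]
    columns: list[tuple[int | None, int | None]]  # (query_pos|None, subject_pos|None)
    source: str = EXPERIMENTAL

    def query_coverage(self, query_length: int) -> float:
        s, e = self.query_span
        return (e - s + 1) / query_length


_MATRICES: dict[str, tuple[np.ndarray, dict[str, int]]] = {}


def _scoring(matrix_name: str):
    if matrix_name not in _MATRICES:
        m = substitution_matrices.load(matrix_name)
        letters = "".join(m.alphabet)
        idx = {c: i for i, c in enumerate(letters)}
        arr = np.array(m, dtype=np.int32)
        _MATRICES[matrix_name] = (arr, idx)
    return _MATRICES[matrix_name]


def _encode(seq: str, idx: dict[str, int]) -> np.ndarray:
    x = idx.get("X", idx.get("*"))
    return np.array([idx.get(c, x) for c in seq.upper()], dtype=np.int32)


def align_local(
    query_seq: str,
    subject_seq: str,
    params: AlignmentParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Smith-Waterman local alignment with affine gaps.

    Returns ``None`` when no positive-scoring local alignment exists.
    """
    if not query_seq or not subject_seq:
        raise InputError("cannot align empty sequences")
    params = params or AlignmentParams()
    sub, idx = _scoring(params.matrix_name)
    q = _encode(query_seq, idx)
    s = _encode(subject_seq, idx)
    n, m = len(q), len(s)
    gap_first = params.gap_open + params.gap_extend
    gap_ext = params.gap_extend
    NEG = np.int32(-(10**8))

    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in query (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in subject (up)
    srow = sub[q][:, s]  # (n, m) substitution scores
    for i in range(1, n + 1):
        F[i] = np.maximum(H[i - 1] - gap_first, F[i - 1] - gap_ext)
        Hi = H[i]
        Him1 = H[i - 1]
        Ei = E[i]
        sc = srow[i - 1]
        e = NEG
        # sequential in j because E[i][j] depends on E[i][j-1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - gap_first, e - gap_ext)
            Ei[j] = e
            h = Him1[j - 1] + sc[j - 1]
            if F[i, j] > h:
                h = F[i, j]
            if e > h:
                h = e
            Hi[j] = h if h > 0 else 0

    best = int(H.max())
    if best <= 0:
        return None
    ii, jj = np.unravel_index(int(np.argmax(H)), H.shape)  # first max, row-major
    i, j = int(ii), int(jj)

    cols: list[tuple[int | None, int | None]] = []
    state = "H"
    while H[i, j] > 0 or state != "H":
        if state == "H":
            # tie preference: diagonal, then up (consume query), then left
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + srow[i - 1, j - 1]:
                cols.append((i, j))
                i, j = i - 1, j - 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols.append((i, None))
            # prefer closing the gap (shorter gaps) on ties
            state = "H" if H[i - 1, j] - gap_first == F[i, j] else "F"
            i -= 1
        else:  # E
            cols.append((None, j))
            state = "H" if E[i, j] == H[i, j - 1] - gap_first else "E"
            j -= 1
    cols.reverse()

    qpos = [c[0] for c in cols if c[0] is not None]
    spos = [c[1] for c in cols if c[1] is not None]
    both = [(a, b) for a, b in cols if a is not None and b is not None]
    ident = sum(1 for a, b in both if query_seq[a - 1].upper() == subject_seq[b - 1].upper())
    identity_pct = 100.0 * ident / len(both) if both else 0.0
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=best,
        identity_pct=identity_pct,
        query_span=(qpos[0], qpos[-1]),
        subject_span=(spos[0], spos[-1]),
        columns=cols,
    )


@dataclass
class HitFilters:
    """Filter criteria for library hits (all configurable)."""

    min_identity_pct: float = 30.0
    min_query_coverage: float = 0.25
    cover_position: int | None = None  # query position that must map to a residue
    sources: tuple[str, ...] | None = None  # include-list; None = all


def search_library(
    query_seq: str,
    library: list[StructureSeqRecord],
    filters: HitFilters | None = None,
    params: AlignmentParams | None = None,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Align the query against every library record; filter and rank hits.

    Hits are sorted by score descending, ties by subject id.  An empty list
    is a valid result.
    """
    filters = filters or HitFilters()
    hits: list[AlignmentHit] = []
    for rec in library:
        if filters.sources is not None and rec.source not in filters.sources:
            continue
        hit = align_local(query_seq, rec.sequence, params, query_id, rec.id)
        if hit is None:
            continue
        hit.source = rec.source
        if hit.identity_pct < filters.min_identity_pct:
            continue
        if hit.query_coverage(len(query_seq)) < filters.min_query_coverage:
            continue
        if filters.cover_position is not None:
            mapped = map_query_position(hit, filters.cover_position)
            if mapped is NOT_COVERED or mapped is GAP:
                continue
        hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def map_query_position(hit: AlignmentHit, query_pos: int):
    """Subject SEQRES position aligned to ``query_pos``.

    Returns :data:`NOT_COVERED` outside the aligned span and :data:`GAP` when
    the position is aligned against a subject gap.
    """
    if query_pos < 1:
        return NOT_COVERED
    s, e = hit.query_span
    if not s <= query_pos <= e:
        return NOT_COVERED
    for qp, sp in hit.columns:
        if qp == query_pos:
            return sp if sp is not None else GAP
    return NOT_COVERED  # pragma: no cover - span guarantees a column exists


def query_to_structure_map(hit: AlignmentHit, smap: SeqresAtomMap) -> dict[int, object]:
    """query position -> author ResidueID (or UNRESOLVED) for aligned columns."""
    out: dict[int, object] = {}
    for qp, sp in hit.columns:
        if qp is None or sp is None:
            continue
        if 1 <= sp <= len(smap.entries):
            out[qp] = smap.entries[sp - 1]
    return out


def structure_to_query_map(hit: AlignmentHit, smap: SeqresAtomMap) -> dict:
    """author ResidueID -> query position (inverse bridge for annotation)."""
    out = {}
    for qp, rid in query_to_structure_map(hit, smap).items():
        if rid is not UNRESOLVED:
            out[rid] = qp
    return out


@dataclass
class ThreeWayAlignment:
    """Query vs subject-SEQRES vs subject-ATOM rows, plus a variant marker row.

    The ATOM row equals the SEQRES row with dashes substituted at positions
    whose SEQRES index is unresolved in the coordinates; the marker row
    carries ``^`` under the input variant position (empty if not covered).
    """

    query_row: str
    seqres_row: str
    atom_row: str
    marker_row: str
    query_start: int
    subject_start: int

    def text(self, width: int = 60) -> str:
        lines = []
        for off in range(0, len(self.query_row), width):
            sl = slice(off, off + width)
            lines.append(f"query  {self.query_row[sl]}")
            lines.append(f"seqres {self.seqres_row[sl]}")
            lines.append(f"atom   {self.atom_row[sl]}")
            if self.marker_row[sl].strip():
                lines.append(f"       {self.marker_row[sl]}")
            lines.append("")
        return "\n".join(lines)


def build_threeway(
    query_seq: str,
    hit: AlignmentHit,
    smap: SeqresAtomMap,
    variant_pos: int | None = None,
) -> ThreeWayAlignment:
    """Render the aligned region as the three-row display used for hits.

    Row one is the query, row two the subject SEQRES sequence and row three
    the resolved (ATOM) sequence where unresolved SEQRES positions appear as
    dashes -- missing loops and disordered regions simply vanish from it.
    The subject sequence is taken from :func:`attach_subject_sequence`.
    """
    q_row, s_row, a_row, m_row = [], [], [], []
    for qp, sp in hit.columns:
        q_row.append(query_seq[qp - 1] if qp is not None else "-")
        m_row.append("^" if (variant_pos is not None and qp == variant_pos) else " ")
        if sp is None:
            s_row.append("-")
            a_row.append("-")
        else:
            letter = hit_subject_letter(hit, sp)
            s_row.append(letter)
            unres = 1 <= sp <= len(smap.entries) and smap.entries[sp - 1] is UNRESOLVED
            a_row.append("-" if unres else letter)
    return ThreeWayAlignment(
        query_row="".join(q_row),
        seqres_row="".join(s_row),
        atom_row="".join(a_row),
        marker_row="".join(m_row),
        query_start=hit.query_span[0],
        subject_start=hit.subject_span[0],
    )


def hit_subject_letter(hit: AlignmentHit, sp: int) -> str:
    """Subject letter at 1-based position ``sp`` (cached on the hit)."""
    seq = getattr(hit, "_subject_seq", None)
    if seq is not None and 1 <= sp <= len(seq):
        return seq[sp - 1]
    return "?"


def attach_subject_sequence(hit: AlignmentHit, subject_seq: str) -> AlignmentHit:
    """Remember the subject sequence on the hit for rendering."""
    hit._subject_seq = subject_seq  # type: ignore[attr-defined]
    return hit


# ---------------------------------------------------------------------------
# library I/O
# ---------------------------------------------------------------------------

def load_library_fasta(path) -> list[StructureSeqRecord]:
    """Read a structure-sequence library FASTA.

    Headers encode ``id|chain|source|metadata``; the record id becomes
    ``"<id>_<chain>"``.  A bare header is treated as an experimental record.
    """
    from Bio import SeqIO

    records: list[StructureSeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.split()[0]
        parts = header.split("|")
        if len(parts) >= 2:
            sid = f"{parts[0]}_{parts[1]}"
            source = parts[2] if len(parts) >= 3 and parts[2] else EXPERIMENTAL
            meta = parts[3] if len(parts) >= 4 else ""
        else:
            sid, source, meta = header, EXPERIMENTAL, ""
        records.append(StructureSeqRecord(sid, str(rec.seq).upper(), source, meta))
    return records


def hits_to_tsv(hits: list[AlignmentHit], query_length: int) -> str:
    """Tabular export: query, subject, score, identity, spans, coverage."""
    lines = ["query\tsubject\tsource\tscore\tidentity_pct\tquery_span\tsubject_span\tcoverage"]
    for h in hits:
        qs, qe = h.query_span
        ss, se = h.subject_span
        lines.append(
            f"{h.query_id}\t{h.subject_id}\t{h.source}\t{h.score}\t"
            f"{h.identity_pct:.1f}\t{qs}-{qe}\t{ss}-{se}\t"
            f"{h.query_coverage(query_length):.3f}"
        )
    return "\n".join(lines) + "\n"
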