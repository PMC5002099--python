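"""Annotation tracks: variant databases, sequence motifs and conservation.

Variant tracks emulate the shape of ClinVar/COSMIC/dbSNP-style dumps coerced
to a closed class palette (pathogenic, cancer, common, catalytic, other);
motifs use a subset of the Prosite pattern grammar; conservation is a
per-residue 0-9 profile (HSSP-style), consumed rather than computed.  The
neighborhood report overlays all three onto a residue contact table, mapping
structure residues back to query protein positions through the alignment and
SEQRES->ATOM bridges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .contacts import ResidueContactTable
from .errors import GrammarError, InputError, ParseError
from .genecoord import GenomicVariant, TranscriptModel, genomic_variant_to_protein

VARIANT_CLASSES = ("pathogenic", "cancer", "common", "catalytic", "other")


@dataclass(frozen=True)
class VariantEntry:
    protein_id: str
    residue: int  # 1-based
    vclass: str
    source: str = ""
    note: str = ""

    def __post_init__(self):
        if self.residue < 1:
            raise InputError(f"residue index must be >= 1, got {self.residue}")
        if self.vclass not in VARIANT_CLASSES:
            raise InputError(
                f"class {self.vclass!r} not in {VARIANT_CLASSES}"
            )


@dataclass
class VariantTrack:
    entries: list[VariantEntry] = field(default_factory=list)
    unmappable: list[tuple[str, str]] = field(default_factory=list)  # (row, reason)

    def at(self, protein_id: str, residue: int) -> list[VariantEntry]:
        return [
            e
            for e in self.entries
            if e.residue == residue and (not e.protein_id or e.protein_id == protein_id)
        ]


def load_variant_track(
    path, transcripts: list[TranscriptModel] | None = None, build: str = "hg19"
) -> VariantTrack:
    """Read a variant track TSV in either dialect.

    Protein-space rows: ``protein_id  residue  class  [source  [note]]``.
    Genomic-space rows: ``chrom  pos  ref  alt  class  [source  [note]]`` --
    these are pushed through the transcript models; rows that do not land in
    a CDS are recorded as unmappable, not fatal.  Dialect is detected per
    file from the header line (``protein_id`` vs ``chrom``).
    """
    track = VariantTrack()
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not lines:
        return track
    header = lines[0].lstrip("#").strip().split("\t")
    genomic = header[0].lower() in ("chrom", "chr", "chromosome")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            if genomic:
                if len(parts) < 5:
                    raise ParseError("genomic row needs >=5 columns", line=ln)
                chrom, pos, ref, alt, vclass = parts[:5]
                source = parts[5] if len(parts) > 5 else ""
                note = parts[6] if len(parts) > 6 else ""
                gv = GenomicVariant(chrom, int(pos), ref.upper(), alt.upper(), build)
                variants, skipped = genomic_variant_to_protein(transcripts or [], gv)
                if not variants:
                    why = "; ".join(s.reason for s in skipped) or "no transcript"
                    track.unmappable.append((line, why))
                    continue
                for pv in variants:
                    track.entries.append(
                        VariantEntry(pv.transcript_id, pv.protein_position, vclass, source, note)
                    )
            else:
                if len(parts) < 3:
                    raise ParseError("protein row needs >=3 columns", line=ln)
                pid, pos, vclass = parts[:3]
                source = parts[3] if len(parts) > 3 else ""
                note = parts[4] if len(parts) > 4 else ""
                track.entries.append(VariantEntry(pid, int(pos), vclass, source, note))
        except (InputError, ValueError) as exc:
            track.unmappable.append((line, str(exc)))
    return track


# ---------------------------------------------------------------------------
# Prosite-style motif patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str


@dataclass(frozen=True)
class _Element:
    kind: str  # "exact" | "any" | "set" | "notset"
    letters: str
    min_rep: int
    max_rep: int


def _parse_pattern(pattern: str) -> tuple[bool, bool, list[_Element]]:
    """Parse the grammar subset: letters, x, [abc], {abc}, e(n), e(n,m), '-',
    anchors ``<`` and ``>``.  Raises :class:`GrammarError` with a position."""
    anchored_start = pattern.startswith("<")
    body = pattern[1:] if anchored_start else pattern
    anchored_end = body.endswith(">")
    if anchored_end:
        body = body[:-1]
    if not body:
        raise GrammarError("empty pattern", 0)
    elements: list[_Element] = []
    offset = (1 if anchored_start else 0)
    for tok in body.split("-"):
        pos = offset
        offset += len(tok) + 1
        if not tok:
            raise GrammarError("empty element", pos)
        m = re.fullmatch(r"(.+?)(?:\((\d+)(?:,(\d+))?\))?", tok)
        core, n, mx = m.group(1), m.group(2), m.group(3)
        min_rep = int(n) if n else 1
        max_rep = int(mx) if mx else min_rep
        if max_rep < min_rep:
            raise GrammarError(f"bad repeat range in {tok!r}", pos)
        if core == "x":
            elements.append(_Element("any", "", min_rep, max_rep))
        elif re.fullmatch(r"\[[A-Za-z]+\]", core):
            elements.append(_Element("set", core[1:-1].upper(), min_rep, max_rep))
        elif re.fullmatch(r"\{[A-Za-z]+\}", core):
            elements.append(_Element("notset", core[1:-1].upper(), min_rep, max_rep))
        elif re.fullmatch(r"[A-Za-z]", core):
            elements.append(_Element("exact", core.upper(), min_rep, max_rep))
        else:
            raise GrammarError(f"cannot parse element {tok!r}", pos)
    return anchored_start, anchored_end, elements


def _elem_matches(elem: _Element, ch: str) -> bool:
    if elem.kind == "any":
        return True
    if elem.kind == "exact" or elem.kind == "set":
        return ch in elem.letters
    return ch not in elem.letters  # notset


def _match_here(seq: str, i: int, elements: list[_Element], k: int, end_anchor: bool):
    """Backtracking match of elements[k:] at seq[i:]; returns end index or None.

    Repetitions are greedy (longest first), mirroring regex semantics.
    """
    if k == len(elements):
        if end_anchor and i != len(seq):
            return None
        return i
    elem = elements[k]
    # count how many consecutive characters can satisfy this element
    max_take = 0
    while (
        max_take < elem.max_rep
        and i + max_take < len(seq)
        and _elem_matches(elem, seq[i + max_take])
    ):
        max_take += 1
    for take in range(max_take, elem.min_rep - 1, -1):
        res = _match_here(seq, i + take, elements, k + 1, end_anchor)
        if res is not None:
            return res
    return None


def match_motifs(
    sequence: str, pattern: MotifPattern, all_matches: bool = False
) -> list[tuple[int, int]]:
    """Match a Prosite-style pattern; 1-based inclusive intervals.

    By default reports leftmost non-overlapping matches (configurable to all
    leftmost matches at every start).  Deterministic.
    """
    seq = sequence.upper()
    start_anchor, end_anchor, elements = _parse_pattern(pattern.pattern)
    out: list[tuple[int, int]] = []
    i = 0
    while i < len(seq):
        end = _match_here(seq, i, elements, 0, end_anchor)
        if end is not None and end > i:
            out.append((i + 1, end))
            i = i if all_matches else end - 1
        if start_anchor:
            break
        i += 1
    return out


def load_motifs_tsv(path) -> list[MotifPattern]:
    """``name<TAB>pattern`` per line; '#' comments allowed."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pat = line.split("\t")[:2]
            motifs.append(MotifPattern(name, pat))
    return motifs


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationTrack:
    """Per-residue integer conservation scores, 0 (variable) .. 9 (conserved)."""

    scores: list[int]

    def __post_init__(self):
        for s in self.scores:
            if not 0 <= s <= 9:
                raise InputError(f"conservation score {s} outside 0..9")

    def at(self, residue: int) -> int | None:
        if 1 <= residue <= len(self.scores):
            return self.scores[residue - 1]
        return None


def load_conservation_tsv(path, length: int | None = None) -> ConservationTrack:
    """Two-column TSV ``residue<TAB>score``; missing residues default to 0."""
    pairs = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos_s, score_s = line.split("\t")[:2]
            pairs[int(pos_s)] = int(score_s)
    n = length or (max(pairs) if pairs else 0)
    return ConservationTrack([pairs.get(i, 0) for i in range(1, n + 1)])


# ---------------------------------------------------------------------------
# neighborhood report
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedContactRow:
    partner: str
    partner_res_name: str
    query_position: int | None
    contact_area: float
    min_distance: float
    clash: bool
    labels: list[str]
    conservation: int | None


@dataclass
class NeighborhoodReport:
    input_query_position: int
    input_motifs: list[str]
    input_conservation: int | None
    rows: list[AnnotatedContactRow]
    class_counts: dict[str, int]


def neighborhood_report(
    contact_table: ResidueContactTable,
    tracks: list[VariantTrack],
    conservation: ConservationTrack | None,
    input_position: int,
    structure_to_query: dict,
    protein_id: str = "",
    motifs: list[MotifPattern] | None = None,
    query_sequence: str | None = None,
) -> NeighborhoodReport:
    """Overlay tracks/conservation/motifs on a residue contact table.

    ``structure_to_query`` maps author ResidueIDs back to query protein
    positions (see :func:`varstruct.homology.structure_to_query_map`); contact
    partners outside the alignment keep empty annotations.
    """
    input_motif_names: list[str] = []
    if motifs and query_sequence:
        for motif in motifs:
            for s, e in match_motifs(query_sequence, motif):
                if s <= input_position <= e:
                    input_motif_names.append(motif.name)
                    break
    rows: list[AnnotatedContactRow] = []
    counts: dict[str, int] = {}
    for row in contact_table.rows:
        qpos = structure_to_query.get(row.partner)
        labels: list[str] = []
        if qpos is not None:
            for track in tracks:
                for entry in track.at(protein_id, qpos):
                    labels.append(entry.vclass)
                    counts[entry.vclass] = counts.get(entry.vclass, 0) + 1
        rows.append(
            AnnotatedContactRow(
                partner=str(row.partner),
                partner_res_name=row.partner_res_name,
                query_position=qpos,
                contact_area=row.contact_area,
                min_distance=row.min_distance,
                clash=row.clash,
                labels=labels,
                conservation=conservation.at(qpos) if (conservation and qpos) else None,
            )
        )
    return NeighborhoodReport(
        input_query_position=input_position,
        input_motifs=input_motif_names,
        input_conservation=conservation.at(input_position) if conservation else None,
        rows=rows,
        class_counts=counts,
    )
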