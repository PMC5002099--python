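"""Genomic <-> CDS <-> protein coordinate conversion on transcript models.

A :class:`TranscriptModel` carries the ordered coding-exon intervals of a
transcript together with its spliced coding sequence.  Conversions follow the
usual conventions of variant annotation: all genomic and CDS coordinates are
1-based inclusive, residue indices are 1-based, the reference allele of a
genomic variant is always given on the forward genomic strand and is
complemented internally for minus-strand transcripts, and CDS position ``n``
lies in codon ``(n - 1) // 3 + 1``.

Only single-nucleotide substitutions are handled; indels raise
:class:`~varstruct.errors.IndelError`.  Genome builds are opaque labels that
must match between variant and transcript (no liftover).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    BuildMismatchError,
    IndelError,
    InputError,
    InvalidCodonError,
    NonCodingError,
    ParseError,
    RangeError,
    RefMismatchError,
)

STOP = "*"

#: Standard (NCBI table 1) genetic code.
GENETIC_CODE: dict[str, str] = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            GENETIC_CODE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

START_CODON = "ATG"


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate a single codon with the standard genetic code.

    Returns a one-letter amino acid, or ``"*"`` for a stop codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise InvalidCodonError(f"not a valid codon: {codon!r}")
    return GENETIC_CODE[codon]


def translate_cds(cds: str) -> str:
    """Translate a full CDS (length divisible by 3) into a protein string."""
    if len(cds) % 3 != 0:
        raise InputError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class GenomicVariant:
    """A single-nucleotide substitution in genome coordinates (forward strand)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    build: str = "hg19"

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise IndelError(
                f"only single-base substitutions supported, got {self.ref}>{self.alt}"
            )
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise InputError(f"alleles must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise InputError("ref and alt alleles are identical")


#: Consequence labels attached to a ProteinVariant.
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
NONSENSE = "nonsense"
START_LOSS = "start-loss"
STOP_LOSS = "stop-loss"


@dataclass(frozen=True)
class ProteinVariant:
    """A coding consequence of a nucleotide substitution."""

    transcript_id: str
    protein_position: int  # 1-based residue index
    ref_aa: str
    alt_aa: str
    cds_pos: int  # 1-based position within the CDS
    ref_codon: str
    alt_codon: str
    consequence: str = MISSENSE

    def __post_init__(self):
        assert self.protein_position == (self.cds_pos - 1) // 3 + 1
        assert translate_codon(self.ref_codon) == self.ref_aa
        assert translate_codon(self.alt_codon) == self.alt_aa
        assert sum(a != b for a, b in zip(self.ref_codon, self.alt_codon)) == 1

    def short(self) -> str:
        return f"{self.ref_aa}{self.protein_position}{self.alt_aa}"


@dataclass
class TranscriptModel:
    """Coding-exon model of one transcript.

    ``cds_exons`` are 1-based inclusive genomic intervals listed in
    *transcription order* (ascending genomic coordinates for ``+`` strand,
    descending for ``-``).  ``cds_sequence`` is the spliced coding sequence
    on the coding strand, 5'->3'.
    """

    transcript_id: str
    gene: str
    chrom: str
    build: str
    strand: str
    cds_exons: list[tuple[int, int]]
    cds_sequence: str
    partial: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds_sequence = self.cds_sequence.upper()
        exons = [(int(s), int(e)) for s, e in self.cds_exons]
        for s, e in exons:
            if s > e:
                raise InputError(f"exon interval {s}-{e} reversed")
        by_start = sorted(exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 <= e1:
                raise InputError("exons overlap")
        expect = by_start if self.strand == "+" else by_start[::-1]
        if exons != expect:
            raise InputError("exons not in transcription order")
        self.cds_exons = exons
        total = sum(e - s + 1 for s, e in exons)
        if total != len(self.cds_sequence):
            raise InputError(
                f"exon lengths sum to {total} but CDS has {len(self.cds_sequence)} nt"
            )
        if not self.partial:
            if len(self.cds_sequence) % 3 != 0:
                raise InputError("CDS length not divisible by 3 (flag partial=True?)")
            if not self.cds_sequence.startswith(START_CODON):
                raise InputError("CDS does not start with ATG (flag partial=True?)")

    # -- derived -----------------------------------------------------------
    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    def protein_sequence(self) -> str:
        return translate_cds(self.cds_sequence)

    def genomic_positions(self) -> list[int]:
        """Genomic position of every CDS base, in transcription order."""
        out: list[int] = []
        for s, e in self.cds_exons:
            if self.strand == "+":
                out.extend(range(s, e + 1))
            else:
                out.extend(range(e, s - 1, -1))
        return out

    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.cds_exons]
        ends = [e for _, e in self.cds_exons]
        return min(starts), max(ends)


def genomic_to_cds(tm: TranscriptModel, chrom: str, pos: int, build: str | None = None) -> int:
    """Map a genomic position to its 1-based CDS position on ``tm``.

    Raises :class:`BuildMismatchError` on build disagreement and
    :class:`NonCodingError` (region ``"intronic"`` or ``"outside"``) when the
    position is not inside a coding exon.
    """
    if build is not None and build != tm.build:
        raise BuildMismatchError(
            f"variant build {build!r} != transcript build {tm.build!r}"
        )
    if chrom != tm.chrom:
        raise NonCodingError(
            f"{chrom}:{pos} not on transcript chromosome {tm.chrom}", region="outside"
        )
    offset = 0
    for s, e in tm.cds_exons:
        if s <= pos <= e:
            if tm.strand == "+":
                return offset + (pos - s + 1)
            return offset + (e - pos + 1)
        offset += e - s + 1
    lo, hi = tm.span()
    region = "intronic" if lo <= pos <= hi else "outside"
    raise NonCodingError(f"{chrom}:{pos} is {region} for {tm.transcript_id}", region=region)


def protein_to_genomic(tm: TranscriptModel, protein_position: int) -> tuple[int, int, int]:
    """Genomic positions of the three codon bases, in transcription order.

    For minus-strand transcripts the returned positions descend along the
    genome.  ``genomic_to_cds`` of the three positions yields CDS positions
    ``3p-2, 3p-1, 3p``.
    """
    if not 1 <= protein_position <= tm.protein_length:
        raise RangeError(
            f"protein position {protein_position} outside 1..{tm.protein_length}"
        )
    allpos = tm.genomic_positions()
    i = 3 * (protein_position - 1)
    return allpos[i], allpos[i + 1], allpos[i + 2]


def cds_variant_to_protein(
    tm: TranscriptModel, cds_pos: int, ref_cds_base: str, alt_cds_base: str
) -> ProteinVariant:
    """Apply a substitution at a CDS position and report its protein consequence."""
    if not 1 <= cds_pos <= tm.cds_length:
        raise RangeError(f"CDS position {cds_pos} outside 1..{tm.cds_length}")
    ref_cds_base = ref_cds_base.upper()
    alt_cds_base = alt_cds_base.upper()
    if len(ref_cds_base) != 1 or len(alt_cds_base) != 1:
        raise IndelError("only single-base substitutions supported")
    have = tm.cds_sequence[cds_pos - 1]
    if have != ref_cds_base:
        raise RefMismatchError(
            f"{tm.transcript_id} CDS position {cds_pos}: expected {have}, given {ref_cds_base}",
            expected=have,
            given=ref_cds_base,
        )
    codon_idx = (cds_pos - 1) // 3  # 0-based
    within = (cds_pos - 1) % 3
    ref_codon = tm.cds_sequence[3 * codon_idx : 3 * codon_idx + 3]
    alt_codon = ref_codon[:within] + alt_cds_base + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if codon_idx == 0 and ref_codon == START_CODON and alt_codon != START_CODON:
        consequence = START_LOSS
    elif alt_aa == STOP and ref_aa != STOP:
        consequence = NONSENSE
    elif ref_aa == STOP and alt_aa != STOP:
        consequence = STOP_LOSS
    elif alt_aa == ref_aa:
        consequence = SYNONYMOUS
    else:
        consequence = MISSENSE
    return ProteinVariant(
        transcript_id=tm.transcript_id,
        protein_position=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        cds_pos=cds_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        consequence=consequence,
    )


@dataclass
class SkippedTranscript:
    """Record of why a candidate transcript produced no protein variant."""

    transcript_id: str
    reason: str


def genomic_variant_to_protein(
    tms: list[TranscriptModel], gv: GenomicVariant
) -> tuple[list[ProteinVariant], list[SkippedTranscript]]:
    """Map one genomic variant through every overlapping transcript.

    Returns the protein variants (one per transcript that covers the position)
    together with a record per skipped transcript (non-coding position, build
    mismatch, reference mismatch).  An empty result list is valid.
    """
    variants: list[ProteinVariant] = []
    skipped: list[SkippedTranscript] = []
    for tm in tms:
        try:
            cds_pos = genomic_to_cds(tm, gv.chrom, gv.pos, build=gv.build)
            ref, alt = gv.ref, gv.alt
            if tm.strand == "-":
                ref, alt = complement(ref), complement(alt)
            variants.append(cds_variant_to_protein(tm, cds_pos, ref, alt))
        except (NonCodingError, BuildMismatchError, RefMismatchError) as exc:
            skipped.append(SkippedTranscript(tm.transcript_id, str(exc)))
    return variants, skipped


# ---------------------------------------------------------------------------
# external interfaces
# ---------------------------------------------------------------------------

def load_transcript_table(tsv_path, cds_fasta_path) -> list[TranscriptModel]:
    """Read transcript models from the tabular interchange format.

    The TSV columns are ``transcript_id  gene  chrom  build  strand  exons``
    where ``exons`` is a comma-separated list of ``start-end`` intervals in
    transcription order; CDS sequences come from a FASTA keyed by
    transcript_id.
    """
    from Bio import SeqIO

    cds = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}
    models: list[TranscriptModel] = []
    with open(tsv_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"expected >=6 tab-separated columns, got {len(parts)}", line=ln)
            tid, gene, chrom, build, strand, exons_str = parts[:6]
            try:
                exons = [
                    (int(a), int(b))
                    for a, b in (iv.split("-") for iv in exons_str.split(","))
                ]
            except ValueError as exc:
                raise ParseError(f"bad exon list {exons_str!r}: {exc}", line=ln) from exc
            if tid not in cds:
                raise ParseError(f"transcript {tid} missing from CDS FASTA", line=ln)
            models.append(
                TranscriptModel(tid, gene, chrom, build, strand, exons, cds[tid])
            )
    return models


def parse_vcf_variants(path, build: str = "hg19") -> list[GenomicVariant]:
    """Read substitutions from a minimal VCF (CHROM POS ID REF ALT ...).

    Header lines (``#``) are skipped; multi-allelic ALT fields are split;
    non-SNV alleles raise :class:`IndelError`.
    """
    out: list[GenomicVariant] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError("fewer than 5 VCF columns", line=ln)
            chrom, pos, _id, ref, alts = parts[:5]
            for alt in alts.split(","):
                out.append(GenomicVariant(chrom, int(pos), ref.upper(), alt.upper(), build))
    return out


def parse_protein_variant_spec(spec: str) -> tuple[str, int, str, str]:
    """Parse ``"PROTEIN:pos:REF>ALT"`` into (protein_id, pos, ref_aa, alt_aa)."""
    try:
        pid, pos_s, change = spec.split(":")
        ref_aa, alt_aa = change.split(">")
        pos = int(pos_s)
    except ValueError as exc:
        raise InputError(f"cannot parse protein variant spec {spec!r}") from exc
    if pos < 1 or len(ref_aa) != 1 or len(alt_aa) != 1:
        raise InputError(f"cannot parse protein variant spec {spec!r}")
    return pid, pos, ref_aa.upper(), alt_aa.upper()
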