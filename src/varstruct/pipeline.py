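"""End-to-end pipeline: variant -> protein -> structure hits -> analyses.

Stages run in order: coordinate conversion (genomic input only), library
search, SEQRES->ATOM mapping, mutant side-chain modelling, contact-surface
and clash analysis, annotation overlay.  A failure in one hit's analysis is
recorded on that hit and the pipeline continues with the remaining hits; a
variant with no coding consequence yields an explicit report rather than an
error.  Reports serialize to JSON (validated by the shipped schema, which is
generated from these pydantic models) and to human-readable text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pydantic import BaseModel

from . import annotate as _annotate
from . import contacts as _contacts
from . import genecoord as _gene
from . import homology as _hom
from . import mutator as _mut
from . import structlib as _struct
from .errors import InputError

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    probe_radius: float = 1.4
    clash_tolerance: float = 0.4
    min_identity_pct: float = 30.0
    min_query_coverage: float = 0.25
    n_surface_points: int = 24000
    require_position_covered: bool = True
    sources: tuple[str, ...] | None = None
    model_mutant: bool = True
    max_hits: int | None = None

    def radii(self) -> _contacts.RadiiTable:
        return _contacts.RadiiTable(probe_radius=self.probe_radius)


def load_config(path) -> PipelineConfig:
    """Read ``key=value`` overrides (unknown keys rejected)."""
    cfg = PipelineConfig()
    import dataclasses

    valid = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"config line {ln}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise InputError(f"config line {ln}: unknown key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            elif key == "sources":
                setattr(cfg, key, tuple(v.strip() for v in value.split(",")))
            else:  # pragma: no cover
                setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# report models (pydantic; the JSON schema ships as package data)
# ---------------------------------------------------------------------------

class VariantReport(BaseModel):
    transcript_id: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    cds_pos: int
    ref_codon: str
    alt_codon: str
    consequence: str


class GenomicInputReport(BaseModel):
    chrom: str
    pos: int
    ref: str
    alt: str
    build: str


class ContactRowReport(BaseModel):
    partner: str
    partner_res_name: str
    query_position: int | None = None
    contact_area: float
    min_distance: float
    clash: bool
    labels: list[str] = []
    conservation: int | None = None


class ClashReport(BaseModel):
    partner: str
    res_name: str
    min_distance: float
    vdw_sum: float
    atom_pair: list[str]


class MutationReport(BaseModel):
    new_res_name: str
    rotamer_index: int
    chi: list[float]
    steric_score: float
    clashes: list[ClashReport]
    warnings: list[str] = []


class ThreeWayReport(BaseModel):
    query_row: str
    seqres_row: str
    atom_row: str
    marker_row: str


class HitReport(BaseModel):
    subject_id: str
    source: str
    score: int
    identity_pct: float
    query_span: list[int]
    subject_span: list[int]
    coverage: float
    subject_seqres_position: int | None = None
    structure_residue: str | None = None
    unresolved: bool = False
    skipped_reason: str | None = None
    threeway: ThreeWayReport | None = None
    wt_sasa: float | None = None
    mut_sasa: float | None = None
    contact_table: list[ContactRowReport] = []
    mutation: MutationReport | None = None
    class_counts: dict[str, int] = {}
    input_motifs: list[str] = []
    input_conservation: int | None = None
    error: str | None = None


class IsoformReport(BaseModel):
    variant: VariantReport
    hits: list[HitReport] = []


class PipelineReport(BaseModel):
    status: str  # "ok" | "no_coding_consequence"
    genomic_input: GenomicInputReport | None = None
    skipped_transcripts: list[str] = []
    isoforms: list[IsoformReport] = []

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    def to_text(self) -> str:
        lines = [f"status: {self.status}"]
        if self.genomic_input is not None:
            g = self.genomic_input
            lines.append(f"input: {g.chrom}:{g.pos} {g.ref}>{g.alt} ({g.build})")
        for sk in self.skipped_transcripts:
            lines.append(f"skipped transcript: {sk}")
        for iso in self.isoforms:
            v = iso.variant
            lines.append(
                f"\n== {v.transcript_id}: {v.ref_aa}{v.protein_position}{v.alt_aa}"
                f" (c.{v.cds_pos}{v.ref_codon}>{v.alt_codon}, {v.consequence}) =="
            )
            for h in iso.hits:
                lines.append(
                    f"\nhit {h.subject_id} [{h.source}] score={h.score}"
                    f" identity={h.identity_pct:.1f}% coverage={h.coverage:.2f}"
                )
                if h.skipped_reason:
                    lines.append(f"  analysis skipped: {h.skipped_reason}")
                    continue
                if h.error:
                    lines.append(f"  analysis failed: {h.error}")
                    continue
                lines.append(
                    f"  mapped residue: seqres {h.subject_seqres_position}"
                    f" -> {h.structure_residue}"
                )
                if h.threeway:
                    t = _hom.ThreeWayAlignment(
                        h.threeway.query_row, h.threeway.seqres_row,
                        h.threeway.atom_row, h.threeway.marker_row, 0, 0,
                    )
                    lines.append(t.text())
                for row in h.contact_table:
                    lab = f" [{','.join(row.labels)}]" if row.labels else ""
                    lines.append(
                        f"  contact {row.partner} {row.partner_res_name}"
                        f" area={row.contact_area:.1f}A2 mind={row.min_distance:.2f}A"
                        f"{' CLASH' if row.clash else ''}{lab}"
                    )
                if h.mutation:
                    m = h.mutation
                    lines.append(
                        f"  mutant {m.new_res_name} rotamer={m.rotamer_index}"
                        f" chi={m.chi} score={m.steric_score:.3f}"
                        f" clashes={len(m.clashes)}"
                    )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    transcripts: list = field(default_factory=list)
    library: list = field(default_factory=list)
    structures: dict = field(default_factory=dict)  # subject_id -> Structure|pdb text
    tracks: list = field(default_factory=list)
    conservation: _annotate.ConservationTrack | None = None
    motifs: list = field(default_factory=list)


def _get_structure(inputs: PipelineInputs, subject_id: str) -> _struct.Structure:
    obj = inputs.structures[subject_id]
    if isinstance(obj, str):
        obj = _struct.parse_structure(obj, name=subject_id)
        inputs.structures[subject_id] = obj
    return obj


def _chain_of(subject_id: str, structure: _struct.Structure) -> _struct.ChainModel:
    chain_id = subject_id.rsplit("_", 1)[-1] if "_" in subject_id else None
    if chain_id and chain_id in structure.chains:
        return structure.chains[chain_id]
    return next(iter(structure.chains.values()))


def run_pipeline(
    variant: _gene.GenomicVariant | tuple[str, int, str, str],
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Execute the full analysis for one variant.

    ``variant`` is either a :class:`GenomicVariant` or a protein-space tuple
    ``(protein_id, position, ref_aa, alt_aa)`` where the protein id names a
    transcript.  Stage failures are captured per hit.
    """
    config = config or PipelineConfig()
    report = PipelineReport(status="ok")
    isoform_variants: list[tuple[_gene.TranscriptModel, _gene.ProteinVariant]] = []

    if isinstance(variant, _gene.GenomicVariant):
        report.genomic_input = GenomicInputReport(
            chrom=variant.chrom, pos=variant.pos, ref=variant.ref,
            alt=variant.alt, build=variant.build,
        )
        pvs, skipped = _gene.genomic_variant_to_protein(inputs.transcripts, variant)
        report.skipped_transcripts = [f"{s.transcript_id}: {s.reason}" for s in skipped]
        by_id = {tm.transcript_id: tm for tm in inputs.transcripts}
        isoform_variants = [(by_id[pv.transcript_id], pv) for pv in pvs]
        if not pvs:
            report.status = "no_coding_consequence"
            return report
    else:
        pid, pos, ref_aa, alt_aa = variant
        by_id = {tm.transcript_id: tm for tm in inputs.transcripts}
        if pid not in by_id:
            raise InputError(f"unknown protein/transcript id {pid!r}")
        tm = by_id[pid]
        prot = tm.protein_sequence().rstrip("*")
        if not 1 <= pos <= len(prot):
            raise InputError(f"position {pos} outside protein 1..{len(prot)}")
        if prot[pos - 1] != ref_aa:
            raise InputError(
                f"reference amino acid mismatch at {pos}: protein has {prot[pos - 1]}"
            )
        cds_pos = 3 * (pos - 1) + 1
        ref_codon = tm.cds_sequence[cds_pos - 1 : cds_pos + 2]
        alt_codon = _codon_for(ref_codon, alt_aa)
        pv = _gene.ProteinVariant(
            transcript_id=pid, protein_position=pos, ref_aa=ref_aa, alt_aa=alt_aa,
            cds_pos=cds_pos + _codon_diff_index(ref_codon, alt_codon),
            ref_codon=ref_codon, alt_codon=alt_codon,
        )
        isoform_variants = [(tm, pv)]

    for tm, pv in isoform_variants:
        iso = IsoformReport(
            variant=VariantReport(
                transcript_id=pv.transcript_id,
                protein_position=pv.protein_position,
                ref_aa=pv.ref_aa, alt_aa=pv.alt_aa, cds_pos=pv.cds_pos,
                ref_codon=pv.ref_codon, alt_codon=pv.alt_codon,
                consequence=pv.consequence,
            )
        )
        query_seq = tm.protein_sequence().rstrip("*")
        filters = _hom.HitFilters(
            min_identity_pct=config.min_identity_pct,
            min_query_coverage=config.min_query_coverage,
            cover_position=pv.protein_position if config.require_position_covered else None,
            sources=config.sources,
        )
        hits = _hom.search_library(
            query_seq, inputs.library, filters, query_id=pv.transcript_id
        )
        if config.max_hits is not None:
            hits = hits[: config.max_hits]
        seq_by_id = {rec.id: rec.sequence for rec in inputs.library}
        for hit in hits:
            _hom.attach_subject_sequence(hit, seq_by_id[hit.subject_id])
            iso.hits.append(_analyse_hit(hit, pv, query_seq, inputs, config))
        report.isoforms.append(iso)
    return report


def _codon_for(ref_codon: str, alt_aa: str) -> str:
    """Single-base codon change producing ``alt_aa``; first in codon order."""
    for i in range(3):
        for base in "ACGT":
            if base == ref_codon[i]:
                continue
            cand = ref_codon[:i] + base + ref_codon[i + 1 :]
            if _gene.translate_codon(cand) == alt_aa:
                return cand
    raise InputError(
        f"no single-base change of codon {ref_codon} produces {alt_aa}"
    )


def _codon_diff_index(a: str, b: str) -> int:
    return next(i for i in range(3) if a[i] != b[i])


def _analyse_hit(
    hit: _hom.AlignmentHit,
    pv: _gene.ProteinVariant,
    query_seq: str,
    inputs: PipelineInputs,
    config: PipelineConfig,
) -> HitReport:
    hr = HitReport(
        subject_id=hit.subject_id,
        source=hit.source,
        score=hit.score,
        identity_pct=round(hit.identity_pct, 2),
        query_span=list(hit.query_span),
        subject_span=list(hit.subject_span),
        coverage=round(hit.query_coverage(len(query_seq)), 4),
    )
    try:
        if hit.subject_id not in inputs.structures:
            hr.skipped_reason = "no coordinate file for this hit"
            return hr
        structure = _get_structure(inputs, hit.subject_id)
        chain = _chain_of(hit.subject_id, structure)
        smap = _struct.build_seqres_atom_map(chain)

        tw = _hom.build_threeway(query_seq, hit, smap, pv.protein_position)
        hr.threeway = ThreeWayReport(
            query_row=tw.query_row, seqres_row=tw.seqres_row,
            atom_row=tw.atom_row, marker_row=tw.marker_row,
        )
        mapped = _hom.map_query_position(hit, pv.protein_position)
        if mapped is _hom.NOT_COVERED or mapped is _hom.GAP:
            hr.skipped_reason = "variant position not aligned to the subject"
            return hr
        hr.subject_seqres_position = int(mapped)
        rid = _struct.resolve_seqres_index(smap, int(mapped))
        if rid is _struct.UNRESOLVED:
            hr.unresolved = True
            hr.skipped_reason = "variant position unresolved in the coordinates"
            return hr
        hr.structure_residue = str(rid)

        radii = config.radii()
        partitions = _contacts.partition_atom_surfaces(
            structure, radii, n_points=config.n_surface_points
        )
        wt_table = _contacts.residue_contact_table(
            partitions, structure, rid, radii, config.clash_tolerance
        )
        hr.wt_sasa = round(wt_table.target_sasa, 2)

        s2q = _hom.structure_to_query_map(hit, smap)
        nbr = _annotate.neighborhood_report(
            wt_table, inputs.tracks, inputs.conservation, pv.protein_position,
            s2q, protein_id=pv.transcript_id, motifs=inputs.motifs,
            query_sequence=query_seq,
        )
        hr.contact_table = [
            ContactRowReport(
                partner=r.partner, partner_res_name=r.partner_res_name,
                query_position=r.query_position,
                contact_area=round(r.contact_area, 2),
                min_distance=round(r.min_distance, 3),
                clash=r.clash, labels=r.labels, conservation=r.conservation,
            )
            for r in nbr.rows
        ]
        hr.class_counts = nbr.class_counts
        hr.input_motifs = nbr.input_motifs
        hr.input_conservation = nbr.input_conservation

        if config.model_mutant and pv.alt_aa in _struct.ONE_TO_THREE:
            result = _mut.mutate_residue(
                structure, rid, pv.alt_aa, radii=radii,
                clash_tolerance=config.clash_tolerance,
            )
            mut_partitions = _contacts.partition_atom_surfaces(
                result.structure, radii, n_points=config.n_surface_points
            )
            mut_table = _contacts.residue_contact_table(
                mut_partitions, result.structure, rid, radii, config.clash_tolerance
            )
            hr.mut_sasa = round(mut_table.target_sasa, 2)
            hr.mutation = MutationReport(
                new_res_name=result.new_res_name,
                rotamer_index=result.rotamer_index,
                chi=list(result.chi),
                steric_score=round(result.score, 4),
                clashes=[
                    ClashReport(
                        partner=str(c.partner), res_name=c.partner_res_name,
                        min_distance=round(c.min_distance, 3),
                        vdw_sum=round(c.vdw_sum, 3),
                        atom_pair=list(c.atom_pair),
                    )
                    for c in result.clashes
                ],
                warnings=result.warnings,
            )
    except Exception as exc:  # noqa: BLE001 - per-hit isolation is the contract
        hr.error = f"{type(exc).__name__}: {exc}"
    return hr


def report_json_schema() -> dict:
    """JSON schema of :class:`PipelineReport` (also shipped as package data)."""
    return PipelineReport.model_json_schema()
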