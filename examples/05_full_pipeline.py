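"""End-to-end: genomic variant -> protein -> structure hit -> full report.

Generates a toy transcript, an identical-sequence helix "structure" and a
small annotation track, then runs the whole pipeline.  The text report
walks through every stage: the coding consequence, the hit with its
three-way alignment, the mapped structure residue, the contact table with
annotation labels, and the modelled mutant.
"""

from varstruct import GenomicVariant, genomic_variant_to_protein
from varstruct.annotate import ConservationTrack, VariantEntry, VariantTrack
from varstruct.fixtures import make_helix_fixture, make_toy_transcript
from varstruct.homology import StructureSeqRecord
from varstruct.pipeline import PipelineConfig, PipelineInputs, run_pipeline

toy = make_toy_transcript(n_exons=2, strand="+", seed=31, n_codons=20)
tm = toy.tm
protein = tm.protein_sequence().rstrip("*")

# first genomic substitution that is missense in the middle of the protein
gv = None
for gpos in sorted(toy.cds_pos_of_genomic):
    ref = toy.chrom_seq[gpos - 1]
    for alt in "ACGT":
        if alt == ref:
            continue
        cand = GenomicVariant(tm.chrom, gpos, ref, alt, tm.build)
        pvs, _ = genomic_variant_to_protein([tm], cand)
        if pvs and pvs[0].consequence == "missense" and 6 <= pvs[0].protein_position <= 15:
            gv = cand
            break
    if gv:
        break

inputs = PipelineInputs(
    transcripts=[tm],
    library=[StructureSeqRecord("hlx1_A", protein)],
    structures={"hlx1_A": make_helix_fixture(protein)},
    tracks=[VariantTrack([VariantEntry(tm.transcript_id, 9, "pathogenic", "toydb")])],
    conservation=ConservationTrack([7] * len(protein)),
)
report = run_pipeline(gv, inputs, PipelineConfig(n_surface_points=8000))
print(report.to_text())
# status "ok" with one hit: the variant was coding, the library covered it,
# and contacts/mutation analyses ran on the mapped structure residue.
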