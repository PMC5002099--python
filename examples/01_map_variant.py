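"""Map a genomic substitution to CDS and protein coordinates.

Builds a toy transcript (two coding exons on the minus strand) and pushes a
genomic variant through it.  The printed line is the standard c./p. notation:
the CDS position of the substituted base, the codon change and the resulting
amino-acid change.
"""

from varstruct import GenomicVariant, genomic_variant_to_protein
from varstruct.fixtures import make_toy_transcript

toy = make_toy_transcript(n_exons=2, strand="-", seed=5, n_codons=30)
tm = toy.tm
print(f"transcript {tm.transcript_id}: {len(tm.cds_exons)} exons, "
      f"{tm.cds_length} nt CDS, strand {tm.strand}")

# pick a coding genomic position (via the fixture's enumeration oracle) whose
# substitution is missense
gv = None
for gpos, _cds in sorted(toy.cds_pos_of_genomic.items()):
    ref = toy.chrom_seq[gpos - 1]
    for alt in "ACGT":
        if alt == ref:
            continue
        cand = GenomicVariant(tm.chrom, gpos, ref, alt, tm.build)
        pvs, _ = genomic_variant_to_protein([tm], cand)
        if pvs and pvs[0].consequence == "missense":
            gv = cand
            break
    if gv:
        break

variants, skipped = genomic_variant_to_protein([tm], gv)
for pv in variants:
    print(f"{tm.chrom}:{gv.pos} {gv.ref}>{gv.alt}  ->  "
          f"c.{pv.cds_pos}{pv.ref_codon}>{pv.alt_codon}  "
          f"p.{pv.ref_aa}{pv.protein_position}{pv.alt_aa}  ({pv.consequence})")
# On the minus strand the genomic alleles are complemented before the codon
# is rebuilt; the protein position is the codon index of the CDS position.
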