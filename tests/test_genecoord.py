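"""Genomic <-> CDS <-> protein conversion."""

import numpy as np
import pytest

from varstruct import genecoord as gc
from varstruct.errors import (
    BuildMismatchError,
    IndelError,
    InputError,
    InvalidCodonError,
    NonCodingError,
    RangeError,
    RefMismatchError,
)
from varstruct.fixtures import make_toy_transcript

from _oracles import translation_diff_oracle


class TestTranslateCodon:
    def test_case_study_codons(self):
        assert gc.translate_codon("GCG") == "A"
        assert gc.translate_codon("ACG") == "T"
        assert gc.translate_codon("ATG") == "M"

    def test_stops_are_never_amino_acids(self):
        for codon in ("TAA", "TAG", "TGA"):
            assert gc.translate_codon(codon) == "*"

    def test_all_64_codons_match_independent_table(self):
        from Bio.Seq import Seq

        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    codon = b1 + b2 + b3
                    assert gc.translate_codon(codon) == str(Seq(codon).translate())

    @pytest.mark.parametrize("bad", ["AC", "ACGT", "ANG", "AC-"])
    def test_invalid_codons_rejected(self, bad):
        with pytest.raises(InvalidCodonError):
            gc.translate_codon(bad)


def _plus_transcript():
    # single exon 101..109, CDS ATGGCGTAA
    return gc.TranscriptModel(
        "T1", "G1", "chr1", "toy", "+", [(101, 109)], "ATGGCGTAA"
    )


def _minus_transcript():
    # exons in transcription order: (201,206) then (101,106); CDS = revcomp slices
    cds = gc.reverse_complement("AGGCAT") + gc.reverse_complement("GGCCAT")
    # make it a valid CDS: ATGCCT + ATGGCC
    assert cds == "ATGCCTATGGCC"
    return gc.TranscriptModel(
        "T2", "G2", "chr1", "toy", "-", [(201, 206), (101, 106)], cds
    )


class TestGenomicToCds:
    def test_first_base_plus_strand(self):
        assert gc.genomic_to_cds(_plus_transcript(), "chr1", 101) == 1

    def test_minus_strand_agrees_with_enumeration(self):
        tm = _minus_transcript()
        # enumerate: transcription order traverses exon (201,206) descending...
        expected = {}
        cds_idx = 1
        for s, e in tm.cds_exons:
            for pos in range(e, s - 1, -1):
                expected[pos] = cds_idx
                cds_idx += 1
        for pos, idx in expected.items():
            assert gc.genomic_to_cds(tm, "chr1", pos) == idx

    def test_build_mismatch(self):
        with pytest.raises(BuildMismatchError):
            gc.genomic_to_cds(_plus_transcript(), "chr1", 101, build="hg38")

    def test_intronic_vs_outside(self):
        tm = _minus_transcript()
        with pytest.raises(NonCodingError) as e1:
            gc.genomic_to_cds(tm, "chr1", 150)
        assert e1.value.region == "intronic"
        with pytest.raises(NonCodingError) as e2:
            gc.genomic_to_cds(tm, "chr1", 500)
        assert e2.value.region == "outside"


class TestCdsVariantToProtein:
    def test_start_loss(self):
        pv = gc.cds_variant_to_protein(_plus_transcript(), 1, "A", "G")
        assert pv.consequence == gc.START_LOSS
        assert pv.protein_position == 1

    def test_nonsense_flag(self):
        # codon 2 GCG -> TCG is missense; make a stop: TAA from GCG needs 2 subs,
        # use position 9 A of TAA? already stop; instead C5->A gives GAG? no.
        tm = gc.TranscriptModel("T", "G", "chr1", "toy", "+", [(1, 9)], "ATGTGGTAA")
        pv = tm and gc.cds_variant_to_protein(tm, 5, "G", "A")  # TGG -> TAG
        assert pv.consequence == gc.NONSENSE
        assert pv.alt_aa == "*"

    def test_ref_mismatch_reports_expected_and_given(self):
        with pytest.raises(RefMismatchError) as exc:
            gc.cds_variant_to_protein(_plus_transcript(), 4, "T", "A")
        assert exc.value.expected == "G"
        assert exc.value.given == "T"

    def test_random_substitutions_match_translation_diff(self):
        rng = np.random.default_rng(42)
        codons = [c for c, aa in gc.GENETIC_CODE.items() if aa != "*"]
        cds = "ATG" + "".join(
            codons[k] for k in rng.integers(0, len(codons), 98)
        ) + "TAA"
        tm = gc.TranscriptModel("TR", "G", "chr9", "toy", "+", [(1, 300)], cds)
        for _ in range(200):
            pos = int(rng.integers(1, 301))
            ref = cds[pos - 1]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            pv = gc.cds_variant_to_protein(tm, pos, ref, alt)
            mutant = cds[: pos - 1] + alt + cds[pos:]
            diff = translation_diff_oracle(cds, mutant)
            if diff is None:
                assert pv.consequence == gc.SYNONYMOUS
                assert pv.ref_aa == pv.alt_aa
            else:
                dpos, daa_ref, daa_alt = diff
                assert (pv.protein_position, pv.ref_aa, pv.alt_aa) == (
                    dpos, daa_ref, daa_alt,
                )


class TestGenomicVariantToProtein:
    def test_composition_plus_strand(self):
        tm = _plus_transcript()
        gv = gc.GenomicVariant("chr1", 104, "G", "A", "toy")
        variants, skipped = gc.genomic_variant_to_protein([tm], gv)
        assert not skipped
        cds_pos = gc.genomic_to_cds(tm, "chr1", 104)
        assert variants == [gc.cds_variant_to_protein(tm, cds_pos, "G", "A")]

    def test_minus_strand_sees_complement(self):
        tm = _minus_transcript()
        # genomic A>G at pos 205 -> CDS position 2, coding base T>C
        gv = gc.GenomicVariant("chr1", 205, "A", "G", "toy")
        variants, _ = gc.genomic_variant_to_protein([tm], gv)
        assert len(variants) == 1
        assert variants[0].cds_pos == 2
        assert variants[0].ref_codon[1] == "T"
        assert variants[0].alt_codon[1] == "C"

    def test_overlapping_isoforms_report_different_positions(self):
        t1 = make_toy_transcript(1, "+", seed=11, n_codons=30)
        tm1 = t1.tm
        s, e = tm1.cds_exons[0]
        # second isoform starts one codon downstream (same frame, shorter)
        tm2 = gc.TranscriptModel(
            "ISO2", tm1.gene, tm1.chrom, tm1.build, "+",
            [(s + 3, e)], tm1.cds_sequence[3:], partial=True,
        )
        pos = s + 10  # inside both
        ref = t1.chrom_seq[pos - 1]
        alt = "A" if ref != "A" else "G"
        gv = gc.GenomicVariant(tm1.chrom, pos, ref, alt, tm1.build)
        variants, _ = gc.genomic_variant_to_protein([tm1, tm2], gv)
        assert len(variants) == 2
        assert variants[0].protein_position == variants[1].protein_position + 1
        for tm, pv in zip((tm1, tm2), variants):
            mutant_cds = (
                tm.cds_sequence[: pv.cds_pos - 1]
                + pv.alt_codon[(pv.cds_pos - 1) % 3]
                + tm.cds_sequence[pv.cds_pos:]
            )
            diff = translation_diff_oracle(tm.cds_sequence, mutant_cds)
            if diff is not None:
                assert diff[0] == pv.protein_position

    def test_ref_mismatch_is_per_transcript_not_fatal(self):
        tm = _plus_transcript()
        gv = gc.GenomicVariant("chr1", 104, "C", "A", "toy")  # actual base is G
        variants, skipped = gc.genomic_variant_to_protein([tm], gv)
        assert variants == []
        assert len(skipped) == 1 and "expected" in skipped[0].reason


class TestProteinToGenomic:
    def test_plus_strand_first_codon(self):
        assert gc.protein_to_genomic(_plus_transcript(), 1) == (101, 102, 103)

    def test_minus_strand_descends(self):
        tm = _minus_transcript()
        pos = gc.protein_to_genomic(tm, 1)
        assert pos == (206, 205, 204)

    def test_round_trip_identity(self):
        for seed in range(5):
            for strand in "+-":
                tm = make_toy_transcript(3, strand, seed=seed).tm
                for p in range(1, tm.protein_length + 1):
                    g = gc.protein_to_genomic(tm, p)
                    cds = [gc.genomic_to_cds(tm, tm.chrom, x) for x in g]
                    assert cds == [3 * p - 2, 3 * p - 1, 3 * p]

    def test_out_of_range(self):
        with pytest.raises(RangeError):
            gc.protein_to_genomic(_plus_transcript(), 4)


def test_strand_symmetry_of_protein_variants():
    """Reverse-complementing the genome and flipping strand/intervals leaves
    every protein-level consequence unchanged."""
    toy = make_toy_transcript(3, "+", seed=7, n_codons=25)
    tm = toy.tm
    L = len(toy.chrom_seq)
    flipped = gc.TranscriptModel(
        tm.transcript_id, tm.gene, tm.chrom, tm.build, "-",
        [(L - e + 1, L - s + 1) for s, e in tm.cds_exons],
        tm.cds_sequence,
    )
    rng = np.random.default_rng(3)
    for gpos, cpos in list(toy.cds_pos_of_genomic.items())[::7]:
        ref = toy.chrom_seq[gpos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        gv = gc.GenomicVariant(tm.chrom, gpos, ref, alt, tm.build)
        gv_flip = gc.GenomicVariant(
            tm.chrom, L - gpos + 1, gc.complement(ref), gc.complement(alt), tm.build
        )
        v1, _ = gc.genomic_variant_to_protein([tm], gv)
        v2, _ = gc.genomic_variant_to_protein([flipped], gv_flip)
        assert v1 == v2


class TestExternalInterfaces:
    def test_transcript_table_round_trip(self, tmp_path):
        toy = make_toy_transcript(2, "-", seed=13)
        (tmp_path / "t.tsv").write_text(toy.table_row() + "\n")
        (tmp_path / "c.fa").write_text(toy.cds_fasta())
        models = gc.load_transcript_table(tmp_path / "t.tsv", tmp_path / "c.fa")
        assert len(models) == 1
        assert models[0].cds_exons == toy.tm.cds_exons
        assert models[0].cds_sequence == toy.tm.cds_sequence

    def test_minimal_vcf(self, tmp_path):
        vcf = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\nchr1\t104\t.\tG\tA\n"
        p = tmp_path / "v.vcf"
        p.write_text(vcf)
        (variants,) = gc.parse_vcf_variants(p, build="toy")
        assert (variants.chrom, variants.pos, variants.ref, variants.alt) == (
            "chr1", 104, "G", "A",
        )

    def test_indels_rejected(self):
        with pytest.raises(IndelError):
            gc.GenomicVariant("chr1", 5, "AT", "A", "toy")

    def test_protein_variant_spec(self):
        assert gc.parse_protein_variant_spec("Q9UBC3:585:A>T") == ("Q9UBC3", 585, "A", "T")
        with pytest.raises(InputError):
            gc.parse_protein_variant_spec("oops")
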