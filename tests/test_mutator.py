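"""Side-chain construction, steric scoring and fixed-backbone mutation."""

import copy
import warnings

import numpy as np
import pytest

from varstruct import mutator as mt
from varstruct.contacts import RadiiTable
from varstruct.errors import IncompleteBackboneError, UnknownResidueError
from varstruct.geometry import bond_angle, dihedral
from varstruct.sidechains import (
    CHI_COUNTS,
    SIDE_CHAIN_TEMPLATES,
    atom_depths,
    default_rotamer_library,
)
from varstruct.structlib import ONE_TO_THREE, ResidueID, parse_structure, write_pdb

from conftest import atoms_structure
from _oracles import naive_steric_score


def ideal_backbone():
    return {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
        "C": np.array([2.009, 1.42, 0.0]),
    }


class TestBuildSideChain:
    def test_glycine_has_no_side_chain(self):
        assert mt.build_side_chain(ideal_backbone(), "GLY", ()) == []

    def test_alanine_cb_geometry(self):
        (name, element, cb), = mt.build_side_chain(ideal_backbone(), "ALA", ())
        assert name == "CB" and element == "C"
        bb = ideal_backbone()
        assert 1.52 <= np.linalg.norm(cb - bb["CA"]) <= 1.54
        assert 109.0 <= bond_angle(bb["N"], bb["CA"], cb) <= 112.0

    def test_cb_has_l_amino_acid_chirality(self):
        bb = ideal_backbone()
        (_n, _e, cb), = mt.build_side_chain(bb, "ALA", ())
        # improper C-N-CA-CB is about -120 deg for L residues (CCD convention)
        assert dihedral(bb["C"], bb["N"], bb["CA"], cb) == pytest.approx(-120.0, abs=3.0)

    @pytest.mark.parametrize("chi1", [-60.0, 60.0, 180.0, 47.5])
    def test_thr_chi1_round_trip(self, chi1):
        bb = ideal_backbone()
        atoms = {n: x for n, _e, x in mt.build_side_chain(bb, "THR", (chi1,))}
        measured = dihedral(bb["N"], bb["CA"], atoms["CB"], atoms["OG1"])
        assert measured == pytest.approx(chi1, abs=0.1)

    @pytest.mark.parametrize("aa", sorted(SIDE_CHAIN_TEMPLATES))
    def test_every_residue_type_builds(self, aa):
        chi = tuple([-60.0] * CHI_COUNTS[aa])
        atoms = mt.build_side_chain(ideal_backbone(), aa, chi)
        names = [n for n, _e, _x in atoms]
        if aa == "GLY":
            assert names == []
        else:
            assert names[0] == "CB"
            assert len(names) == len(set(names))
            # every bond to the template parent has a chemically sane length
            pos = {n: x for n, _e, x in atoms}
            pos.update(ideal_backbone())
            for rec in SIDE_CHAIN_TEMPLATES[aa]:
                d = np.linalg.norm(pos[rec[0]] - pos[rec[3]])
                assert 1.2 < d < 1.9

    def test_bond_geometry_close_to_reference_residues(self):
        """Bond lengths placed by the templates agree with the CCD ideal
        residue geometry (biotite's component dictionary) within 0.1 A."""
        import biotite.structure.info as info

        for aa in ("SER", "LEU", "ASP", "LYS", "PHE", "TRP"):
            ref = info.residue(aa)

            def ref_xyz(name):
                sel = ref.coord[ref.atom_name == name]
                return sel[0] if len(sel) else None

            chi = tuple([-60.0] * CHI_COUNTS[aa])
            pos = {n: x for n, _e, x in mt.build_side_chain(ideal_backbone(), aa, chi)}
            for rec in SIDE_CHAIN_TEMPLATES[aa]:
                a, b = ref_xyz(rec[0]), ref_xyz(rec[3])
                if a is None or b is None:
                    continue
                assert np.linalg.norm(pos[rec[0]] - pos[rec[3]]) == pytest.approx(
                    np.linalg.norm(a - b), abs=0.1
                )

    def test_missing_backbone_rejected(self):
        with pytest.raises(IncompleteBackboneError):
            mt.build_side_chain({"N": np.zeros(3), "CA": np.ones(3)}, "ALA", ())

    def test_atom_depths_follow_templates(self):
        d = atom_depths("LYS")
        assert d == {"CB": 1, "CG": 2, "CD": 3, "CE": 4, "NZ": 5}


class TestStericScore:
    def test_isolated_residue_scores_zero(self, polyala_helix):
        # helix ends are exposed; a small side chain at a terminus fits freely
        one = atoms_structure([(1, "N", "N", (0, 0, 0)),
                               (1, "CA", "C", (1.458, 0, 0)),
                               (1, "C", "C", (2.009, 1.42, 0))])
        res = one.chains["A"].residues[0]
        res.res_name = "ALA"
        cand = mt.build_side_chain(ideal_backbone(), "ALA", ())
        assert mt.steric_score(one, cand, ResidueID("A", 1), aa3="ALA") == 0.0

    def test_single_overlap_arithmetic(self):
        # one candidate carbon at d = vdW sum - 0.5 from one far environment C
        st = atoms_structure([
            (1, "N", "N", (0, 0, 0)), (1, "CA", "C", (1.458, 0, 0)),
            (1, "C", "C", (2.009, 1.42, 0)),
            (2, "CX", "C", (10.0, 0.0, 0.0)),
        ])
        st.chains["A"].residues[0].res_name = "GLY"
        cand = [("CB", "C", np.array([10.0 - (3.4 - 0.5), 0.0, 0.0]))]
        score = mt.steric_score(st, cand, ResidueID("A", 1), aa3="ALA")
        assert score == pytest.approx(0.25)

    def test_matches_naive_all_pairs_oracle(self, packed_pair):
        rid = ResidueID("A", 8)
        res = packed_pair.get_residue(rid)
        bb = {n: res.atom(n).xyz for n in ("N", "CA", "C")}
        for aa, chi in (("THR", (-60.0,)), ("LEU", (180.0, 60.0)), ("TRP", (-60.0, 90.0))):
            cand = mt.build_side_chain(bb, aa, chi)
            mine = mt.steric_score(packed_pair, cand, rid, aa3=aa)
            ref = naive_steric_score(packed_pair, cand, rid)
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-9)


class TestMutateResidue:
    def test_to_glycine_scores_zero_everywhere(self, polyala_helix):
        for res in polyala_helix.chains["A"].residues[2:10]:
            out = mt.mutate_residue(polyala_helix, res.rid, "G")
            assert out.score == 0.0
            assert out.structure.get_residue(res.rid).atoms == [
                a for a in out.structure.get_residue(res.rid).atoms
                if a.name in ("N", "CA", "C", "O")
            ]

    def test_backbone_bit_identical_and_only_target_changes(self, packed_pair):
        rid = ResidueID("A", 8)
        before = {
            (r.rid, a.name): a.xyz.copy() for r, a in packed_pair.iter_atoms()
        }
        out = mt.mutate_residue(packed_pair, rid, "T")
        after = {(r.rid, a.name): a.xyz for r, a in out.structure.iter_atoms()}
        for key, xyz in before.items():
            r, name = key
            if r == rid and name not in ("N", "CA", "C", "O"):
                continue
            assert np.array_equal(after[key], xyz)
        changed = {k for k in after if k not in before}
        assert all(k[0] == rid for k in changed)

    def test_choice_equals_exhaustive_enumeration(self, packed_pair):
        """The selected rotamer is the argmin of independently scored
        candidates (ties -> lowest index)."""
        rid = ResidueID("A", 8)
        res = packed_pair.get_residue(rid)
        bb = {n: res.atom(n).xyz for n in ("N", "CA", "C")}
        rotlib = default_rotamer_library()
        for aa1 in ("S", "T", "V", "L"):
            aa3 = ONE_TO_THREE[aa1]
            scores = []
            for chi in rotlib[aa3]:
                cand = mt.build_side_chain(bb, aa3, chi)
                scores.append(naive_steric_score(packed_pair, cand, rid))
            expect = int(np.argmin(scores))  # first minimum = lowest index
            out = mt.mutate_residue(packed_pair, rid, aa1)
            assert out.rotamer_index == expect

    def test_deterministic(self, packed_pair):
        rid = ResidueID("A", 8)
        a = mt.mutate_residue(packed_pair, rid, "W")
        b = mt.mutate_residue(packed_pair, rid, "W")
        assert a.rotamer_index == b.rotamer_index and a.chi == b.chi
        xa = [at.xyz for _r, at in a.structure.iter_atoms()]
        xb = [at.xyz for _r, at in b.structure.iter_atoms()]
        assert all(np.array_equal(p, q) for p, q in zip(xa, xb))

    def test_self_mutation_sanity(self, packed_pair):
        rid = ResidueID("A", 8)
        res = packed_pair.get_residue(rid)
        bb = {n: res.atom(n).xyz for n in ("N", "CA", "C")}
        out = mt.mutate_residue(packed_pair, rid, "A")
        assert out.new_res_name == "ALA"
        worst = max(
            mt.steric_score(packed_pair, mt.build_side_chain(bb, "ALA", ()), rid, aa3="ALA")
            for _ in range(1)
        )
        assert out.score <= worst + 1e-12

    def test_proline_warns(self, polyala_helix):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = mt.mutate_residue(polyala_helix, ResidueID("A", 6), "P")
        assert out.warnings and any("proline" in str(w.message) for w in caught)

    def test_unknown_type_rejected(self, polyala_helix):
        with pytest.raises(UnknownResidueError):
            mt.mutate_residue(polyala_helix, ResidueID("A", 6), "Z")

    def test_mutant_structure_round_trips_through_pdb(self, polyala_helix):
        out = mt.mutate_residue(polyala_helix, ResidueID("A", 6), "L")
        st = parse_structure(write_pdb(out.structure))
        assert st.chains["A"].seqres == "AAAAALAAAAAA"
        assert st.chains["A"].residues[5].res_name == "LEU"

    def test_larger_side_chain_in_packed_core_clashes(self, packed_pair):
        out = mt.mutate_residue(packed_pair, ResidueID("A", 8), "T")
        assert len(out.clashes) >= 1
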