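"""Sphere-surface partition, contact tables, clashes, wt/mut comparison."""

import numpy as np
import pytest

from varstruct import contacts as ct
from varstruct.errors import DegenerateGeometryError, UnknownResidueError
from varstruct.structlib import ResidueID

from conftest import atoms_structure, single_atom_structure
from _oracles import sphere_cap_sampling_oracle

RID1, RID2 = ResidueID("A", 1), ResidueID("A", 2)


def two_carbons(d):
    return atoms_structure(
        [(1, "C1", "C", (0.0, 0.0, 0.0)), (2, "C2", "C", (d, 0.0, 0.0))]
    )


class TestPartition:
    def test_isolated_atom_is_all_solvent(self):
        parts = ct.partition_atom_surfaces(single_atom_structure())
        p = parts[(RID1, "C1")]
        assert p.contacts == {}
        assert p.sasa == pytest.approx(4 * np.pi * 3.1**2)
        assert p.sasa == pytest.approx(120.76, abs=0.1)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_sphere_buried_area_matches_cap_and_sampling(self, d):
        R = 1.7 + 1.4
        parts = ct.partition_atom_surfaces(two_carbons(d), n_points=8000)
        area = parts[(RID1, "C1")].contacts[(RID2, "C2")]
        cap = 2 * np.pi * R * (R - d / 2)
        assert area == pytest.approx(cap, rel=0.005)
        sampled = sphere_cap_sampling_oracle((0, 0, 0), R, (d, 0, 0), R, 100_000)
        assert area == pytest.approx(sampled, rel=0.005)

    def test_fully_caged_atom_has_zero_sasa(self):
        spec = [(1, "C1", "C", (0.0, 0.0, 0.0))]
        offsets = [(2.0, 0, 0), (-2.0, 0, 0), (0, 2.0, 0), (0, -2.0, 0),
                   (0, 0, 2.0), (0, 0, -2.0)]
        for k, off in enumerate(offsets, start=2):
            spec.append((k, "S1", "S", off))
        parts = ct.partition_atom_surfaces(atoms_structure(spec))
        p = parts[(RID1, "C1")]
        assert p.sasa == 0.0
        assert sum(p.contacts.values()) == pytest.approx(p.total_area)

    def test_conservation_on_structured_fixture(self, helix12):
        parts = ct.partition_atom_surfaces(helix12, n_points=4000)
        for p in parts.values():
            assert p.sasa + sum(p.contacts.values()) == pytest.approx(
                p.total_area, rel=1e-9
            )
            assert p.sasa >= 0 and all(a >= 0 for a in p.contacts.values())

    def test_doubling_density_changes_areas_under_half_percent(self, helix12):
        """Doubling the default sampling density moves every atom-level area
        by < 0.5% of the atom's sphere and every residue-level reported area
        by < 0.5% relative."""
        a = ct.partition_atom_surfaces(helix12)
        b = ct.partition_atom_surfaces(helix12, n_points=48000)
        for key in a:
            yard = 0.005 * a[key].total_area
            assert abs(b[key].sasa - a[key].sasa) < yard
            for nb, area in a[key].contacts.items():
                assert abs(b[key].contacts.get(nb, 0.0) - area) < yard
        for res in helix12.iter_residues():
            ta = ct.residue_contact_table(a, helix12, res.rid)
            tb = ct.residue_contact_table(b, helix12, res.rid)
            pb = tb.partner_map()
            if ta.target_sasa > 1.0:
                assert tb.target_sasa == pytest.approx(ta.target_sasa, rel=0.005)
            for row in ta.rows:
                if row.contact_area > 1.0:
                    other = pb.get(row.partner)
                    assert other is not None
                    assert other.contact_area == pytest.approx(
                        row.contact_area, rel=0.005
                    )

    def test_far_atom_changes_nothing(self):
        near = ct.partition_atom_surfaces(two_carbons(2.5))
        spec = [(1, "C1", "C", (0.0, 0.0, 0.0)), (2, "C2", "C", (2.5, 0.0, 0.0)),
                (3, "C3", "C", (50.0, 0.0, 0.0))]
        far = ct.partition_atom_surfaces(atoms_structure(spec))
        p1, p2 = near[(RID1, "C1")], far[(RID1, "C1")]
        assert p1.sasa == p2.sasa
        assert p1.contacts == {k: v for k, v in p2.contacts.items()}

    def test_coincident_centers_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ct.partition_atom_surfaces(two_carbons(0.005))

    def test_agreement_with_independent_sasa_implementation(self, helix12):
        """Residue-level SASA within 5% of biotite's Shrake-Rupley."""
        import biotite.structure as bst

        residues = list(helix12.iter_residues())
        atoms = [(r, a) for r in residues for a in r.heavy_atoms()]
        arr = bst.AtomArray(len(atoms))
        arr.coord = np.array([a.xyz for _r, a in atoms], dtype=np.float32)
        arr.chain_id = np.array(["A"] * len(atoms))
        arr.res_id = np.array([r.rid.res_seq for r, _a in atoms])
        arr.res_name = np.array([r.res_name for r, _a in atoms])
        arr.atom_name = np.array([a.name for _r, a in atoms])
        arr.element = np.array([a.element for _r, a in atoms])
        ref = bst.sasa(arr, probe_radius=1.4, point_number=2000,
                       vdw_radii="Single")
        parts = ct.partition_atom_surfaces(helix12, n_points=8000)
        for res in residues:
            mine = sum(parts[(res.rid, a.name)].sasa for a in res.heavy_atoms())
            idx = [i for i, (r, _a) in enumerate(atoms) if r.rid == res.rid]
            theirs = float(np.sum(ref[idx]))
            if theirs > 5.0:
                assert mine == pytest.approx(theirs, rel=0.05)


class TestResidueTables:
    def test_dipeptide_aggregation_matches_partition_sums(self):
        st = two_carbons(2.8)
        parts = ct.partition_atom_surfaces(st)
        table = ct.residue_contact_table(parts, st, RID1)
        assert len(table.rows) == 1
        row = table.rows[0]
        assert row.partner == RID2
        assert row.contact_area == pytest.approx(
            parts[(RID1, "C1")].contacts[(RID2, "C2")]
        )
        assert row.min_distance == pytest.approx(2.8)

    def test_isolated_residue_has_empty_table(self):
        st = single_atom_structure()
        parts = ct.partition_atom_surfaces(st)
        table = ct.residue_contact_table(parts, st, RID1)
        assert table.rows == []

    def test_unknown_residue_rejected(self, helix12):
        parts = ct.partition_atom_surfaces(helix12, n_points=2000)
        with pytest.raises(UnknownResidueError):
            ct.residue_contact_table(parts, helix12, ResidueID("A", 99))

    def test_rows_sorted_by_area(self, helix12):
        parts = ct.partition_atom_surfaces(helix12, n_points=4000)
        table = ct.residue_contact_table(parts, helix12, ResidueID("A", 6))
        areas = [r.contact_area for r in table.rows]
        assert areas == sorted(areas, reverse=True)
        assert len(table.rows) > 0

    def test_atom_detail_sums_to_residue_area(self, helix12):
        parts = ct.partition_atom_surfaces(helix12, n_points=4000)
        table = ct.residue_contact_table(parts, helix12, ResidueID("A", 6))
        for row in table.rows:
            if row.contact_area == 0:
                continue
            detail = ct.atom_contact_detail(parts, helix12, ResidueID("A", 6), row.partner)
            assert sum(r.contact_area for r in detail) == pytest.approx(row.contact_area)

    def test_atom_detail_no_contact_is_empty(self):
        spec = [(1, "C1", "C", (0, 0, 0)), (2, "C2", "C", (30.0, 0, 0))]
        st = atoms_structure(spec)
        parts = ct.partition_atom_surfaces(st)
        assert ct.atom_contact_detail(parts, st, RID1, RID2) == []

    def test_symmetric_detail_uses_respective_spheres(self):
        st = atoms_structure(
            [(1, "C1", "C", (0, 0, 0)), (2, "O1", "O", (2.6, 0, 0))]
        )
        parts = ct.partition_atom_surfaces(st)
        ab = ct.atom_contact_detail(parts, st, RID1, RID2)
        ba = ct.atom_contact_detail(parts, st, RID2, RID1)
        assert {(r.atom_a, r.atom_b) for r in ab} == {("C1", "O1")}
        assert {(r.atom_a, r.atom_b) for r in ba} == {("O1", "C1")}
        # areas measured on different spheres need not be equal
        assert ab[0].distance == pytest.approx(ba[0].distance)


class TestClashes:
    def test_overlapping_carbons_clash(self):
        clashes = ct.detect_clashes(two_carbons(2.0), RID1)
        assert len(clashes) == 1
        assert clashes[0].min_distance == pytest.approx(2.0)
        assert clashes[0].vdw_sum == pytest.approx(3.4)

    def test_separated_carbons_do_not_clash(self):
        assert ct.detect_clashes(two_carbons(3.2), RID1) == []

    def test_bonded_neighbors_excluded(self, helix12):
        # peptide-bonded neighbors sit far below vdW sums yet never clash
        for res in helix12.chains["A"].residues[1:-1]:
            assert ct.detect_clashes(helix12, res.rid) == []


class TestCompareWtMut:
    def test_identical_structures_give_zero_deltas(self, helix12):
        parts = ct.partition_atom_surfaces(helix12, n_points=4000)
        t = ct.residue_contact_table(parts, helix12, ResidueID("A", 6))
        cmp = ct.compare_wt_mut(t, t)
        assert cmp.wt_sasa == cmp.mut_sasa
        for d in cmp.deltas:
            assert d.wt_area == d.mut_area
            assert not d.gained and not d.lost

    def test_ala_to_gly_uncovers_backbone_and_loses_cb_contacts(self, polyala_helix):
        """Removing CB can only expose the remaining atoms (per-atom SASA is
        monotone under neighbor removal) and drops the CB-mediated contacts."""
        from varstruct.mutator import mutate_residue

        rid = ResidueID("A", 6)
        parts = ct.partition_atom_surfaces(polyala_helix, n_points=8000)
        wt = ct.residue_contact_table(parts, polyala_helix, rid)
        res = mutate_residue(polyala_helix, rid, "G")
        mparts = ct.partition_atom_surfaces(res.structure, n_points=8000)
        mut = ct.residue_contact_table(mparts, res.structure, rid)
        for name in ("N", "CA", "C", "O"):
            assert mparts[(rid, name)].sasa >= parts[(rid, name)].sasa - 0.1
        cmp = ct.compare_wt_mut(wt, mut)
        # summed contact area shrinks once the CB sphere is gone
        assert sum(d.mut_area for d in cmp.deltas) < sum(d.wt_area for d in cmp.deltas)

    def test_mutant_clash_flagged_only_on_mut_side(self, packed_pair):
        from varstruct.mutator import mutate_residue

        rid = ResidueID("A", 8)
        parts = ct.partition_atom_surfaces(packed_pair, n_points=4000)
        wt = ct.residue_contact_table(parts, packed_pair, rid)
        res = mutate_residue(packed_pair, rid, "W")
        mparts = ct.partition_atom_surfaces(res.structure, n_points=4000)
        mut = ct.residue_contact_table(mparts, res.structure, rid)
        cmp = ct.compare_wt_mut(wt, mut)
        assert not any(d.wt_clash for d in cmp.deltas)
        assert any(d.mut_clash for d in cmp.deltas)

    def test_mismatched_targets_rejected(self, helix12):
        parts = ct.partition_atom_surfaces(helix12, n_points=2000)
        t1 = ct.residue_contact_table(parts, helix12, ResidueID("A", 5))
        t2 = ct.residue_contact_table(parts, helix12, ResidueID("A", 6))
        with pytest.raises(Exception):
            ct.compare_wt_mut(t1, t2)
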