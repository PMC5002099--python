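"""Model a mutant side chain on a fixed backbone and compare contacts.

Two parallel poly-Ala helices form a packed interface.  Mutating an
interface alanine to threonine builds every rotamer of the new side chain,
keeps the one with the least steric overlap, and reports clashes -- the
backbone never moves, so a larger residue in a tight pocket shows up as
clash partners rather than being relaxed away.
"""

from varstruct import (
    ResidueID,
    compare_wt_mut,
    detect_clashes,
    mutate_residue,
    partition_atom_surfaces,
    residue_contact_table,
)
from varstruct.fixtures import make_helix_pair_structure

pair = make_helix_pair_structure("A" * 14, "A" * 14, separation=9.0)
target = ResidueID("A", 8)

print("wild-type clashes:", len(detect_clashes(pair, target)))
result = mutate_residue(pair, target, "T")
print(f"Ala -> Thr: rotamer {result.rotamer_index} chi={result.chi} "
      f"steric score {result.score:.3f}")
for c in result.clashes:
    print(f"  clash with {c.partner} {c.partner_res_name}: "
          f"{c.min_distance:.2f} A < vdW sum {c.vdw_sum:.2f} A "
          f"({c.atom_pair[0]}-{c.atom_pair[1]})")

wt_parts = partition_atom_surfaces(pair)
mut_parts = partition_atom_surfaces(result.structure)
wt = residue_contact_table(wt_parts, pair, target)
mut = residue_contact_table(mut_parts, result.structure, target)
cmp = compare_wt_mut(wt, mut)
print(f"\ntarget SASA: wt {cmp.wt_sasa:.1f} -> mut {cmp.mut_sasa:.1f} A^2")
for d in cmp.deltas:
    flag = " CLASH(mut)" if d.mut_clash and not d.wt_clash else ""
    print(f"  {d.partner} {d.partner_res_name:>3s}: area {d.wt_area:6.2f} -> "
          f"{d.mut_area:6.2f} A^2{flag}")
# A clash appearing only on the mutant side signals strain the fixed-backbone
# model cannot absorb -- the physical protein would shift its backbone.
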