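"""Search a structure-sequence library and render a three-way alignment.

The library holds one close homolog (a mutated copy of the query's middle
domain) and one unrelated decoy.  The homolog is retrieved despite not being
identical; the three-row alignment shows the query, the hit's full sequence
(SEQRES) and the resolved part (ATOM) where a deleted loop appears as
dashes, with the variant position marked by a caret.
"""

import numpy as np

from varstruct import (
    HitFilters,
    StructureSeqRecord,
    build_seqres_atom_map,
    build_threeway,
    map_query_position,
    parse_structure,
    search_library,
)
from varstruct.homology import attach_subject_sequence
from varstruct.fixtures import make_helix_fixture

rng = np.random.default_rng(0)
AA = "ACDEFGHIKLMNPQRSTVWY"
query = "".join(AA[k] for k in rng.integers(0, 20, 60))

homolog = list(query[20:50])          # middle domain only
for i in range(0, 30, 5):
    homolog[i] = AA[int(rng.integers(0, 20))]
homolog = "".join(homolog)
decoy = "".join(AA[k] for k in rng.integers(0, 20, 40))

library = [
    StructureSeqRecord("homolog_A", homolog),
    StructureSeqRecord("decoy_A", decoy),
]
variant_pos = 35
hits = search_library(query, library, HitFilters(cover_position=variant_pos))
for h in hits:
    print(f"hit {h.subject_id}: score={h.score} identity={h.identity_pct:.1f}% "
          f"query span {h.query_span}")

# structure for the hit: helix with a deleted loop (unresolved residues 8-11)
pdb = make_helix_fixture(homolog, deleted=(8, 11))
chain = parse_structure(pdb).chains["A"]
smap = build_seqres_atom_map(chain)
hit = attach_subject_sequence(hits[0], homolog)
print(f"query {variant_pos} -> subject seqres {map_query_position(hit, variant_pos)}")
print(build_threeway(query, hit, smap, variant_pos).text())
# The dash run in the third row is the unresolved loop: those residues exist
# in the protein but have no coordinates in the structure.
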