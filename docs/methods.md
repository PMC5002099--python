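# Methods

This note records the models, conventions and numerical choices behind
varstruct, and what its synthetic fixtures do and do not establish about
real data.

## Coordinate conversion

Transcript models carry 1-based inclusive genomic intervals in
*transcription order* and the spliced coding sequence on the coding strand.
All conversions are exact integer arithmetic; the only modelling choices
are conventions:

- Reference alleles are always given on the forward genomic strand (VCF
  convention) and complemented internally for minus-strand transcripts.
- Only single-nucleotide substitutions are accepted; indels raise a
  dedicated error rather than being approximated.
- Genome builds are opaque labels that must match between variant and
  transcript; no liftover is attempted.
- When several isoforms overlap a position, all consequences are reported;
  the toolkit never silently picks a canonical isoform.
- Consequences are classified as missense / synonymous / nonsense /
  start-loss / stop-loss from the codon change alone; splice-site and UTR
  effects are out of scope.

## SEQRES → ATOM mapping

Structures are parsed with gemmi (PDB v3.3 fixed-column; first MODEL only).
Altloc groups collapse to the highest-occupancy conformer, ties broken
alphabetically; waters and non-polymer HETATM groups are dropped; MSE and
MODRES-listed residues map to their standard parent in one-letter space;
unknown residues become `X`. Author numbering (res_seq + insertion code) is
never assumed sequential or positive; ordering follows file order.

The SEQRES sequence is globally aligned to the resolved-residue sequence
with match +1, mismatch −10, gap −1 (X matches anything at 0), making gaps
cheap and mismatches nearly forbidden — numbering gaps are common in
crystal structures, real sequence mismatches rare. Aligned columns that do
mismatch are tolerated up to 5% of aligned columns (configurable), beyond
which mapping fails loudly. A homopolymeric chain with an internal deletion
is genuinely ambiguous under alignment (any gap placement is optimal);
fixtures for unresolved-region behaviour therefore use heterogeneous
sequences.

## Homology search

Smith–Waterman with affine gaps is implemented in-package (Gotoh recursion,
int32 DP) so the traceback tie policy can be fixed: prefer diagonal, then
the query-consuming move, then the subject-consuming move; the start cell
is the first maximum in row-major order; within a gap, closing beats
extending. Scoring defaults are BLOSUM62 with gap open 11 / extend 1 (a
length-*k* gap costs 11+*k*). Identity is computed over non-gap aligned
columns; coverage is aligned-query-span over query length. Defaults
(identity ≥30%, coverage ≥0.25) are this package's own choices and are
exposed as parameters. Ranking is by raw score (ties by subject id);
e-value statistics add nothing at library scales of tens of entries.
Theoretical models are ordinary library entries distinguished only by a
source tag.

## Surface partition

The contact-surface model assigns every point of an atom's probe-expanded
sphere (R = r_vdW + r_probe) to the neighbor whose expanded sphere contains
it with minimal power distance ‖p−c_j‖²−R_j², or to solvent. Evaluation is
numeric: a deterministic Fibonacci lattice, by default 24 000 points per
atom, with the lattice pole rotated onto the nearest-neighbor axis so the
dominant contact boundary coincides with the lattice's uniform-z
stratification (two-sphere areas are then accurate to ~0.03%, verified
against the closed-form cap 2πR(R−d/2)). Because every point lands in
exactly one bucket, SASA + Σ contacts = 4πR² to float round-off on every
atom. Ties in power distance go to the lower atom serial.

Convergence is stated against two yardsticks: doubling the density moves
atom-level areas by less than 0.5% *of the atom's sphere area*, and
residue-level reported areas above 1 Å² by less than 0.5% relative. A
per-area relative bound on sub-Å² slivers is not meaningful for any
sampling method at practical densities, which is why the absolute sphere
yardstick is used at atom level.

Radii are Bondi-style: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, default
1.70 Å; probe 1.4 Å; all configurable. Hydrogens are parsed and flagged but
excluded from all surface and clash analyses, since most crystal structures
lack them.

## Clash detection

Two atoms clash when d < r_vdW,i + r_vdW,j − tol with tol = 0.4 Å by
default. Covalent bonds are inferred from distance (d < r_cov,i + r_cov,j +
0.45 Å); pairs separated by three or fewer bonds (directly bonded, 1-3,
1-4) are exempt, which keeps peptide neighbors and geminal atoms out of the
clash list. The residue contact table lists partners with positive contact
area *or* a sub-threshold distance, so a clash-only partner is never
dropped.

## Side-chain modelling

Side chains are rebuilt from ideal internal coordinates (bond length, bond
angle, torsion per atom; NeRF placement) with CB placed from N/CA/C using
the L-amino-acid improper C-N-CA-CB ≈ −120°. The rotamer library is
deliberately compact and backbone-independent: every chi draws from the
staggered wells −60°/180°/+60° (proline instead has two approximate ring
puckers). Candidates are scored by the soft overlap penalty
Σ max(0, r_i+r_j−d_ij)² over candidate–environment heavy-atom pairs,
excluding intra-side-chain pairs and pairs within three covalent bonds
(computed exactly from template topology through the CA anchor); the
argmin wins, ties to the lowest rotamer index, making the choice fully
deterministic. The backbone and all other residues are bit-identical
before and after mutation.

Reduced fidelity is intentional and documented: production rotamer engines
use backbone-dependent statistical libraries and richer energy terms.
Within a fixed-backbone model, a strained best rotamer (positive score,
clash partners) is the *finding* — the physical protein would respond with
backbone shifts this model deliberately does not attempt. Aromatic and
proline ring closure is approximate (rings built atom-by-atom with fixed
torsions); proline mutations always carry a warning.

## Annotation

Variant tracks are coerced to five classes (pathogenic, cancer, common,
catalytic, other) with free-text sources, so any database dump can be
mapped into the schema; genomic-space rows are pushed through the
transcript models and unmappable rows are reported, not fatal. When one
residue carries several labels, all are attached — nothing is collapsed.
The motif matcher implements a Prosite-style grammar subset (letters, `x`,
`[..]`, `{..}`, `e(n)`, `e(n,m)`, anchors `<`/`>`) as a direct backtracking
scanner with greedy repetition, reporting leftmost non-overlapping matches
by default; tests hold it against a mechanical regex translation.
Conservation (0–9 per residue) is consumed, never computed.

## Synthetic fixtures and their scope

All tests run offline on generated data:

- **Ideal helices** (phi/psi best-fit to a requested rise/twist;
  CA–CA ≈ 3.8 Å) with optional deleted ranges (unresolved-loop fixtures)
  and author-numbering offsets. With ideal bond geometry the canonical
  1.5 Å/100° helix is approached to within a few hundredths of an Å in
  rise; the generator least-squares fits rather than failing.
- **Toy transcripts**: random exon structures with an ATG start, no
  internal stop, a final stop codon, on either strand; the genome assembly
  records an enumeration oracle (genomic position → CDS position) used to
  check the arithmetic independently.
- **A homolog case stand-in**: a 740-residue query whose C-terminal domain
  is covered by a ~70%-identical "structure" with author numbering offset
  +508 and an unresolved stretch, reproducing the shape of mapping a
  variant through a close homolog with offset ATOM numbering.
- **A packed two-helix interface** (parallel poly-Ala helices 9 Å apart)
  where the wild-type alanine is clash-free but any threonine rotamer
  clashes — the larger-side-chain-in-core scenario.

What passing these tests shows: the coordinate arithmetic, alignment
composition, surface partition and rotamer selection are internally
consistent and agree with independent oracles. What they do not show:
behaviour on real crystallographic pathologies (alternate conformation
networks, microheterogeneity, non-standard polymers), real rotamer
distributions, or real database dumps at scale.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in well under a minute on one CPU: 24 000 surface points per atom,
libraries of a handful of sequences, transcripts of 20–60 codons, 100-item
property batteries. All sizes are parameters and scale up without code
changes.

## Known limitations

- mmCIF input is not supported (PDB fixed-column only); only the first
  MODEL of NMR ensembles is read; biological assemblies are not expanded.
- No e-values, no profile/iterative search.
- No free-energy or stability estimation; clash lists and contact deltas
  are geometric observations only.
- The SEQRES↔ATOM map cannot disambiguate deletions inside homopolymeric
  runs (inherent to alignment-based mapping).
- Liftover between genome builds is out of scope; build labels must match.
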