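# Methods

## Molecular entities and their graphs

A chemical description is modelled as a set of *molecular entities*:
connected attributed graphs whose vertices are atoms (element, formal
charge, optional isotope, aromatic flag, implicit-hydrogen count) and
whose edges are bonds (integer order, aromatic flag). Implicit
hydrogens are part of the atom's colour, not vertices; explicit `[H]`
atoms written in the input remain vertices and are deliberately *not*
folded away — hydrogen-representation differences between descriptions
are exactly what the `sh` simplification exists to absorb. Entity sets
are kept distinct by canonical key, so a description is a set in the
mathematical sense.

Stereochemistry lives in two descriptor types rather than in the graph
itself:

* **Tetrahedral centres** store four attachments in a reference order
  plus a clockwise/counterclockwise parity. An attachment may be the
  `LONE_PAIR` sentinel (three-coordinate chiral S/N, lone pair as the
  fourth attachment) or the `IMPLICIT_H` sentinel (the bracket hydrogen
  of `[C@H]`). Sentinels keep the *graph* identical to the stereo-free
  spelling of the same molecule, so stripping the descriptor (`s@`)
  reconciles a chiral description with an achiral one — without the
  sentinel an explicit-H vertex would leak a second, spurious
  difference.
* **Double-bond configurations** store (substituent, substituent,
  cis|trans) relations across the bond. One relation determines the
  rest; the closure is computed on demand and inconsistent inputs are
  rejected.

## Stereo descriptors as subgraphs

Canonical labelling works on plain vertex-coloured graphs, so the
descriptors are flattened into auxiliary subgraphs:

* every substituent pair across a configured double bond is joined
  through a carrier vertex coloured "cis" or "trans" (four for a fully
  substituted bond);
* a tetrahedral centre emits one *enumeration-listing* vertex per
  clockwise enumeration of three attachments viewed from the fourth.
  The 12 valid enumerations form a coset of the alternating group A4:
  any input listing of the same spatial configuration produces the same
  12 orderings, the mirror image produces the complementary 12, which
  is why the encoding is input-order invariant and chirality-
  discriminating. Each enumeration vertex connects to the centre, to
  its viewing attachment, and to the three enumerated attachments
  through chains of one, two and three "dot" vertices that realise the
  first/second/third position labels in purely vertex-coloured form.

Bond attributes other than plain single covalent ride on carrier
vertices coloured (order, aromatic); default bonds stay direct edges,
which keeps the graphs small without losing discriminating power.

Cis/trans descriptors on double bonds inside rings of size ≤ 8 (the
`stereo_ring_cutoff`, configurable) are dropped when entities are
built: ring geometry fixes them, and descriptions differ arbitrarily in
whether they write them.

## Canonical labelling and keys

The labeller is an individualisation–refinement search: stable colour
refinement (1-WL) partitions vertices; the first non-singleton cell is
split by individualising each candidate in turn; the leaf with the
lexicographically smallest colour-partition + upper-triangular
adjacency certificate defines the canonical order. Automorphisms
discovered when two leaves produce equal certificates prune later
branches (orbit pruning restricted to generators fixing the current
individualisation prefix), which keeps even the pathological cases —
empty or complete same-coloured graphs, the 12-cycle — in milliseconds.
Tie-breaking is lowest-candidate-first, so certificates are
byte-stable: no hashing, no iteration-order dependence.

An entity's **canonical key** is its canonical SMILES: the writer runs
a depth-first traversal from the rank-0 atom, always descending into
the lowest-ranked unvisited neighbour, re-deriving chiral symbols from
the output neighbour order (permutation parity against the stored
descriptor) and solving a 2-colouring for the `/`–`\` markers of all
configured double bonds; if the first marker in the finished string is
`\`, all markers are flipped. Ring digits are emitted closures-first
and take the smallest free number; bond symbols appear on the opening
digit only. Equal keys imply isomorphic entities; `verify_isomorphic`
(VF2 with categorical colour matching, an independent code path from
the labeller) re-checks the implication and returns a witness atom
mapping.

Certificates are self-consistent, not byte-compatible with any
external canonicaliser; conformance is defined by the invariants
(equal certificate ⇔ isomorphic), which the test suite checks against
brute-force isomorphism on a thousand random coloured graphs.

### SMILES conventions

Lone-pair chiral centres follow the convention that the lone pair is
the *first* attachment when the chiral atom starts the SMILES and the
*second* otherwise. Note that RDKit resolves atom-initial lone-pair
centres the opposite way; the two toolkits therefore disagree on
`[S@](=O)(C)CC` (ours pairs it with `C[S@](=O)CC`). The bracket
hydrogen of a chiral atom occupies the position where it is written —
right after the preceding atom, or first if there is none.

Aromatic form is preferred on output; Kekulé input is never
aromatised (perceiving aromaticity is a different, heuristic problem).
The **conservative kekulisation filter** bridges the two conventions in
the one direction that is unambiguous: a ring that is entirely
aromatic, even-sized, chord-free and shares no atom with any other
SSSR ring (and has no aromatic bond leaving it) is rewritten with
alternating single/double bonds, the double phase anchored at the
lowest-canonical-rank atom's lower-ranked ring neighbour for
determinism. Everything else — fused systems, odd rings — is left
untouched, so the filter is idempotent and connectivity-preserving. It
is off by default (`--kekulise` to enable).

## The simplification lattice

The seven simplifications, in list order: `s@` (1) drop tetrahedral
descriptors, `sct` (2) drop double-bond configurations, `s±` (3) zero
formal charges, `sb` (4) set every bond order to 1, `sa` (5) clear
aromatic flags on atoms and bonds, `sh` (6) delete hydrogen vertices
and zero hydrogen counts (descriptors that referenced a removed or
implicit hydrogen go with them; an entity may split or vanish), `se`
(7) replace every element with the wildcard `*` and clear isotopes.

`bin()` encodes a combination as 7 binary digits with `s@` the least
significant (rightmost) digit. Combinations are ordered by category —
(1) H and atom types preserved, (2) H removed, (3) atom types removed —
then by member count, then by `bin()` value as a binary number; this
yields a strict total order over all 128 combinations beginning with
the empty set.

Comparison of two entity sets: remove key matches; then, for each
combination in order, apply it to pristine copies of the remaining
entities of both sides, recompute keys, collate within-set duplicates,
remove cross-side matches, and stop at the first combination leaving
nothing unmatched (recorded as minimal) or at a strict subset of keys
(verdict: superfluous entities). Exhausting the list is a mismatch.
Applying each combination to fresh copies, never cumulatively, is what
makes "minimal" well-defined. The subset test runs after every
combination, mirroring the remove-then-simplify loop of the workflow.

Duplicate search within one SMILES list reuses the same keys: records
with byte-identical input strings are collapsed first and reported as
false positives (identical input canonicalises identically, so they
carry no information about the method); the rest are grouped by the
canonical key of their entity set.

## SDF conversion rules

V2000 records are read with fixed-width parsing (whitespace fallback);
`M CHG` supersedes the atom-block charge column entirely, `M ISO`
assigns isotopes, and a declared atom or bond count above 999 is a
format violation (the format cannot express it). Implicit hydrogen
counts are filled to the default valence, shifted by formal charge
(N/P/B cations gain a bond, anions lose |charge|) — the molfile
convention.

**Chirality from geometry.** A candidate centre needs exactly four
*constitutionally distinct* neighbours; distinctness is judged by
connectivity-only canonical certificates of the four substituent
branches (root marked, stereo ignored). The *chiral volume* is the
tetrahedron volume of the four unit vectors from the centre,
`|det[u2−u1, u3−u1, u4−u1]|/6`: 0 for square-planar, ≈ 0.5132 for ideal
tetrahedral geometry. Centres with volume strictly greater than
0.25 ų (ties to non-chiral) become tetrahedral descriptors, parity
from the sign of the unnormalised determinant; the threshold sits
halfway between the two ideal geometries and separates the
almost-invariably square-planar four-coordinate Pd/Pt complexes from
genuine stereocentres.

**Coordination bonds** (V2000 type 8, "any", configurable) have no
SMILES equivalent. Each becomes a single covalent bond; if its
endpoints then carry non-zero charges of opposite signs, the order is
raised to the smaller absolute charge and both charges shrink in
magnitude by that order — total charge is conserved and no charge ever
crosses zero. Bonds are processed in ascending (metal index, partner
index) order in a single pass; iterating shared-ligand charge
consumption to a fixed point would be an alternative reading, but the
single pass is documented and deterministic.

## Name regularisation

Four rules, applied repeatedly until the name is stable (a later rule
can expose material for an earlier one): strip surrounding quotes and
terminating dots; remove mixture-proportion suffixes (trailing
`(2:1)`-style ratios, bare trailing ratios, and the word "solvate" —
the shipped regular expressions are documented approximations, the
depositions vary); convert `^...^` superscript notation to plain
locants; apply the spelling-fix table (shipped with
napthalen→naphthalen, extensible; replacements protect already-correct
occurrences so a fix whose output contains its input still settles).
Names with unbalanced parentheses are passed through but flagged —
they are errors, but fixing them needs a curator. A non-empty name is
never reduced to the empty string.

## Synthetic fixtures

The generator emulates small organic molecules as they appear in
curated crystal annotations: 4–12 heavy atoms from a C/N/O/S/halogen
palette, valence-respecting tree growth with occasional extra ring
closures, an aromatic benzene ring in ~30 % of molecules, double/triple
bond promotion (~25 % of eligible bonds), alkoxide/ammonium-style
charges (~15 % of eligible atoms) and stereo descriptors on half of
the eligible sites by default (`stereo_density`). All randomness comes
from the seed in the `FixtureSpec`; the same spec is byte-reproducible.
Idealised square-planar/tetrahedral/interpolated geometries are
generated for the chirality-from-coordinates rules, with the
tetrahedral arrangement matching a stored parity.

What the generator does *not* emulate: realistic conformers, fused
ring systems beyond one aromatic ring, organometallics, tautomerism,
or the error modes of real chemical perception. Passing tests
therefore demonstrate the correctness of the encodings, the labeller
and the comparison logic under controlled perturbations — not recall
on any real database.

## Problem sizes and numerical choices

The test suite and the acceptance script run the soundness sweep on
1000 random coloured graphs of ≤ 12 vertices (certificate equality
checked against VF2), key invariance under 100 relabellings per
molecule on an 8-molecule corpus, round trips on corpora of 25–30
molecules, and perturbation recovery with 8 molecules per
simplification — sizes chosen so the whole suite completes in seconds
while each property still has non-trivial witnesses. Floating-point
comparisons of chiral volumes use absolute tolerances (10⁻¹² for exact
zeros, 10⁻³ against the closed-form ideal value); everything else is
exact.

## Known limitations

* No aromaticity perception: Kekulé and aromatic inputs only meet
  through the kekulisation filter or the `sa`+`sb` simplifications.
* Allene/axial and square-planar/octahedral stereochemistry are not
  encoded; `@`/`@@` beyond tetrahedral (e.g. `@TH1` spellings, extended
  chirality) is not parsed.
* Polymers and periodic connectivity are out of scope (SMILES cannot
  express them).
* The comparison explains differences only through the seven global
  simplifications; it does not attempt substructure moves (e.g. a
  methyl attached at a different ring position) or missing-atom
  resolution beyond the subset verdict.
* Canonical certificates are stable across runs and platforms but are
  not interchangeable with nauty's or any other tool's numbering.
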