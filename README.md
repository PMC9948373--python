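# molcrosscheck

Cross-checking chemical descriptions by molecular-graph isomorphism.

Crystal structures are published with several partly redundant chemical
annotations — curated SMILES, chemical names, coordinate-derived
connectivity in SDF files — and these descriptions of the *same* crystal
frequently disagree in representation (aromatic vs. Kekulé form, missing
stereo markers, omitted charges or hydrogens) or in substance (wrong
atom types, superfluous solvent molecules). `molcrosscheck` reconciles
two such descriptions automatically and reports the *minimal* set of
chemical simplifications that explains their difference, for database
curators and publication pipelines that need to flag genuine errors
without drowning in notational noise.

## The method

Each description is a set of distinct **molecular entities** (connected
groups of atoms). An entity is encoded as a vertex-coloured simple
graph:

* atoms are vertices coloured by (element, charge, isotope, aromaticity,
  implicit-H count); bond attributes ride on inserted *carrier*
  vertices;
* the cis/trans configuration of a double bond joins substituents on
  opposite ends with "cis"/"trans"-labelled auxiliary edges (4 for a
  fully substituted bond);
* a tetrahedral centre contributes 12 *enumeration-listing* vertices —
  the clockwise enumerations of three attachments viewed from the
  fourth, one A4-coset of orderings — so the same configuration yields
  the same subgraph whatever the input atom order, and mirror images
  yield non-isomorphic subgraphs.

Graphs are canonically labelled by individualisation–refinement with
automorphism (orbit) pruning; equal certificates ⇔ isomorphic graphs,
and each entity gets a canonical SMILES **key** written in the canonical
atom order. Two entity sets are compared by keys. If they differ, all
2⁷ = 128 combinations of seven simplifications —

s@ chiral markers · sct cis/trans markers · s± charges · sb bond
orders→single · sa aromaticity · sh hydrogens · se atom types

— are applied to fresh copies in a fixed order (categories: keep H and
atom types → drop H → drop atom types; then by size, then by `bin()`
value, s@ the least significant digit). The first combination making
the remaining key sets equal is reported as minimal; entities of one
set that merge under a simplification (a racemate once chiral markers
are stripped) are collated; a strict key-subset terminates with a
"superfluous entities" verdict.

Supporting conventions implemented alongside: an OpenSMILES reader and
canonical writer (lone-pair chiral centres, "/" normalisation), a
conservative kekulisation filter for isolated even aromatic rings, SDF
V2000 conversion with the chiral-volume test (threshold 0.25 ų) and
metal-coordination-bond charge arithmetic, chemical-name regularisation,
and a seeded synthetic-molecule generator that makes the whole package
testable offline.

## Worked example

```python
>>> from molcrosscheck import parse_smiles, compare_entity_sets, EntitySet
>>> racemate = parse_smiles("N[C@@H](C)C(=O)O.N[C@H](C)C(=O)O")
>>> achiral  = parse_smiles("NC(C)C(=O)O")
>>> report = compare_entity_sets(racemate, achiral)
>>> report.verdict.value
'isomorphic-with-simplifications'
>>> str(report.minimal), report.minimal.encoding
('{s@}', '0000001')
>>> report.collations[0].merged_keys
['C([C@@H](C)N)(=O)O', 'C([C@H](C)N)(=O)O']
```

The two alanine enantiomers and the stereo-free spelling describe the
same constitution: stripping chiral markers (`s@`, the least drastic
simplification, encoding `0000001`) collates the racemic pair into one
entity and makes the sets identical — so the difference is explained by
missing stereochemistry, not by a structural error.

Command-line wrappers cover the common workflows: `smi-canonicalise
[--kekulise]`, `sdf2smi`, `molcompare A.smi B.smi --report out.json`,
`moldedupe list.smi`, `regularise-names`, `molfixtures`.

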