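"""Minimal-simplification comparison of molecular entity sets.

Two chemical descriptions of the same crystal are compared by canonical
keys.  When the key sets differ, both sides are subjected to *graph
simplifications* — removal of chiral markers, cis/trans markers, charges,
bond orders, aromaticity, hydrogens, or atom types — and all 2^7 = 128
combinations are tried in a fixed order of increasing drasticness.  The
first combination under which the remaining keys coincide is reported as
the minimal explanation of the difference.  Simplification may merge
entities of one set (e.g. the two enantiomers of a racemate once chiral
markers are stripped); such entities are *collated* back into one.  If
one side's keys ever become a strict subset of the other's, the larger
set has superfluous entities and the comparison stops with a ``subset``
verdict.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple, Union

import networkx as nx

from .canonical import canonical_key
from .molgraph import IMPLICIT_H, Atom, Bond, EntitySet, MolecularEntity
from .smiles_io import SmilesParseError, parse_smiles

__all__ = [
    "Simplification",
    "SimplificationSet",
    "all_combinations",
    "compare_combinations",
    "apply_simplifications",
    "compare_entity_sets",
    "ComparisonReport",
    "Verdict",
    "find_duplicates",
    "DuplicateReport",
]


class Simplification(Enum):
    """The seven graph simplifications, in their fixed list order."""

    CHIRALITY = ("s@", 1)       # remove chiral markers
    CIS_TRANS = ("sct", 2)      # remove cis/trans markers
    CHARGE = ("s±", 3)          # remove formal charges
    BOND_ORDERS = ("sb", 4)     # convert all bond orders to single covalent
    AROMATICITY = ("sa", 5)     # remove aromaticity settings
    HYDROGENS = ("sh", 6)       # remove hydrogen atoms
    ATOM_TYPES = ("se", 7)      # remove atom types

    def __init__(self, symbol: str, position: int) -> None:
        self.symbol = symbol
        self.position = position

    @classmethod
    def from_symbol(cls, symbol: str) -> "Simplification":
        for member in cls:
            if member.symbol == symbol:
                return member
        raise KeyError(symbol)


@total_ordering
@dataclass(frozen=True)
class SimplificationSet:
    """A combination of simplifications with its binary encoding.

    The encoding is a 7-character binary string where position 1 (chiral
    markers) is the least significant — rightmost — digit and position 7
    (atom types) the most significant.  Combinations fall into three
    categories: (1) hydrogen atoms and atom types preserved, (2)
    hydrogens removed but atom types preserved, (3) atom types removed.
    """

    members: FrozenSet[Simplification]

    @classmethod
    def of(cls, *members: Union[Simplification, str]) -> "SimplificationSet":
        resolved = frozenset(
            m if isinstance(m, Simplification) else Simplification.from_symbol(m)
            for m in members
        )
        return cls(resolved)

    @property
    def encoding(self) -> str:
        digits = ["0"] * 7
        for s in self.members:
            digits[7 - s.position] = "1"
        return "".join(digits)

    @property
    def value(self) -> int:
        return int(self.encoding, 2)

    @property
    def category(self) -> int:
        if Simplification.ATOM_TYPES in self.members:
            return 3
        if Simplification.HYDROGENS in self.members:
            return 2
        return 1

    @property
    def sort_key(self) -> Tuple[int, int, int]:
        return (self.category, len(self.members), self.value)

    def symbols(self) -> List[str]:
        return [s.symbol for s in sorted(self.members, key=lambda m: m.position)]

    def __lt__(self, other: "SimplificationSet") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return "{" + ",".join(self.symbols()) + "}"


def bin_encoding(s: SimplificationSet) -> str:
    """The bin() encoding: 7 binary digits, chiral-marker bit rightmost."""
    return s.encoding


def compare_combinations(a: SimplificationSet, b: SimplificationSet) -> int:
    """Application-order comparator: category, then size, then bin() value."""
    ka, kb = a.sort_key, b.sort_key
    return (ka > kb) - (ka < kb)


def all_combinations() -> List[SimplificationSet]:
    """All 128 combinations in application order (the empty set first)."""
    sets = [
        SimplificationSet(frozenset(combo))
        for r in range(8)
        for combo in itertools.combinations(Simplification, r)
    ]
    return sorted(sets, key=lambda s: s.sort_key)


# ---------------------------------------------------------------------------
# Applying simplifications
# ---------------------------------------------------------------------------


def _strip_hydrogens(entity: MolecularEntity) -> List[MolecularEntity]:
    """Drop explicit H vertices and implicit H counts; may split or empty."""
    keep = [i for i, atom in entity.atoms.items() if atom.element != "H"]
    removed = set(entity.atoms) - set(keep)
    out = MolecularEntity()
    for idx in sorted(keep):
        atom = entity.atoms[idx]
        out.add_atom(Atom(atom.element, atom.charge, atom.isotope, atom.aromatic, 0), idx)
    for (a, b), bond in entity.bonds.items():
        if a not in removed and b not in removed:
            out.add_bond(a, b, bond)
    for centre in entity.stereocentres.values():
        if centre.centre in removed:
            continue
        if any(n >= 0 and n in removed for n in centre.neighbours):
            continue  # descriptor referenced a removed atom
        if IMPLICIT_H in centre.neighbours:
            continue  # its implicit-H attachment is removed with the hydrogens
        out.add_stereocentre(centre)
    for key, config in entity.bond_configs.items():
        if key[0] in removed or key[1] in removed:
            continue
        kept_relations = frozenset(
            (x, y, rel)
            for x, y, rel in config.relations
            if x not in removed and y not in removed
        )
        if kept_relations:
            try:
                out.add_bond_config(type(config)(config.bond, kept_relations))
            except ValueError:
                pass  # configuration no longer determined once H substituents left
    if not out.atoms:
        return []
    components = sorted(sorted(c) for c in nx.connected_components(out.to_nx()))
    if len(components) == 1:
        return [out]
    split: List[MolecularEntity] = []
    for comp in components:
        member = set(comp)
        sub = MolecularEntity()
        for idx in comp:
            sub.add_atom(out.atoms[idx], idx)
        for (a, b), bond in out.bonds.items():
            if a in member:
                sub.add_bond(a, b, bond)
        for centre in out.stereocentres.values():
            if centre.centre in member:
                sub.add_stereocentre(centre)
        for key, config in out.bond_configs.items():
            if key[0] in member:
                sub.add_bond_config(config)
        split.append(sub)
    return split


def apply_simplifications(
    entity: MolecularEntity, s: SimplificationSet
) -> List[MolecularEntity]:
    """Apply a combination of simplifications to a fresh copy of ``entity``.

    Combinations are always applied to the pristine entity, never
    cumulatively.  Removing hydrogens can split an entity or make it
    vanish, so a list is returned (usually of length one).
    """
    out = entity.copy()
    m = s.members
    if Simplification.CHIRALITY in m:
        out.stereocentres.clear()
    if Simplification.CIS_TRANS in m:
        out.bond_configs.clear()
    if Simplification.CHARGE in m:
        for idx, atom in out.atoms.items():
            if atom.charge:
                out.set_atom(idx, Atom(atom.element, 0, atom.isotope, atom.aromatic, atom.hcount))
    if Simplification.BOND_ORDERS in m:
        for key, bond in out.bonds.items():
            if bond.order != 1:
                out.bonds[key] = Bond(order=1, aromatic=bond.aromatic)
    if Simplification.AROMATICITY in m:
        for idx, atom in out.atoms.items():
            if atom.aromatic:
                out.set_atom(idx, Atom(atom.element, atom.charge, atom.isotope, False, atom.hcount))
        for key, bond in out.bonds.items():
            if bond.aromatic:
                out.bonds[key] = Bond(order=bond.order, aromatic=False)
    if Simplification.ATOM_TYPES in m:
        for idx, atom in out.atoms.items():
            out.set_atom(idx, Atom("*", atom.charge, None, atom.aromatic, atom.hcount))
    if Simplification.HYDROGENS in m:
        return _strip_hydrogens(out)
    return [out]


# ---------------------------------------------------------------------------
# Entity-set comparison
# ---------------------------------------------------------------------------


class Verdict(str, Enum):
    IDENTICAL = "identical"
    SIMPLIFIED = "isomorphic-with-simplifications"
    SUBSET = "subset"
    MISMATCH = "mismatch"


@dataclass
class CollationEvent:
    """Entities of one side merged under a simplification combination."""

    side: str
    combination: SimplificationSet
    merged_keys: List[str]
    collated_key: str


@dataclass
class ComparisonReport:
    verdict: Verdict
    minimal: Optional[SimplificationSet]
    matched: List[str]
    unmatched_a: List[str]
    unmatched_b: List[str]
    collations: List[CollationEvent] = field(default_factory=list)
    simplified_matches: List[Tuple[str, List[str], List[str]]] = field(default_factory=list)
    subset_side: Optional[str] = None
    combinations_tried: int = 0

    def to_dict(self) -> Dict:
        return {
            "verdict": self.verdict.value,
            "minimal": None
            if self.minimal is None
            else {"symbols": self.minimal.symbols(), "bin": self.minimal.encoding},
            "matched": self.matched,
            "unmatched_a": self.unmatched_a,
            "unmatched_b": self.unmatched_b,
            "collations": [
                {
                    "side": c.side,
                    "combination": c.combination.symbols(),
                    "merged_keys": c.merged_keys,
                    "collated_key": c.collated_key,
                }
                for c in self.collations
            ],
            "simplified_matches": [
                {"key": k, "from_a": a, "from_b": b}
                for k, a, b in self.simplified_matches
            ],
            "subset_side": self.subset_side,
            "combinations_tried": self.combinations_tried,
        }


def _simplified_keys(
    remaining: Dict[str, MolecularEntity], combo: SimplificationSet
) -> Dict[str, List[str]]:
    """Map simplified canonical key -> original keys that produce it.

    An entity that splits under hydrogen removal is represented by the
    dot-joined sorted keys of its fragments; one that vanishes maps to
    the empty key, which is dropped (it carries no distinct entity).
    """
    out: Dict[str, List[str]] = {}
    for orig_key in sorted(remaining):
        fragments = apply_simplifications(remaining[orig_key], combo)
        if not fragments:
            continue
        key = ".".join(sorted(canonical_key(f) for f in fragments))
        out.setdefault(key, []).append(orig_key)
    return out


def compare_entity_sets(a: EntitySet, b: EntitySet) -> ComparisonReport:
    """Find the minimal simplification combination reconciling two sets.

    Keys matching outright are removed first.  The 128 combinations are
    then applied — always to the original remaining entities — in
    application order; within-set duplicates arising from a combination
    are collated, matching keys are removed, and the first combination
    leaving nothing unmatched on either side is recorded as minimal.  A
    strict subset of keys at any point terminates with a ``subset``
    verdict; exhausting the list yields ``mismatch``.
    """
    keys_a, keys_b = set(a.keys()), set(b.keys())
    matched = sorted(keys_a & keys_b)
    remaining_a = {k: a.get(k) for k in sorted(keys_a - keys_b)}
    remaining_b = {k: b.get(k) for k in sorted(keys_b - keys_a)}
    if not remaining_a and not remaining_b:
        return ComparisonReport(Verdict.IDENTICAL, None, matched, [], [])

    tried = 0
    for combo in all_combinations():
        tried += 1
        mapped_a = _simplified_keys(remaining_a, combo)
        mapped_b = _simplified_keys(remaining_b, combo)
        collations = [
            CollationEvent(side, combo, sorted(origs), key)
            for side, mapped in (("A", mapped_a), ("B", mapped_b))
            for key, origs in sorted(mapped.items())
            if len(origs) > 1
        ]
        set_a, set_b = set(mapped_a), set(mapped_b)
        common = set_a & set_b
        left_a, left_b = set_a - common, set_b - common
        if not left_a and not left_b:
            report = ComparisonReport(
                Verdict.SIMPLIFIED,
                combo,
                matched,
                [],
                [],
                collations=collations,
                combinations_tried=tried,
            )
            report.simplified_matches = [
                (k, mapped_a[k], mapped_b[k]) for k in sorted(common)
            ]
            return report
        if not left_a or not left_b:
            # One side's keys are a strict subset of the other's: the
            # larger set has superfluous molecular entities.
            subset_side = "A" if not left_a else "B"
            leftovers = mapped_b if subset_side == "A" else mapped_a
            superfluous = sorted(
                orig for k in (left_b if subset_side == "A" else left_a) for orig in leftovers[k]
            )
            return ComparisonReport(
                Verdict.SUBSET,
                None,
                matched,
                superfluous if subset_side == "B" else [],
                superfluous if subset_side == "A" else [],
                collations=collations,
                subset_side=subset_side,
                combinations_tried=tried,
            )
    return ComparisonReport(
        Verdict.MISMATCH,
        None,
        matched,
        sorted(remaining_a),
        sorted(remaining_b),
        combinations_tried=tried,
    )


# ---------------------------------------------------------------------------
# Duplicate detection within one list of SMILES records
# ---------------------------------------------------------------------------


@dataclass
class DuplicateReport:
    """Duplicate groups found in one list of SMILES records.

    ``false_positives`` groups records whose *input strings* were already
    byte-identical (identical input necessarily canonicalises identically,
    so these say nothing about the method and are excluded up front);
    ``groups`` are the genuine duplicates: distinct input spellings that
    share a canonical key.  ``skipped`` counts unparseable records.
    """

    groups: List[List[str]]
    false_positives: List[List[str]]
    skipped: int
    skipped_ids: List[str] = field(default_factory=list)


def find_duplicates(
    records: Iterable[Union[str, Tuple[str, str]]]
) -> DuplicateReport:
    """Group SMILES records sharing a canonical key.

    Records are ``smiles`` strings or ``(identifier, smiles)`` pairs.
    Byte-identical input SMILES are collapsed first and reported as
    false-positive duplicates; the rest are grouped by the canonical key
    of their entity set.  Unparseable records are skipped and counted.
    """
    normalised: List[Tuple[str, str]] = []
    for i, rec in enumerate(records):
        if isinstance(rec, str):
            normalised.append((f"record-{i + 1}", rec.strip()))
        else:
            ident, smiles = rec
            normalised.append((str(ident), smiles.strip()))

    by_input: Dict[str, List[str]] = {}
    for ident, smiles in normalised:
        by_input.setdefault(smiles, []).append(ident)
    false_positives = sorted(ids for ids in by_input.values() if len(ids) > 1)

    by_key: Dict[str, List[str]] = {}
    skipped = 0
    skipped_ids: List[str] = []
    for smiles, ids in sorted(by_input.items()):
        if len(ids) > 1:
            continue
        try:
            entities = parse_smiles(smiles)
        except (SmilesParseError, ValueError):
            skipped += 1
            skipped_ids.extend(ids)
            continue
        key = ".".join(entities.keys())
        by_key.setdefault(key, []).append(ids[0])
    groups = sorted(ids for ids in by_key.values() if len(ids) > 1)
    return DuplicateReport(groups, false_positives, skipped, sorted(skipped_ids))
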