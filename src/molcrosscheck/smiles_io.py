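"""OpenSMILES reading, canonical SMILES writing and conservative kekulisation.

The parser covers the OpenSMILES constructs needed for cross-checking
chemical descriptions: organic-subset and bracket atoms, charges,
isotopes, ring closures (including ``%nn``), branches, dots, aromatic
lowercase forms, tetrahedral ``@``/``@@`` markers (including lone-pair
centres with only three attachments) and ``/``/``\\`` double-bond
geometry.  The writer emits SMILES in a caller-supplied canonical atom
order; combined with :func:`molcrosscheck.canonical.canonical_labelling`
it yields one byte-stable string per isomorphism class.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .molgraph import (
    CIS,
    CLOCKWISE,
    COUNTERCLOCKWISE,
    IMPLICIT_H,
    LONE_PAIR,
    TRANS,
    Atom,
    Bond,
    ConfigurationConflictError,
    DoubleBondConfig,
    EntitySet,
    MolGraphError,
    MolecularEntity,
    PERIODIC_TABLE,
    STEREO_RING_CUTOFF,
    TetrahedralCentre,
    drop_ring_cis_trans,
    encode_cis_trans,
)

__all__ = [
    "SmilesParseError",
    "parse_smiles",
    "parse_one",
    "write_canonical_smiles",
    "kekulise_filter",
    "canonicalise",
]

# Normal valences used to fill implicit hydrogens (OpenSMILES).
DEFAULT_VALENCES: Dict[str, Tuple[int, ...]] = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}
ORGANIC_SUBSET = set(DEFAULT_VALENCES) | {"*"}
AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}
AROMATIC_BRACKET = {"b", "c", "n", "o", "p", "s", "se", "as", "te", "si"}

_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, "$": 4}


class SmilesParseError(ValueError):
    """Malformed SMILES input; carries the text offset of the problem."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


def _implied_hcount(element: str, aromatic: bool, bond_total: int) -> Optional[int]:
    """Implicit hydrogen count an unbracketed atom of this valence implies.

    ``bond_total`` counts aromatic bonds as 1; aromatic atoms reserve one
    extra valence unit for the delocalised system.  Returns None for
    elements outside the organic subset (those must be bracketed).
    """
    if element == "*":
        return 0
    if element not in DEFAULT_VALENCES:
        return None
    total = bond_total + (1 if aromatic else 0)
    for valence in DEFAULT_VALENCES[element]:
        if valence >= total:
            return valence - total
    return 0


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------


class _RingSlot:
    """Placeholder in a neighbour-appearance list for a pending ring bond."""

    __slots__ = ("atom",)

    def __init__(self) -> None:
        self.atom: Optional[int] = None


@dataclass
class _AtomState:
    element: str
    aromatic: bool
    bracket: bool
    charge: int = 0
    isotope: Optional[int] = None
    bracket_h: int = 0
    chiral: Optional[str] = None
    has_parent: bool = False


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.i = 0
        self.states: List[_AtomState] = []
        self.bonds: Dict[Tuple[int, int], Bond] = {}
        self.order_lists: Dict[int, List[object]] = {}
        self.directional: List[Tuple[int, int, str]] = []
        self.ring_open: Dict[int, Tuple[int, Optional[str], _RingSlot, int]] = {}
        self.prev: Optional[int] = None
        self.pending: Optional[str] = None
        self.pending_at = 0
        self.dangling_dot: Optional[int] = None
        self.stack: List[Optional[int]] = []

    def error(self, message: str, offset: Optional[int] = None) -> SmilesParseError:
        return SmilesParseError(message, self.i if offset is None else offset)

    # -- scanning ------------------------------------------------------

    def parse(self) -> None:
        text = self.text
        n = len(text)
        while self.i < n:
            ch = text[self.i]
            if ch in "-=#$:/\\":
                if self.pending is not None:
                    raise self.error("two bond symbols in a row")
                self.pending = ch
                self.pending_at = self.i
                self.i += 1
            elif ch == "(":
                if self.prev is None:
                    raise self.error("branch cannot start a SMILES")
                self.stack.append(self.prev)
                self.i += 1
            elif ch == ")":
                if not self.stack:
                    raise self.error("unbalanced ')'")
                if self.pending is not None:
                    raise self.error("dangling bond symbol before ')'")
                self.prev = self.stack.pop()
                self.i += 1
            elif ch == ".":
                if self.pending is not None:
                    raise self.error("bond symbol before '.'")
                if self.prev is None:
                    raise self.error("'.' must separate two entities")
                self.prev = None
                self.dangling_dot = self.i
                self.i += 1
            elif ch.isdigit() or ch == "%":
                self.ring_digit()
            elif ch == "[":
                self.bracket_atom()
            else:
                self.organic_atom()
        if self.stack:
            raise self.error("unclosed branch")
        if self.pending is not None:
            raise self.error("dangling bond symbol at end", self.pending_at)
        if self.prev is None and self.dangling_dot is not None:
            raise self.error("'.' must separate two entities", self.dangling_dot)
        if self.ring_open:
            nums = ", ".join(str(k) for k in sorted(self.ring_open))
            raise self.error(f"unpaired ring closure(s): {nums}")

    def new_atom(self, state: _AtomState) -> None:
        idx = len(self.states)
        self.states.append(state)
        self.order_lists[idx] = []
        if self.prev is not None:
            self.make_bond(self.prev, idx, self.pending, self.pending_at)
            state.has_parent = True
        elif self.pending is not None:
            raise self.error("bond symbol without preceding atom", self.pending_at)
        self.pending = None
        self.prev = idx

    def make_bond(self, a: int, b: int, sym: Optional[str], at: int) -> None:
        key = (a, b) if a < b else (b, a)
        if a == b:
            raise self.error("atom bonded to itself", at)
        if key in self.bonds:
            raise self.error("duplicate bond", at)
        if sym in ("/", "\\"):
            self.directional.append((a, b, sym))
            bond = Bond(order=1)
        elif sym == ":":
            bond = Bond(order=1, aromatic=True)
        elif sym is None:
            both_aromatic = self.states[a].aromatic and self.states[b].aromatic
            bond = Bond(order=1, aromatic=both_aromatic)
        else:
            bond = Bond(order=_BOND_ORDERS[sym])
        self.bonds[key] = bond
        self.order_lists[a].append(b)
        self.order_lists[b].append(a)

    def ring_digit(self) -> None:
        text = self.text
        at = self.i
        if self.prev is None:
            raise self.error("ring closure digit without preceding atom")
        if text[self.i] == "%":
            if self.i + 2 >= len(text) or not text[self.i + 1 : self.i + 3].isdigit():
                raise self.error("'%' must be followed by two digits")
            num = int(text[self.i + 1 : self.i + 3])
            self.i += 3
        else:
            num = int(text[self.i])
            self.i += 1
        sym = self.pending
        self.pending = None
        if num not in self.ring_open:
            slot = _RingSlot()
            self.order_lists[self.prev].append(slot)
            self.ring_open[num] = (self.prev, sym, slot, at)
            return
        partner, sym1, slot, at1 = self.ring_open.pop(num)
        if partner == self.prev:
            raise self.error("ring bond to the same atom", at)
        # Reconcile bond symbols given on either closure digit.
        dir1 = sym1 in ("/", "\\")
        dir2 = sym in ("/", "\\")
        if dir1 or dir2:
            if dir1 and dir2 and sym1 == sym:
                # u->v up at one end implies v->u down at the other.
                raise self.error("conflicting directional ring bond symbols", at)
            eff = sym1 if dir1 else ("\\" if sym == "/" else "/")
            self.make_ring_bond(partner, self.prev, eff, at, slot, directional=True)
        else:
            if sym1 is not None and sym is not None and sym1 != sym:
                raise self.error("conflicting ring bond symbols", at)
            self.make_ring_bond(partner, self.prev, sym1 or sym, at, slot, directional=False)

    def make_ring_bond(
        self,
        a: int,
        b: int,
        sym: Optional[str],
        at: int,
        slot: _RingSlot,
        directional: bool,
    ) -> None:
        key = (a, b) if a < b else (b, a)
        if key in self.bonds:
            raise self.error("duplicate ring bond", at)
        if directional:
            self.directional.append((a, b, sym))
            bond = Bond(order=1)
        elif sym == ":":
            bond = Bond(order=1, aromatic=True)
        elif sym is None:
            both_aromatic = self.states[a].aromatic and self.states[b].aromatic
            bond = Bond(order=1, aromatic=both_aromatic)
        else:
            bond = Bond(order=_BOND_ORDERS[sym])
        self.bonds[key] = bond
        slot.atom = b
        self.order_lists[b].append(a)

    def organic_atom(self) -> None:
        text = self.text
        two = text[self.i : self.i + 2]
        if two in ("Cl", "Br"):
            self.new_atom(_AtomState(two, False, False))
            self.i += 2
            return
        ch = text[self.i]
        if ch in "BCNOPSFI":
            self.new_atom(_AtomState(ch, False, False))
        elif ch in AROMATIC_ORGANIC:
            self.new_atom(_AtomState(ch.upper(), True, False))
        elif ch == "*":
            self.new_atom(_AtomState("*", False, False))
        else:
            raise self.error(f"unexpected character {ch!r}")
        self.i += 1

    def bracket_atom(self) -> None:
        text = self.text
        start = self.i
        if "]" not in text[self.i :]:
            raise self.error("unterminated bracket atom", start)
        self.i += 1  # consume '['
        isotope: Optional[int] = None
        digits = ""
        while self.i < len(text) and text[self.i].isdigit():
            digits += text[self.i]
            self.i += 1
        if digits:
            isotope = int(digits)
            if isotope == 0:
                raise self.error("isotope must be positive", start)
        # element symbol, possibly aromatic lowercase
        sym2 = text[self.i : self.i + 2]
        sym1 = text[self.i : self.i + 1]
        aromatic = False
        if sym2 and sym2[0].isupper() and sym2[1:].islower() and sym2 in PERIODIC_TABLE:
            element = sym2
            self.i += 2
        elif sym1.isupper() and sym1 in PERIODIC_TABLE:
            element = sym1
            self.i += 1
        elif sym2.lower() == sym2 and sym2 in AROMATIC_BRACKET:
            element = sym2.capitalize()
            aromatic = True
            self.i += 2
        elif sym1 in AROMATIC_BRACKET:
            element = sym1.upper()
            aromatic = True
            self.i += 1
        elif sym1 == "*":
            element = "*"
            self.i += 1
        else:
            raise self.error(f"unknown element in bracket atom")
        chiral: Optional[str] = None
        if text[self.i : self.i + 2] == "@@":
            chiral = "@@"
            self.i += 2
        elif text[self.i : self.i + 1] == "@":
            chiral = "@"
            self.i += 1
        bracket_h = 0
        if text[self.i : self.i + 1] == "H":
            self.i += 1
            digits = ""
            while self.i < len(text) and text[self.i].isdigit():
                digits += text[self.i]
                self.i += 1
            bracket_h = int(digits) if digits else 1
        charge = 0
        if text[self.i : self.i + 1] in "+-":
            sign = 1 if text[self.i] == "+" else -1
            symbol = text[self.i]
            self.i += 1
            digits = ""
            while self.i < len(text) and text[self.i].isdigit():
                digits += text[self.i]
                self.i += 1
            if digits:
                charge = sign * int(digits)
            else:
                charge = sign
                while self.i < len(text) and text[self.i] == symbol:
                    charge += sign
                    self.i += 1
        if text[self.i : self.i + 1] == ":":  # atom map, parsed and discarded
            self.i += 1
            if not text[self.i : self.i + 1].isdigit():
                raise self.error("atom map must be numeric")
            while self.i < len(text) and text[self.i].isdigit():
                self.i += 1
        if text[self.i : self.i + 1] != "]":
            raise self.error("unterminated bracket atom", start)
        self.i += 1
        self.new_atom(
            _AtomState(
                element,
                aromatic,
                True,
                charge=charge,
                isotope=isotope,
                bracket_h=bracket_h,
                chiral=chiral,
            )
        )

    # -- graph assembly ------------------------------------------------

    def build(self) -> MolecularEntity:
        entity = MolecularEntity()
        for idx, st in enumerate(self.states):
            entity.add_atom(Atom(st.element, st.charge, st.isotope, st.aromatic, 0), idx)
        for (a, b), bond in self.bonds.items():
            entity.add_bond(a, b, bond)

        # Implicit hydrogen filling.
        for idx, st in enumerate(self.states):
            if st.bracket:
                hcount = st.bracket_h
            else:
                total = sum(
                    1 if entity.bond(idx, w).aromatic else entity.bond(idx, w).order
                    for w in entity.neighbours(idx)
                )
                hcount = _implied_hcount(st.element, st.aromatic, total) or 0
            if hcount:
                entity.set_atom(idx, Atom(st.element, st.charge, st.isotope, st.aromatic, hcount))

        order_of: Dict[int, List[int]] = {}
        for idx, entries in self.order_lists.items():
            resolved: List[int] = []
            for entry in entries:
                if isinstance(entry, _RingSlot):
                    if entry.atom is None:
                        raise SmilesParseError("unresolved ring bond", 0)
                    resolved.append(entry.atom)
                else:
                    resolved.append(entry)
            order_of[idx] = resolved

        self._build_stereocentres(entity, order_of)
        self._build_bond_configs(entity)
        drop_ring_cis_trans(entity, STEREO_RING_CUTOFF)
        return entity

    def _build_stereocentres(
        self, entity: MolecularEntity, order_of: Dict[int, List[int]]
    ) -> None:
        for idx, st in enumerate(self.states):
            if st.chiral is None:
                continue
            attachments = list(order_of[idx])
            if st.bracket_h >= 1:
                # The bracket hydrogen is an attachment of the centre, in
                # the written position (right after the preceding atom, or
                # first); it stays implicit in the atom's hcount.
                attachments.insert(1 if st.has_parent else 0, IMPLICIT_H)
            if len(attachments) == 3:
                # Three-attachment chiral centre: the lone pair plays the
                # fourth attachment; first in the enumeration if the atom
                # starts the SMILES, second otherwise.
                attachments.insert(1 if st.has_parent else 0, LONE_PAIR)
            if len(attachments) != 4:
                raise SmilesParseError(
                    f"chiral atom with {len(attachments)} attachments is not tetrahedral",
                    0,
                )
            parity = COUNTERCLOCKWISE if st.chiral == "@" else CLOCKWISE
            entity.add_stereocentre(
                TetrahedralCentre(idx, tuple(attachments), parity)
            )

    def _build_bond_configs(self, entity: MolecularEntity) -> None:
        # u = direction of a substituent bond normalised substituent->endpoint.
        up: Dict[Tuple[int, int], bool] = {}
        for a, b, sym in self.directional:
            up[(a, b)] = sym == "/"
            up[(b, a)] = sym == "\\"
        for (a, b), bond in entity.bonds.items():
            if bond.order != 2 or bond.aromatic:
                continue
            dirs_a = {
                x: up[(x, a)]
                for x in entity.neighbours(a) - {b}
                if (x, a) in up
            }
            dirs_b = {
                y: up[(y, b)]
                for y in entity.neighbours(b) - {a}
                if (y, b) in up
            }
            for dirs, end in ((dirs_a, a), (dirs_b, b)):
                if len(dirs) == 2 and len(set(dirs.values())) == 1:
                    raise ConfigurationConflictError(
                        f"substituents of atom {end} marked on the same side"
                    )
            if not dirs_a or not dirs_b:
                continue
            relations = frozenset(
                (x, y, TRANS if ux != uy else CIS)
                for x, ux in dirs_a.items()
                for y, uy in dirs_b.items()
            )
            entity.add_bond_config(DoubleBondConfig((a, b), relations))


def _split_components(entity: MolecularEntity) -> List[MolecularEntity]:
    g = entity.to_nx()
    components = [sorted(c) for c in nx.connected_components(g)] if entity.atoms else []
    out = []
    for comp in sorted(components):
        member = set(comp)
        sub = MolecularEntity()
        for idx in comp:
            sub.add_atom(entity.atoms[idx], idx)
        for (a, b), bond in entity.bonds.items():
            if a in member:
                sub.add_bond(a, b, bond)
        for centre in entity.stereocentres.values():
            if centre.centre in member:
                sub.add_stereocentre(centre)
        for key, config in entity.bond_configs.items():
            if key[0] in member:
                sub.add_bond_config(config)
        out.append(sub)
    return out


def parse_smiles(text: str) -> EntitySet:
    """Parse one SMILES line into a set of distinct molecular entities.

    ``.`` separates entities (ring bonds may span it, in which case the
    connected components define the entities).  The set is deduplicated by
    canonical key.
    """
    text = text.strip()
    if not text:
        raise SmilesParseError("empty SMILES", 0)
    parser = _Parser(text)
    parser.parse()
    entity = parser.build()
    return EntitySet(_split_components(entity))


def parse_one(text: str) -> MolecularEntity:
    """Parse a SMILES expected to contain exactly one molecular entity."""
    entities = parse_smiles(text)
    if len(entities) != 1:
        raise SmilesParseError(
            f"expected a single molecular entity, got {len(entities)}", 0
        )
    return next(iter(entities))


# ---------------------------------------------------------------------------
# Canonical writer
# ---------------------------------------------------------------------------


def _permutation_parity(reference: Sequence[int], rearranged: Sequence[int]) -> int:
    perm = [reference.index(x) for x in rearranged]
    swaps = 0
    perm = list(perm)
    for i in range(len(perm)):
        while perm[i] != i:
            j = perm[i]
            perm[i], perm[j] = perm[j], perm[i]
            swaps += 1
    return swaps % 2


def _solve_directions(entity: MolecularEntity) -> Dict[Tuple[int, int], bool]:
    """2-colour the substituent bonds of configured double bonds.

    Returns ``d[(a, b)]`` with ``a < b`` meaning "up when traversed a->b".
    """
    constraints: List[Tuple[Tuple[int, int], Tuple[int, int], bool]] = []
    variables: Set[Tuple[int, int]] = set()

    def var(x: int, e: int) -> Optional[Tuple[int, int]]:
        key = (x, e) if x < e else (e, x)
        bond = entity.bonds[key]
        if bond.order != 1 or bond.aromatic:
            return None
        return key

    def orient(x: int, e: int, key: Tuple[int, int]) -> bool:
        # True when u(x->e) equals d(key); they agree iff x is key[0].
        return x == key[0]

    for (a, b) in sorted(entity.bond_configs):
        relations = encode_cis_trans(entity, (a, b))
        subs_a = sorted(x for x in entity.neighbours(a) - {b} if var(x, a))
        subs_b = sorted(y for y in entity.neighbours(b) - {a} if var(y, b))
        if not subs_a or not subs_b:
            raise MolGraphError(
                f"cannot express cis/trans of bond ({a}, {b}) without single-bond substituents"
            )
        for x in subs_a:
            variables.add(var(x, a))  # type: ignore[arg-type]
        for y in subs_b:
            variables.add(var(y, b))  # type: ignore[arg-type]
        for subs, end in ((subs_a, a), (subs_b, b)):
            if len(subs) == 2:
                k1, k2 = var(subs[0], end), var(subs[1], end)
                # u values of same-end substituents differ; translate the
                # inequality through each variable's orientation.
                same_d = False == (orient(subs[0], end, k1) == orient(subs[1], end, k2))  # type: ignore[arg-type]
                constraints.append((k1, k2, same_d))  # type: ignore[arg-type]
        for x, y, rel in relations:
            kx, ky = var(x, a), var(y, b)
            if kx is None or ky is None:
                continue
            # trans <=> u(x->a) != u(y->b); translate u to d orientation.
            same_u = rel == CIS
            same_d = same_u == (orient(x, a, kx) == orient(y, b, ky))
            constraints.append((kx, ky, same_d))

    adjacency: Dict[Tuple[int, int], List[Tuple[Tuple[int, int], bool]]] = {
        v: [] for v in variables
    }
    for u, v, same in constraints:
        adjacency[u].append((v, same))
        adjacency[v].append((u, same))
    assignment: Dict[Tuple[int, int], bool] = {}
    for root in sorted(variables):
        if root in assignment:
            continue
        assignment[root] = True
        queue = [root]
        while queue:
            u = queue.pop()
            for v, same in adjacency[u]:
                want = assignment[u] if same else not assignment[u]
                if v in assignment:
                    if assignment[v] != want:
                        raise ConfigurationConflictError(
                            "inconsistent cis/trans configuration"
                        )
                else:
                    assignment[v] = want
                    queue.append(v)
    return assignment


def _charge_token(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return sign if mag == 1 else f"{sign}{mag}"


def write_canonical_smiles(entity: MolecularEntity, ranks: Mapping[int, int]) -> str:
    """Write an entity as SMILES following a canonical atom order.

    The depth-first traversal starts at the rank-0 atom and always
    descends into the lowest-ranked unvisited neighbour; ring-closure
    digits are emitted closures-first and get the smallest free number.
    Chiral markers are recomputed for the output neighbour order, and
    directional markers are flipped globally so the first one is ``/``.
    """
    if not entity.atoms:
        return ""
    if set(ranks) != set(entity.atoms):
        raise MolGraphError("canonical order must cover every atom")

    directions = _solve_directions(entity) if entity.bond_configs else {}

    visited: Set[int] = set()
    children: Dict[int, List[int]] = {}
    parent_of: Dict[int, Optional[int]] = {}
    ring_bonds_at: Dict[int, List[int]] = {}
    preorder: List[int] = []
    seen_ring: Set[Tuple[int, int]] = set()

    def rank_of(a: int) -> int:
        return ranks[a]

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * len(entity.atoms) + 200))

    def explore(u: int, parent: Optional[int]) -> None:
        visited.add(u)
        preorder.append(u)
        parent_of[u] = parent
        children[u] = []
        ring_bonds_at.setdefault(u, [])
        for w in sorted(entity.neighbours(u), key=rank_of):
            if w == parent:
                continue
            if w in visited:
                key = (u, w) if u < w else (w, u)
                if key not in seen_ring:
                    seen_ring.add(key)
                    ring_bonds_at[u].append(w)
                    ring_bonds_at.setdefault(w, []).append(u)
            else:
                children[u].append(w)
                explore(w, u)

    roots = sorted(entity.atoms, key=rank_of)
    explore(roots[0], None)
    if len(visited) != len(entity.atoms):
        raise MolGraphError("molecular entity graph must be connected")

    pre_pos = {a: i for i, a in enumerate(preorder)}

    # Ring digit bookkeeping: assigned when the first endpoint is written.
    digit_of: Dict[Tuple[int, int], int] = {}
    in_use: Set[int] = set()

    def take_digit() -> int:
        d = 1
        while d in in_use:
            d += 1
        in_use.add(d)
        return d

    tokens: List[str] = []
    directional_token_idx: List[int] = []

    def bond_token(a: int, b: int) -> str:
        """Bond symbol for the written orientation a->b."""
        bond = entity.bond(a, b)
        if bond.aromatic:
            aromatic_pair = entity.atoms[a].aromatic and entity.atoms[b].aromatic
            return "" if aromatic_pair else ":"
        if bond.order == 1:
            key = (a, b) if a < b else (b, a)
            if key in directions:
                up = directions[key] if a == key[0] else not directions[key]
                directional_token_idx.append(len(tokens))
                return "/" if up else "\\"
            if entity.atoms[a].aromatic and entity.atoms[b].aromatic:
                return "-"
            return ""
        return {2: "=", 3: "#", 4: "$"}[bond.order]

    def atom_token(u: int) -> str:
        atom = entity.atoms[u]
        centre = entity.stereocentres.get(u)
        symbol = atom.element.lower() if atom.aromatic else atom.element
        display_h = atom.hcount
        bond_total = sum(
            1 if entity.bond(u, w).aromatic else entity.bond(u, w).order
            for w in entity.neighbours(u)
        )
        implied = _implied_hcount(atom.element, atom.aromatic, bond_total)
        needs_bracket = (
            atom.charge != 0
            or atom.isotope is not None
            or centre is not None
            or atom.element not in ORGANIC_SUBSET
            or (atom.aromatic and atom.element.lower() not in AROMATIC_ORGANIC)
            or implied is None
            or implied != display_h
        )
        if not needs_bracket:
            return symbol
        chiral_sym = ""
        if centre is not None:
            chiral_sym = _chiral_symbol(u, centre)
        h_part = "" if display_h == 0 else ("H" if display_h == 1 else f"H{display_h}")
        iso = "" if atom.isotope is None else str(atom.isotope)
        return f"[{iso}{symbol}{chiral_sym}{h_part}{_charge_token(atom.charge)}]"

    def _chiral_symbol(u: int, centre: TetrahedralCentre) -> str:
        out_order: List[int] = []
        if parent_of[u] is not None:
            out_order.append(parent_of[u])
        if IMPLICIT_H in centre.neighbours:
            out_order.append(IMPLICIT_H)
        out_order.extend(ring_partner_order[u])
        out_order.extend(children[u])
        if LONE_PAIR in centre.neighbours:
            out_order.insert(0 if parent_of[u] is None else 1, LONE_PAIR)
        if sorted(out_order) != sorted(centre.neighbours):
            raise MolGraphError(
                f"stereocentre {u} attachments do not match its bonds"
            )
        reference = list(centre.clockwise_order())
        parity = _permutation_parity(reference, out_order)
        return "@@" if parity == 0 else "@"

    # Pre-compute the order ring digits will be emitted at each atom:
    # closings first (ascending digit, i.e. opening order), then openings
    # by partner rank.  Digits are simulated in preorder.
    ring_partner_order: Dict[int, List[int]] = {a: [] for a in entity.atoms}
    sim_digit: Dict[Tuple[int, int], int] = {}
    sim_in_use: Set[int] = set()
    for u in preorder:
        closings = [
            w for w in ring_bonds_at.get(u, []) if pre_pos[w] < pre_pos[u]
        ]
        closings.sort(key=lambda w: sim_digit[(u, w) if u < w else (w, u)])
        openings = sorted(
            (w for w in ring_bonds_at.get(u, []) if pre_pos[w] > pre_pos[u]),
            key=rank_of,
        )
        for w in closings:
            key = (u, w) if u < w else (w, u)
            sim_in_use.discard(sim_digit[key])
            ring_partner_order[u].append(w)
        for w in openings:
            key = (u, w) if u < w else (w, u)
            d = 1
            while d in sim_in_use:
                d += 1
            sim_in_use.add(d)
            sim_digit[key] = d
            ring_partner_order[u].append(w)

    def write_atom(u: int, parent: Optional[int]) -> None:
        if parent is not None:
            tokens.append(bond_token(parent, u))
        tokens.append(atom_token(u))
        for w in ring_partner_order[u]:
            key = (u, w) if u < w else (w, u)
            if pre_pos[w] > pre_pos[u]:  # opening
                d = take_digit()
                digit_of[key] = d
                tokens.append(bond_token(u, w))
                tokens.append(str(d) if d < 10 else f"%{d:02d}")
            else:  # closing
                d = digit_of[key]
                in_use.discard(d)
                tokens.append(str(d) if d < 10 else f"%{d:02d}")
        kids = children[u]
        for c in kids[:-1]:
            tokens.append("(")
            write_atom(c, u)
            tokens.append(")")
        if kids:
            write_atom(kids[-1], u)

    write_atom(preorder[0], None)

    if directional_token_idx:
        first = min(directional_token_idx)
        if tokens[first] == "\\":
            for i in directional_token_idx:
                tokens[i] = "/" if tokens[i] == "\\" else "\\"
    return "".join(tokens)


# ---------------------------------------------------------------------------
# Conservative kekulisation
# ---------------------------------------------------------------------------


def kekulise_filter(entity: MolecularEntity) -> MolecularEntity:
    """Rewrite isolated even aromatic rings with alternating bond orders.

    Only rings that consist entirely of aromatic atoms and bonds, have an
    even number of members, and share no atom with any other ring are
    touched; everything else (fused systems, odd rings) is left as
    written.  The rewritten ring loses its aromatic flags.  The filter is
    idempotent and never changes connectivity.
    """
    from .canonical import canonical_labelling
    from .molgraph import to_colored_graph

    out = entity.copy()
    g = out.to_nx()
    rings = [set(r) for r in nx.minimum_cycle_basis(g)] if len(out.bonds) >= len(out.atoms) else []
    if not rings:
        return out
    ranks: Optional[Dict[int, int]] = None
    for i, ring in enumerate(rings):
        if len(ring) % 2 != 0:
            continue
        if any(ring & other for j, other in enumerate(rings) if j != i):
            continue
        if not all(out.atoms[a].aromatic for a in ring):
            continue
        sub = g.subgraph(ring)
        if any(d != 2 for _, d in sub.degree()):
            continue
        ring_edges = [tuple(sorted(e)) for e in sub.edges()]
        if not all(out.bonds[e].aromatic for e in ring_edges):
            continue
        # No aromatic bonds may leave the ring: the rewrite must not strand
        # half-marked aromatic systems.
        leaves_aromatic = any(
            out.bond(a, w).aromatic
            for a in ring
            for w in out.neighbours(a)
            if w not in ring
        )
        if leaves_aromatic:
            continue
        if ranks is None:
            cg = to_colored_graph(entity)
            labelling = canonical_labelling(cg)
            ranks = {a: labelling.permutation[cg.atom_vertex[a]] for a in entity.atoms}
        # Walk the cycle starting at the lowest-ranked atom, towards its
        # lower-ranked ring neighbour; that first bond becomes double.
        anchor = min(ring, key=lambda a: ranks[a])
        nbrs = sorted((w for w in sub.neighbors(anchor)), key=lambda a: ranks[a])
        cycle = [anchor, nbrs[0]]
        while len(cycle) < len(ring):
            nxt = next(w for w in sub.neighbors(cycle[-1]) if w != cycle[-2])
            cycle.append(nxt)
        for pos in range(len(cycle)):
            a, b = cycle[pos], cycle[(pos + 1) % len(cycle)]
            order = 2 if pos % 2 == 0 else 1
            out.set_bond(a, b, Bond(order=order))
        for a in ring:
            atom = out.atoms[a]
            out.set_atom(a, Atom(atom.element, atom.charge, atom.isotope, False, atom.hcount))
    return out


def canonicalise(text: str, kekulise: bool = False) -> str:
    """Canonical SMILES of a whole record (entities sorted, joined by '.')."""
    from .canonical import canonical_key

    entities = parse_smiles(text)
    if kekulise:
        keys = sorted(canonical_key(kekulise_filter(e)) for e in entities)
    else:
        keys = entities.keys()
    return ".".join(keys)
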