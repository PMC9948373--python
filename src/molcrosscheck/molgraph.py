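"""Attributed molecular graphs and their reduction to vertex-coloured simple graphs.

A molecular entity is a connected graph of atoms and bonds together with
stereo descriptors (tetrahedral centres, double-bond cis/trans
configurations).  For canonical labelling the entity is flattened into a
:class:`ColoredGraph` — a plain simple graph whose vertices carry a single
colour each.  Edge attributes (bond order, aromaticity, cis/trans labels)
are expressed by inserting *carrier* vertices on the edge, and
stereochemistry is expressed by small auxiliary subgraphs:

* a configured double bond contributes one labelled auxiliary edge per
  pair of substituents on opposite ends (four edges for a fully
  substituted bond), each realised as a "cis"- or "trans"-coloured
  carrier vertex;
* a tetrahedral centre contributes twelve *enumeration-listing* vertices,
  one per clockwise enumeration of three attachments viewed from the
  fourth; the first/second/third position of an enumerated attachment is
  realised as a chain of one, two or three "dot" vertices on the edge.

These encodings make isomorphism of the coloured graphs coincide with
chemical identity, including stereochemistry, while only ever requiring a
vertex-coloured simple-graph isomorphism test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

__all__ = [
    "LONE_PAIR",
    "IMPLICIT_H",
    "CLOCKWISE",
    "COUNTERCLOCKWISE",
    "CIS",
    "TRANS",
    "Atom",
    "Bond",
    "TetrahedralCentre",
    "DoubleBondConfig",
    "MolecularEntity",
    "EntitySet",
    "ColoredGraph",
    "MolGraphError",
    "ConfigurationConflictError",
    "StereoEncodingError",
    "encode_cis_trans",
    "encode_tetrahedral",
    "to_colored_graph",
    "drop_ring_cis_trans",
    "STEREO_RING_CUTOFF",
]

# Sentinel attachment identifiers used in TetrahedralCentre.neighbours.
# Real atom identifiers are non-negative integers.
LONE_PAIR = -1
#: An implicit hydrogen acting as an attachment of a tetrahedral centre
#: (the bracket-H of e.g. ``[C@H]``); it lives in the atom's hcount, not
#: as a graph vertex, and is realised as a phantom vertex only inside the
#: stereo subgraph.
IMPLICIT_H = -2

CLOCKWISE = "clockwise"
COUNTERCLOCKWISE = "counterclockwise"

CIS = "cis"
TRANS = "trans"

#: Double-bond cis/trans descriptors inside rings of this size or smaller are
#: dropped when entities are constructed from input formats.
STEREO_RING_CUTOFF = 8

# A liberal periodic table: element symbols accepted as vertex types.
PERIODIC_TABLE = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


class MolGraphError(ValueError):
    """Base error for invalid molecular graphs."""


class ConfigurationConflictError(MolGraphError):
    """Raised when cis/trans relations of a double bond are inconsistent."""


class StereoEncodingError(MolGraphError):
    """Raised when a stereo descriptor cannot be encoded as a subgraph."""


@dataclass(frozen=True)
class Atom:
    """A vertex of the molecular graph.

    ``element`` is a periodic-table symbol or the wildcard ``"*"``;
    ``hcount`` holds implicit hydrogens, which participate in the vertex
    colour but are not graph vertices themselves.
    """

    element: str
    charge: int = 0
    isotope: Optional[int] = None
    aromatic: bool = False
    hcount: int = 0

    def __post_init__(self) -> None:
        if self.element != "*" and self.element not in PERIODIC_TABLE:
            raise MolGraphError(f"unknown element symbol {self.element!r}")
        if self.hcount < 0:
            raise MolGraphError("hcount must be non-negative")
        if self.isotope is not None and self.isotope <= 0:
            raise MolGraphError("isotope mass number must be positive")


@dataclass(frozen=True)
class Bond:
    """An edge of the molecular graph.

    ``coordination`` marks metal coordination bonds; it is only set by the
    SDF reader and is normalised away before comparison.
    """

    order: int = 1
    aromatic: bool = False
    coordination: bool = False

    def __post_init__(self) -> None:
        if self.order < 1:
            raise MolGraphError("bond order must be >= 1")

    @property
    def is_default(self) -> bool:
        """True for a plain single covalent bond (no carrier vertex needed)."""
        return self.order == 1 and not self.aromatic


@dataclass(frozen=True)
class TetrahedralCentre:
    """Tetrahedral chirality descriptor.

    ``neighbours`` lists exactly four attachments in a reference order; one
    entry may be the sentinel :data:`LONE_PAIR` for three-coordinate centres
    whose lone electron pair acts as the fourth attachment.  ``parity``
    states whether, looking from the first attachment towards the centre,
    the remaining three appear clockwise or counterclockwise.
    """

    centre: int
    neighbours: Tuple[int, int, int, int]
    parity: str

    def __post_init__(self) -> None:
        if len(self.neighbours) != 4:
            raise StereoEncodingError("tetrahedral centre needs exactly 4 attachments")
        if len(set(self.neighbours)) != 4:
            raise StereoEncodingError("tetrahedral attachments must be distinct")
        if sum(1 for n in self.neighbours if n == LONE_PAIR) > 1:
            raise StereoEncodingError("at most one lone-pair attachment allowed")
        if sum(1 for n in self.neighbours if n == IMPLICIT_H) > 1:
            raise StereoEncodingError("at most one implicit-H attachment allowed")
        if self.parity not in (CLOCKWISE, COUNTERCLOCKWISE):
            raise StereoEncodingError(f"invalid parity {self.parity!r}")

    def clockwise_order(self) -> Tuple[int, int, int, int]:
        """Attachments reordered so that the descriptor reads clockwise."""
        if self.parity == CLOCKWISE:
            return self.neighbours
        a, b, c, d = self.neighbours
        return (a, b, d, c)


@dataclass(frozen=True)
class DoubleBondConfig:
    """Cis/trans configuration of a double bond.

    ``relations`` holds triples ``(x, y, rel)`` where ``x`` is attached to
    the first bond endpoint, ``y`` to the second and ``rel`` is ``"cis"`` or
    ``"trans"``.  A single triple determines the rest by consistency.
    """

    bond: Tuple[int, int]
    relations: FrozenSet[Tuple[int, int, str]]

    def __post_init__(self) -> None:
        if not self.relations:
            raise ConfigurationConflictError("double-bond configuration without relations")
        for _, _, rel in self.relations:
            if rel not in (CIS, TRANS):
                raise ConfigurationConflictError(f"invalid relation {rel!r}")


def _edge_key(a: int, b: int) -> Tuple[int, int]:
    if a == b:
        raise MolGraphError("self-bonds are not allowed")
    return (a, b) if a < b else (b, a)


class MolecularEntity:
    """A connected attributed molecular graph plus stereo descriptors."""

    def __init__(self) -> None:
        self.atoms: Dict[int, Atom] = {}
        self.bonds: Dict[Tuple[int, int], Bond] = {}
        self.stereocentres: Dict[int, TetrahedralCentre] = {}
        self.bond_configs: Dict[Tuple[int, int], DoubleBondConfig] = {}
        self._adj: Dict[int, Set[int]] = {}

    # -- construction -------------------------------------------------

    def add_atom(self, atom: Atom, idx: Optional[int] = None) -> int:
        if idx is None:
            idx = max(self.atoms, default=-1) + 1
        if idx < 0 or idx in self.atoms:
            raise MolGraphError(f"bad atom identifier {idx}")
        self.atoms[idx] = atom
        self._adj[idx] = set()
        return idx

    def add_bond(self, a: int, b: int, bond: Bond = Bond()) -> Tuple[int, int]:
        key = _edge_key(a, b)
        if a not in self.atoms or b not in self.atoms:
            raise MolGraphError("bond endpoint does not exist")
        if key in self.bonds:
            raise MolGraphError(f"duplicate bond {key}")
        self.bonds[key] = bond
        self._adj[a].add(b)
        self._adj[b].add(a)
        return key

    def set_atom(self, idx: int, atom: Atom) -> None:
        if idx not in self.atoms:
            raise MolGraphError(f"no atom {idx}")
        self.atoms[idx] = atom

    def set_bond(self, a: int, b: int, bond: Bond) -> None:
        key = _edge_key(a, b)
        if key not in self.bonds:
            raise MolGraphError(f"no bond {key}")
        self.bonds[key] = bond

    def add_stereocentre(self, centre: TetrahedralCentre) -> None:
        self._check_centre(centre)
        self.stereocentres[centre.centre] = centre

    def add_bond_config(self, config: DoubleBondConfig) -> None:
        key = _edge_key(*config.bond)
        if key not in self.bonds:
            raise MolGraphError(f"no bond {key} for double-bond configuration")
        # Validate the relations against the graph and close them.
        encode_cis_trans(self, key, _config=config)
        self.bond_configs[key] = config

    def _check_centre(self, centre: TetrahedralCentre) -> None:
        if centre.centre not in self.atoms:
            raise StereoEncodingError(f"no atom {centre.centre} for stereocentre")
        real = [n for n in centre.neighbours if n >= 0]
        for n in real:
            if n not in self._adj[centre.centre]:
                raise StereoEncodingError(
                    f"stereocentre attachment {n} is not bonded to {centre.centre}"
                )

    # -- queries -------------------------------------------------------

    def neighbours(self, idx: int) -> Set[int]:
        return self._adj[idx]

    def bond(self, a: int, b: int) -> Bond:
        return self.bonds[_edge_key(a, b)]

    def has_bond(self, a: int, b: int) -> bool:
        return _edge_key(a, b) in self.bonds

    @property
    def total_charge(self) -> int:
        return sum(a.charge for a in self.atoms.values())

    def to_nx(self) -> nx.Graph:
        """Plain connectivity graph (no attributes) for ring/path queries."""
        g = nx.Graph()
        g.add_nodes_from(self.atoms)
        g.add_edges_from(self.bonds)
        return g

    def is_connected(self) -> bool:
        if not self.atoms:
            return True
        return nx.is_connected(self.to_nx())

    def validate(self) -> None:
        if not self.is_connected():
            raise MolGraphError("molecular entity graph must be connected")
        for centre in self.stereocentres.values():
            self._check_centre(centre)
        for key in self.bond_configs:
            if key not in self.bonds:
                raise MolGraphError(f"double-bond configuration on missing bond {key}")

    def relabel(self, mapping: Dict[int, int]) -> "MolecularEntity":
        """The same entity under new atom identifiers (sentinels untouched)."""
        out = MolecularEntity()
        for idx in sorted(self.atoms):
            out.add_atom(self.atoms[idx], mapping[idx])
        for (a, b), bond in self.bonds.items():
            out.add_bond(mapping[a], mapping[b], bond)
        for centre in self.stereocentres.values():
            out.add_stereocentre(
                TetrahedralCentre(
                    mapping[centre.centre],
                    tuple(mapping.get(n, n) for n in centre.neighbours),
                    centre.parity,
                )
            )
        for config in self.bond_configs.values():
            out.add_bond_config(
                DoubleBondConfig(
                    (mapping[config.bond[0]], mapping[config.bond[1]]),
                    frozenset(
                        (mapping[x], mapping[y], rel) for x, y, rel in config.relations
                    ),
                )
            )
        return out

    def copy(self) -> "MolecularEntity":
        out = MolecularEntity()
        out.atoms = dict(self.atoms)
        out.bonds = dict(self.bonds)
        out.stereocentres = dict(self.stereocentres)
        out.bond_configs = dict(self.bond_configs)
        out._adj = {k: set(v) for k, v in self._adj.items()}
        return out

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# Stereo descriptor encodings
# ---------------------------------------------------------------------------


def _close_relations(
    side1: Sequence[int],
    side2: Sequence[int],
    relations: Iterable[Tuple[int, int, str]],
) -> Set[Tuple[int, int, str]]:
    """Close a partial cis/trans relation set over all substituent pairs.

    Substituents on the same end of the double bond are on opposite sides of
    the bond plane, so one known pair relation determines all others.  Sides
    are modelled as booleans; ``cis`` means equal side values.
    """
    if not (1 <= len(side1) <= 2 and 1 <= len(side2) <= 2):
        raise ConfigurationConflictError(
            "configured double bond needs 1-2 substituents on each end"
        )
    u: Dict[int, bool] = {side1[0]: True}
    if len(side1) == 2:
        u[side1[1]] = False
    v: Dict[int, bool] = {}
    pending = list(relations)
    progressed = True
    while pending and progressed:
        progressed = False
        rest = []
        for x, y, rel in pending:
            if x in v or y in u:  # relation given in (side2, side1) orientation
                x, y = y, x
            if x not in u or y not in set(side2):
                raise ConfigurationConflictError(
                    f"relation ({x}, {y}) does not span the double bond"
                )
            want = u[x] if rel == CIS else not u[x]
            if y in v:
                if v[y] != want:
                    raise ConfigurationConflictError(
                        f"substituent pair ({x}, {y}) labelled both cis and trans"
                    )
            else:
                v[y] = want
                progressed = True
        pending = rest
    if len(side2) == 2:
        y1, y2 = side2
        if y1 in v and y2 in v:
            if v[y1] == v[y2]:
                raise ConfigurationConflictError(
                    "substituents on one end cannot share a side"
                )
        elif y1 in v:
            v[y2] = not v[y1]
        elif y2 in v:
            v[y1] = not v[y2]
    if not v:
        raise ConfigurationConflictError("relations do not determine the configuration")
    closed: Set[Tuple[int, int, str]] = set()
    for x in side1:
        for y in side2:
            closed.add((x, y, CIS if u[x] == v[y] else TRANS))
    return closed


def encode_cis_trans(
    entity: MolecularEntity,
    bond: Tuple[int, int],
    _config: Optional[DoubleBondConfig] = None,
) -> Set[Tuple[int, int, str]]:
    """Auxiliary cis/trans edges for a configured double bond.

    Returns one labelled edge per (substituent-on-end-1, substituent-on-end-2)
    pair — four for a fully substituted bond.  The returned relation set is
    the consistency closure of the stored partial relations; inconsistent
    input raises :class:`ConfigurationConflictError`.  A bond without a
    configuration yields the empty set.
    """
    key = _edge_key(*bond)
    config = _config if _config is not None else entity.bond_configs.get(key)
    if config is None:
        return set()
    a, b = key
    side_a = sorted(entity.neighbours(a) - {b})
    side_b = sorted(entity.neighbours(b) - {a})
    relations = []
    members_a = set(side_a)
    members_b = set(side_b)
    for x, y, rel in config.relations:
        if x in members_a and y in members_b:
            relations.append((x, y, rel))
        elif x in members_b and y in members_a:
            relations.append((y, x, rel))
        else:
            raise ConfigurationConflictError(
                f"relation atoms ({x}, {y}) are not substituents of bond {key}"
            )
    return _close_relations(side_a, side_b, relations)


@dataclass
class StereoSubgraph:
    """Auxiliary vertices and edges produced by a stereo encoding.

    Vertices are ``(local_id, colour)`` pairs; edge endpoints are either
    ``("atom", atom_id)`` or ``("aux", local_id)``.
    """

    vertices: List[Tuple[int, Tuple]] = field(default_factory=list)
    edges: List[Tuple[Tuple[str, int], Tuple[str, int]]] = field(default_factory=list)

    def new_vertex(self, colour: Tuple) -> Tuple[str, int]:
        vid = len(self.vertices)
        self.vertices.append((vid, colour))
        return ("aux", vid)

    def add_edge(self, u: Tuple[str, int], v: Tuple[str, int]) -> None:
        self.edges.append((u, v))


_EVEN_PERMUTATIONS_4 = [
    p
    for p in itertools.permutations(range(4))
    if sum(1 for i in range(4) for j in range(i + 1, 4) if p[i] > p[j]) % 2 == 0
]

COLOUR_ENUM = ("enum",)
COLOUR_DOT = ("dot",)
COLOUR_LONE_PAIR = ("lone-pair",)
COLOUR_IMPLICIT_H = ("implicit-h",)


def encode_tetrahedral(entity: MolecularEntity, centre: TetrahedralCentre) -> StereoSubgraph:
    """Enumeration-listing subgraph of a tetrahedral centre.

    The twelve clockwise enumerations (three per viewing attachment) of the
    centre's four attachments form one coset of the alternating group A4;
    each becomes an enumeration-listing vertex joined to the centre, to the
    viewing attachment, and — through chains of one, two and three "dot"
    vertices — to the first, second and third enumerated attachment.  The
    subgraph therefore depends only on the spatial configuration, not on
    the order in which the attachments were listed, and the mirror image
    produces the complementary (non-isomorphic) coset.
    """
    entity._check_centre(centre)
    sub = StereoSubgraph()
    refs: Dict[int, Tuple[str, int]] = {}
    for n in centre.neighbours:
        if n == LONE_PAIR:
            lp = sub.new_vertex(COLOUR_LONE_PAIR)
            sub.add_edge(lp, ("atom", centre.centre))
            refs[n] = lp
        elif n == IMPLICIT_H:
            ih = sub.new_vertex(COLOUR_IMPLICIT_H)
            sub.add_edge(ih, ("atom", centre.centre))
            refs[n] = ih
        else:
            refs[n] = ("atom", n)
    base = centre.clockwise_order()
    for perm in _EVEN_PERMUTATIONS_4:
        viewer, first, second, third = (base[i] for i in perm)
        enum_v = sub.new_vertex(COLOUR_ENUM)
        sub.add_edge(enum_v, ("atom", centre.centre))
        sub.add_edge(enum_v, refs[viewer])
        for position, attachment in enumerate((first, second, third), start=1):
            prev = enum_v
            for _ in range(position):
                dot = sub.new_vertex(COLOUR_DOT)
                sub.add_edge(prev, dot)
                prev = dot
            sub.add_edge(prev, refs[attachment])
    return sub


# ---------------------------------------------------------------------------
# Coloured simple graph
# ---------------------------------------------------------------------------


class ColoredGraph:
    """Simple undirected graph with one colour per vertex.

    ``atom_vertex`` maps atom identifiers of the originating entity to
    vertex indices, so canonical vertex ranks can be projected back onto
    atoms.
    """

    def __init__(self) -> None:
        self.colors: List[Tuple] = []
        self.adj: List[Set[int]] = []
        self.atom_vertex: Dict[int, int] = {}

    def add_vertex(self, colour: Tuple) -> int:
        self.colors.append(colour)
        self.adj.append(set())
        return len(self.colors) - 1

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise MolGraphError("self-loops are not allowed")
        self.adj[u].add(v)
        self.adj[v].add(u)

    @property
    def n(self) -> int:
        return len(self.colors)

    def edge_count(self) -> int:
        return sum(len(a) for a in self.adj) // 2

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        for i, colour in enumerate(self.colors):
            g.add_node(i, color=colour)
        for u, nbrs in enumerate(self.adj):
            for v in nbrs:
                if u < v:
                    g.add_edge(u, v)
        return g


def _atom_colour(atom: Atom) -> Tuple:
    return ("atom", atom.element, atom.charge, atom.isotope, atom.aromatic, atom.hcount)


def to_colored_graph(entity: MolecularEntity) -> ColoredGraph:
    """Flatten an entity into a vertex-coloured simple graph.

    Atoms become vertices coloured by (element, charge, isotope, aromatic,
    implicit-H count).  Bonds with non-default attributes become carrier
    vertices coloured by (order, aromatic); plain single bonds stay direct
    edges.  Stereo descriptors contribute their auxiliary subgraphs.
    """
    g = ColoredGraph()
    for idx in sorted(entity.atoms):
        g.atom_vertex[idx] = g.add_vertex(_atom_colour(entity.atoms[idx]))
    for (a, b), bond in sorted(entity.bonds.items()):
        if bond.is_default:
            g.add_edge(g.atom_vertex[a], g.atom_vertex[b])
        else:
            carrier = g.add_vertex(("bond", bond.order, bond.aromatic))
            g.add_edge(g.atom_vertex[a], carrier)
            g.add_edge(carrier, g.atom_vertex[b])
    for key in sorted(entity.bond_configs):
        for x, y, rel in sorted(encode_cis_trans(entity, key)):
            carrier = g.add_vertex((rel,))
            g.add_edge(g.atom_vertex[x], carrier)
            g.add_edge(carrier, g.atom_vertex[y])
    for centre_idx in sorted(entity.stereocentres):
        sub = encode_tetrahedral(entity, entity.stereocentres[centre_idx])
        local: Dict[int, int] = {}
        for vid, colour in sub.vertices:
            local[vid] = g.add_vertex(colour)

        def resolve(ref: Tuple[str, int]) -> int:
            kind, ident = ref
            return g.atom_vertex[ident] if kind == "atom" else local[ident]

        for u, v in sub.edges:
            g.add_edge(resolve(u), resolve(v))
    return g


# ---------------------------------------------------------------------------
# Construction-time normalisation
# ---------------------------------------------------------------------------


def smallest_ring_through(entity: MolecularEntity, bond: Tuple[int, int]) -> Optional[int]:
    """Size of the smallest ring containing ``bond``, or None for acyclic bonds."""
    a, b = _edge_key(*bond)
    g = entity.to_nx()
    g.remove_edge(a, b)
    try:
        return nx.shortest_path_length(g, a, b) + 1
    except nx.NetworkXNoPath:
        return None


def drop_ring_cis_trans(entity: MolecularEntity, cutoff: int = STEREO_RING_CUTOFF) -> MolecularEntity:
    """Remove cis/trans descriptors on double bonds inside small rings.

    Ring double bonds of size ``cutoff`` or less have their geometry fixed
    by the ring itself, and descriptors on them are a known source of
    spurious mismatches between otherwise identical descriptions; they are
    discarded in place at construction time.
    """
    for key in list(entity.bond_configs):
        ring = smallest_ring_through(entity, key)
        if ring is not None and ring <= cutoff:
            del entity.bond_configs[key]
    return entity


# ---------------------------------------------------------------------------
# Entity sets
# ---------------------------------------------------------------------------


class EntitySet:
    """A set of molecular entities kept distinct by canonical key."""

    def __init__(self, entities: Iterable[MolecularEntity] = ()) -> None:
        self._by_key: Dict[str, MolecularEntity] = {}
        for e in entities:
            self.add(e)

    def add(self, entity: MolecularEntity) -> str:
        from .canonical import canonical_key  # deferred: canonical builds on molgraph

        key = canonical_key(entity)
        self._by_key.setdefault(key, entity)
        return key

    def keys(self) -> List[str]:
        return sorted(self._by_key)

    def get(self, key: str) -> MolecularEntity:
        return self._by_key[key]

    def __iter__(self):
        return iter(self._by_key[k] for k in self.keys())

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EntitySet):
            return NotImplemented
        return self.keys() == other.keys()
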