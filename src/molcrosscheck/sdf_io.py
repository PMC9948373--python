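"""MDL Molfile/SDF V2000 reading and conversion to molecular entities.

Chemically annotated 3D structures are turned into the same attributed
graphs the SMILES layer produces, applying two conversion rules that 3D
input makes necessary:

* tetrahedral chirality is perceived geometrically — an atom with four
  constitutionally distinct neighbours is chiral when the *chiral volume*
  of the unit vectors towards them exceeds a threshold (default 0.25 ų),
  which cleanly separates square-planar metal centres (volume 0) from
  tetrahedral ones (~0.51);
* metal coordination bonds, which SMILES cannot express, are first turned
  into single covalent bonds and then promoted to higher orders by
  consuming opposite formal charges on their endpoints; the sign of a
  charge is never switched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, IO, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .molgraph import (
    CLOCKWISE,
    COUNTERCLOCKWISE,
    Atom,
    Bond,
    EntitySet,
    MolGraphError,
    MolecularEntity,
    STEREO_RING_CUTOFF,
    TetrahedralCentre,
    drop_ring_cis_trans,
)

__all__ = [
    "SdfAtomRecord",
    "SdfBondRecord",
    "SdfParseError",
    "DegenerateGeometryError",
    "parse_sdf",
    "chiral_volume",
    "detect_tetrahedral",
    "normalize_coordination_bonds",
    "record_to_entities",
    "write_sdf",
    "CHIRAL_VOLUME_THRESHOLD",
]

#: Chiral volume (ų of the normalised neighbour vectors) above which a
#: four-coordinate atom is treated as tetrahedral.
CHIRAL_VOLUME_THRESHOLD = 0.25

#: V2000 bond type codes treated as metal coordination bonds ("any" bond).
COORDINATION_BOND_TYPES = (8,)

# Old-style atom-block charge column codes (0 = none, 4 = radical, ignored).
_CHARGE_COLUMN = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}

METALS = frozenset(
    """Li Be Na Mg Al K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Rb Sr Y Zr Nb Mo Tc
    Ru Rh Pd Ag Cd In Sn Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf
    Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm
    Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn""".split()
)


class SdfParseError(ValueError):
    """Malformed SDF input; names the 1-based block index."""

    def __init__(self, message: str, block: int) -> None:
        super().__init__(f"{message} (block {block})")
        self.block = block


class DegenerateGeometryError(MolGraphError):
    """Coincident atom coordinates where a direction vector is required."""


@dataclass(frozen=True)
class SdfAtomRecord:
    element: str
    xyz: Tuple[float, float, float]
    charge: int = 0
    isotope: Optional[int] = None


@dataclass(frozen=True)
class SdfBondRecord:
    a: int  # 0-based atom indices
    b: int
    type_code: int
    coordination: bool = False


SdfRecord = Tuple[List[SdfAtomRecord], List[SdfBondRecord]]


def _counts(line: str, block: int) -> Tuple[int, int]:
    """Atom and bond counts from a V2000 counts line.

    Fixed 3-character fields are tried first; whitespace-separated tokens
    are accepted as a fallback.  Counts above 999 cannot occur in a valid
    V2000 file and are rejected as format violations.
    """
    tokens = line.split()
    try:
        natoms, nbonds = int(line[0:3]), int(line[3:6])
        fixed_ok = True
    except (ValueError, IndexError):
        fixed_ok = False
    if len(tokens) >= 2 and tokens[0].isdigit() and tokens[1].isdigit():
        if len(tokens[0]) > 3 or len(tokens[1]) > 3:
            raise SdfParseError(
                "V2000 cannot describe more than 999 atoms or 999 bonds", block
            )
        if not fixed_ok:
            natoms, nbonds = int(tokens[0]), int(tokens[1])
            fixed_ok = True
    if not fixed_ok:
        raise SdfParseError("malformed counts line", block)
    if natoms > 999 or nbonds > 999:
        raise SdfParseError(
            "V2000 cannot describe more than 999 atoms or 999 bonds", block
        )
    return natoms, nbonds


def parse_sdf(stream: Union[str, IO[str]]) -> List[SdfRecord]:
    """Parse the ``$$$$``-delimited V2000 records of an SDF document."""
    text = stream if isinstance(stream, str) else stream.read()
    blocks: List[List[str]] = []
    current: List[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            blocks.append(current)
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        blocks.append(current)

    records: List[SdfRecord] = []
    for bi, lines in enumerate(blocks, start=1):
        if len(lines) < 4:
            raise SdfParseError("molfile block too short", bi)
        natoms, nbonds = _counts(lines[3], bi)
        atom_lines = lines[4 : 4 + natoms]
        bond_lines = lines[4 + natoms : 4 + natoms + nbonds]
        if len(atom_lines) < natoms:
            raise SdfParseError("atom block shorter than declared", bi)
        if len(bond_lines) < nbonds:
            raise SdfParseError("bond block shorter than declared", bi)

        atoms: List[SdfAtomRecord] = []
        for li, line in enumerate(atom_lines):
            try:
                x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
                element = line[31:34].strip()
                charge_code = int(line[36:39]) if line[36:39].strip() else 0
            except (ValueError, IndexError):
                parts = line.split()
                if len(parts) < 4:
                    raise SdfParseError(f"malformed atom line {li + 1}", bi)
                x, y, z = (float(v) for v in parts[:3])
                element = parts[3]
                charge_code = int(parts[5]) if len(parts) > 5 else 0
            if not all(np.isfinite(v) for v in (x, y, z)):
                raise SdfParseError(f"non-finite coordinates on atom line {li + 1}", bi)
            atoms.append(
                SdfAtomRecord(element, (x, y, z), _CHARGE_COLUMN.get(charge_code, 0))
            )

        bonds: List[SdfBondRecord] = []
        for li, line in enumerate(bond_lines):
            try:
                a, b, code = int(line[0:3]), int(line[3:6]), int(line[6:9])
            except (ValueError, IndexError):
                parts = line.split()
                if len(parts) < 3:
                    raise SdfParseError(f"malformed bond line {li + 1}", bi)
                a, b, code = int(parts[0]), int(parts[1]), int(parts[2])
            if not (1 <= a <= natoms and 1 <= b <= natoms):
                raise SdfParseError(f"bond endpoint out of range on line {li + 1}", bi)
            bonds.append(
                SdfBondRecord(a - 1, b - 1, code, code in COORDINATION_BOND_TYPES)
            )

        # Property lines: M CHG supersedes the charge column entirely,
        # M ISO assigns isotopes.
        charges: Dict[int, int] = {}
        isotopes: Dict[int, int] = {}
        saw_chg = False
        for line in lines[4 + natoms + nbonds :]:
            fields = line.split()
            if fields[:2] == ["M", "CHG"]:
                saw_chg = True
                values = fields[3:]
                for k in range(0, len(values) - 1, 2):
                    charges[int(values[k]) - 1] = int(values[k + 1])
            elif fields[:2] == ["M", "ISO"]:
                values = fields[3:]
                for k in range(0, len(values) - 1, 2):
                    isotopes[int(values[k]) - 1] = int(values[k + 1])
            elif fields[:2] == ["M", "END"]:
                break
        if saw_chg or isotopes:
            rebuilt = []
            for idx, atom in enumerate(atoms):
                charge = charges.get(idx, 0) if saw_chg else atom.charge
                rebuilt.append(
                    SdfAtomRecord(atom.element, atom.xyz, charge, isotopes.get(idx))
                )
            atoms = rebuilt
        records.append((atoms, bonds))
    return records


# ---------------------------------------------------------------------------
# Chirality from geometry
# ---------------------------------------------------------------------------


def chiral_volume(
    centre_xyz: Sequence[float], neighbour_xyz: Sequence[Sequence[float]]
) -> float:
    """Tetrahedron volume spanned by unit vectors towards four neighbours.

    The vectors from the centre to each neighbour are normalised before
    the volume ``|det[u2-u1, u3-u1, u4-u1]| / 6`` is taken, making the
    result invariant under rigid motions and uniform scaling.  Ideal
    square-planar geometry gives 0; ideal tetrahedral geometry gives
    about 0.513.
    """
    if len(neighbour_xyz) != 4:
        raise MolGraphError("chiral volume requires exactly 4 neighbours")
    c = np.asarray(centre_xyz, dtype=float)
    units = []
    for p in neighbour_xyz:
        v = np.asarray(p, dtype=float) - c
        norm = np.linalg.norm(v)
        if norm == 0.0:
            raise DegenerateGeometryError("neighbour coincides with the centre")
        units.append(v / norm)
    m = np.array([units[1] - units[0], units[2] - units[0], units[3] - units[0]])
    return abs(float(np.linalg.det(m))) / 6.0


def _signed_volume(
    centre_xyz: Sequence[float], neighbour_xyz: Sequence[Sequence[float]]
) -> float:
    """Unnormalised signed determinant fixing the parity of a centre."""
    pts = [np.asarray(p, dtype=float) for p in neighbour_xyz]
    m = np.array([pts[1] - pts[0], pts[2] - pts[0], pts[3] - pts[0]])
    return float(np.linalg.det(m))


def _branch_certificate(entity: MolecularEntity, centre: int, root: int) -> bytes:
    """Connectivity-only canonical certificate of a substituent branch.

    Used to decide whether the four neighbours of a candidate centre are
    constitutionally distinct: stereo descriptors are ignored, only
    element/charge/isotope colours and connectivity count, and the
    branch's root atom is marked.
    """
    from .canonical import canonical_labelling
    from .molgraph import ColoredGraph

    member = {root}
    queue = [root]
    while queue:
        u = queue.pop()
        for w in entity.neighbours(u):
            if w != centre and w not in member:
                member.add(w)
                queue.append(w)
    g = ColoredGraph()
    local: Dict[int, int] = {}
    for idx in sorted(member):
        atom = entity.atoms[idx]
        colour = (
            "root" if idx == root else "atom",
            atom.element,
            atom.charge,
            atom.isotope,
            atom.hcount,
        )
        local[idx] = g.add_vertex(colour)
    for (a, b) in entity.bonds:
        if a in member and b in member:
            g.add_edge(local[a], local[b])
    return canonical_labelling(g).certificate


def detect_tetrahedral(
    entity: MolecularEntity,
    coordinates: Optional[Mapping[int, Sequence[float]]] = None,
    threshold: float = CHIRAL_VOLUME_THRESHOLD,
) -> List[TetrahedralCentre]:
    """Perceive tetrahedral centres from 3D coordinates.

    An atom qualifies when it has exactly four constitutionally distinct
    neighbours and the chiral volume of the normalised vectors towards
    them is strictly greater than ``threshold`` (ties go to non-chiral).
    Parity follows the sign of the unnormalised determinant of the
    neighbour positions.
    """
    coords: Dict[int, Tuple[float, float, float]] = dict(coordinates or {})
    centres: List[TetrahedralCentre] = []
    for idx in sorted(entity.atoms):
        nbrs = sorted(entity.neighbours(idx))
        if len(nbrs) != 4:
            continue
        certs = [_branch_certificate(entity, idx, n) for n in nbrs]
        if len(set(certs)) != 4:
            continue
        positions = [coords[n] for n in nbrs]
        volume = chiral_volume(coords[idx], positions)
        if volume <= threshold:
            continue
        parity = CLOCKWISE if _signed_volume(coords[idx], positions) > 0 else COUNTERCLOCKWISE
        centres.append(TetrahedralCentre(idx, tuple(nbrs), parity))
    return centres


# ---------------------------------------------------------------------------
# Coordination bonds
# ---------------------------------------------------------------------------


def normalize_coordination_bonds(entity: MolecularEntity) -> MolecularEntity:
    """Rewrite metal coordination bonds as covalent bonds, in place.

    Every coordination bond first becomes a single covalent bond.  Then,
    if its endpoints carry non-zero formal charges of opposite signs, the
    bond order is raised to the lower of the absolute charges and both
    charges shrink in magnitude by that order.  Residual charges keep
    their sign; the total formal charge is conserved.  Bonds are handled
    in ascending (metal index, partner index) order.
    """

    def sort_key(key: Tuple[int, int]) -> Tuple[int, int]:
        a, b = key
        a_metal = entity.atoms[a].element in METALS
        b_metal = entity.atoms[b].element in METALS
        if b_metal and not a_metal:
            return (b, a)
        return (a, b)

    coordination = [k for k, bond in entity.bonds.items() if bond.coordination]
    for key in sorted(coordination, key=sort_key):
        a, b = key
        atom_a, atom_b = entity.atoms[a], entity.atoms[b]
        order = 1
        if atom_a.charge != 0 and atom_b.charge != 0 and (
            (atom_a.charge > 0) != (atom_b.charge > 0)
        ):
            order = min(abs(atom_a.charge), abs(atom_b.charge))
            for idx, atom in ((a, atom_a), (b, atom_b)):
                sign = 1 if atom.charge > 0 else -1
                entity.set_atom(
                    idx,
                    Atom(
                        atom.element,
                        sign * (abs(atom.charge) - order),
                        atom.isotope,
                        atom.aromatic,
                        atom.hcount,
                    ),
                )
        entity.set_bond(a, b, Bond(order=order))
    return entity


# ---------------------------------------------------------------------------
# Record -> entities
# ---------------------------------------------------------------------------


def _fill_implicit_hydrogens(entity: MolecularEntity) -> None:
    """Fill implicit hydrogen counts the way the molfile format implies them.

    V2000 atoms without explicit hydrogens are understood to carry enough
    implicit ones to reach their default valence.  Charges shift the
    effective valence (ammonium-style N+ gains a bond, anions lose
    |charge|); elements without a valence model (metals, wildcards) get
    none.
    """
    from .smiles_io import DEFAULT_VALENCES

    for idx in sorted(entity.atoms):
        atom = entity.atoms[idx]
        valences = DEFAULT_VALENCES.get(atom.element)
        if valences is None:
            continue
        if atom.charge > 0 and atom.element in ("N", "P", "B"):
            valences = tuple(v + atom.charge for v in valences)
        elif atom.charge != 0:
            valences = tuple(max(0, v - abs(atom.charge)) for v in valences)
        total = sum(
            1 if entity.bond(idx, w).aromatic else entity.bond(idx, w).order
            for w in entity.neighbours(idx)
        ) + (1 if atom.aromatic else 0)
        hcount = 0
        for v in valences:
            if v >= total:
                hcount = v - total
                break
        if hcount:
            entity.set_atom(
                idx, Atom(atom.element, atom.charge, atom.isotope, atom.aromatic, hcount)
            )


def record_to_entities(
    record: SdfRecord,
    threshold: float = CHIRAL_VOLUME_THRESHOLD,
    stereo_ring_cutoff: int = STEREO_RING_CUTOFF,
) -> EntitySet:
    """Convert one SDF record into a set of distinct molecular entities."""
    import networkx as nx

    atoms, bonds = record
    graph = MolecularEntity()
    for i, rec in enumerate(atoms):
        graph.add_atom(Atom(rec.element, rec.charge, rec.isotope), i)
    for brec in bonds:
        aromatic = brec.type_code == 4
        order = brec.type_code if brec.type_code in (1, 2, 3) else 1
        graph.add_bond(
            brec.a,
            brec.b,
            Bond(order=order, aromatic=aromatic, coordination=brec.coordination),
        )
        if aromatic:
            for idx in (brec.a, brec.b):
                atom = graph.atoms[idx]
                if not atom.aromatic:
                    graph.set_atom(
                        idx,
                        Atom(atom.element, atom.charge, atom.isotope, True, atom.hcount),
                    )
    normalize_coordination_bonds(graph)
    _fill_implicit_hydrogens(graph)

    coords = {i: rec.xyz for i, rec in enumerate(atoms)}
    entities: List[MolecularEntity] = []
    for comp in sorted(sorted(c) for c in nx.connected_components(graph.to_nx())):
        member = set(comp)
        sub = MolecularEntity()
        for idx in comp:
            sub.add_atom(graph.atoms[idx], idx)
        for (a, b), bond in graph.bonds.items():
            if a in member:
                sub.add_bond(a, b, bond)
        for centre in detect_tetrahedral(sub, coords, threshold):
            sub.add_stereocentre(centre)
        drop_ring_cis_trans(sub, stereo_ring_cutoff)
        entities.append(sub)
    return EntitySet(entities)


# ---------------------------------------------------------------------------
# Writer (fixtures and round-trip tests)
# ---------------------------------------------------------------------------


def write_sdf(
    entity: MolecularEntity,
    coordinates: Dict[int, Tuple[float, float, float]],
    title: str = "",
) -> str:
    """Serialise an entity with coordinates as one V2000 molfile block."""
    idx_order = sorted(entity.atoms)
    pos = {a: i + 1 for i, a in enumerate(idx_order)}
    lines = [title, "  molcrosscheck", ""]
    lines.append(
        "%3d%3d  0  0  0  0  0  0  0  0999 V2000" % (len(idx_order), len(entity.bonds))
    )
    for a in idx_order:
        x, y, z = coordinates[a]
        atom = entity.atoms[a]
        lines.append(
            "%10.4f%10.4f%10.4f %-3s 0  0  0  0  0  0  0  0  0  0  0  0"
            % (x, y, z, atom.element)
        )
    for (a, b), bond in sorted(entity.bonds.items()):
        code = 8 if bond.coordination else (4 if bond.aromatic else bond.order)
        lines.append("%3d%3d%3d  0  0  0  0" % (pos[a], pos[b], code))
    charged = [(pos[a], atom.charge) for a, atom in entity.atoms.items() if atom.charge]
    for start in range(0, len(charged), 8):
        chunk = charged[start : start + 8]
        lines.append(
            "M  CHG%3d" % len(chunk)
            + "".join("%4d%4d" % pair for pair in chunk)
        )
    isotopes = [
        (pos[a], atom.isotope) for a, atom in entity.atoms.items() if atom.isotope
    ]
    for start in range(0, len(isotopes), 8):
        chunk = isotopes[start : start + 8]
        lines.append(
            "M  ISO%3d" % len(chunk)
            + "".join("%4d%4d" % pair for pair in chunk)
        )
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"
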