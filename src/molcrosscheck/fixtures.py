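"""Deterministic synthetic molecules, geometries and perturbations.

Every other module is testable without downloading any database: this
generator produces connected, valence-respecting molecular graphs with
optional aromatic rings, charges, tetrahedral centres and double-bond
configurations, plus idealised 3D geometries for the chirality-from-
coordinates rules.  All randomness flows from the single seed in the
:class:`FixtureSpec`; the same spec always yields byte-identical output.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .compare import Simplification, SimplificationSet, apply_simplifications
from .molgraph import (
    CIS,
    CLOCKWISE,
    COUNTERCLOCKWISE,
    IMPLICIT_H,
    LONE_PAIR,
    TRANS,
    Atom,
    Bond,
    DoubleBondConfig,
    EntitySet,
    MolGraphError,
    MolecularEntity,
    TetrahedralCentre,
    smallest_ring_through,
)
from .sdf_io import _branch_certificate

__all__ = [
    "FixtureSpec",
    "FixtureSpecError",
    "generate_entities",
    "generate_perturbed_pairs",
    "generate_geometry",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "B": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}


class FixtureSpecError(ValueError):
    """Infeasible fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic fixture corpus.

    ``stereo_density`` is the probability that an eligible tetrahedral
    centre or double bond receives a stereo descriptor; the remaining
    fractions control how often charged atoms, aromatic rings, multiple
    bonds and extra ring closures appear.  The defaults produce small
    drug-like organics (4-12 heavy atoms) with a realistic mix of the
    features the comparison simplifications act on.
    """

    seed: int = 0
    count: int = 20
    atom_count: Tuple[int, int] = (4, 12)
    elements: Tuple[str, ...] = ("C", "C", "C", "C", "N", "O", "O", "S", "F", "Cl")
    stereo_density: float = 0.5
    charge_fraction: float = 0.15
    aromatic_fraction: float = 0.3
    multiple_bond_fraction: float = 0.25
    extra_ring_fraction: float = 0.2
    perturbation: Optional[Simplification] = None

    def validate(self) -> None:
        lo, hi = self.atom_count
        if lo < 1 or hi < lo:
            raise FixtureSpecError(f"bad atom count range {self.atom_count}")
        if not (0.0 <= self.stereo_density <= 1.0):
            raise FixtureSpecError("stereo density must be in [0, 1]")
        if self.stereo_density > 0 and hi < 4:
            raise FixtureSpecError(
                "stereo descriptors require molecules of at least 4 atoms"
            )
        for el in self.elements:
            if el not in _VALENCE:
                raise FixtureSpecError(f"element {el!r} has no valence model")
        if self.count < 1:
            raise FixtureSpecError("count must be positive")


def _grow_molecule(rng: random.Random, spec: FixtureSpec) -> MolecularEntity:
    lo, hi = spec.atom_count
    n_target = rng.randint(lo, hi)
    ent = MolecularEntity()
    free: Dict[int, int] = {}
    aromatic_ring: List[int] = []

    if n_target >= 6 and rng.random() < spec.aromatic_fraction:
        for _ in range(6):
            idx = ent.add_atom(Atom("C", aromatic=True))
            free[idx] = 1  # 4 - two ring bonds - one reserved for the pi system
            aromatic_ring.append(idx)
        for i in range(6):
            ent.add_bond(aromatic_ring[i], aromatic_ring[(i + 1) % 6], Bond(aromatic=True))
    else:
        el = rng.choice([e for e in spec.elements if _VALENCE[e] >= 2] or list(spec.elements))
        idx = ent.add_atom(Atom(el))
        free[idx] = _VALENCE[el]

    while len(ent.atoms) < n_target:
        anchors = [a for a in sorted(free) if free[a] >= 1]
        if not anchors:
            break
        anchor = rng.choice(anchors)
        el = rng.choice(spec.elements)
        idx = ent.add_atom(Atom(el))
        free[idx] = _VALENCE[el] - 1
        free[anchor] -= 1
        ent.add_bond(anchor, idx, Bond())

    # Occasional extra ring closure between distant atoms with spare valence.
    if rng.random() < spec.extra_ring_fraction:
        candidates = [
            (a, b)
            for a in sorted(free)
            for b in sorted(free)
            if a < b and free[a] >= 1 and free[b] >= 1 and not ent.has_bond(a, b)
        ]
        candidates = [
            (a, b) for a, b in candidates if _graph_distance(ent, a, b) >= 3
        ]
        if candidates:
            a, b = rng.choice(candidates)
            ent.add_bond(a, b, Bond())
            free[a] -= 1
            free[b] -= 1

    # Promote some single bonds to double/triple where valence allows.
    for key in sorted(ent.bonds):
        a, b = key
        bond = ent.bonds[key]
        if bond.aromatic:
            continue
        if free[a] >= 1 and free[b] >= 1 and rng.random() < spec.multiple_bond_fraction:
            ent.set_bond(a, b, Bond(order=2))
            free[a] -= 1
            free[b] -= 1
            if free[a] >= 1 and free[b] >= 1 and rng.random() < 0.2:
                ent.set_bond(a, b, Bond(order=3))
                free[a] -= 1
                free[b] -= 1

    # Sprinkle formal charges: alkoxide-style O(-) and ammonium-style N(+).
    for idx in sorted(ent.atoms):
        atom = ent.atoms[idx]
        if atom.aromatic:
            continue
        if atom.element == "O" and free[idx] >= 1 and rng.random() < spec.charge_fraction:
            ent.set_atom(idx, Atom("O", charge=-1))
            free[idx] -= 1
        elif atom.element == "N" and rng.random() < spec.charge_fraction:
            ent.set_atom(idx, Atom("N", charge=1))
            free[idx] += 1

    for idx in sorted(ent.atoms):
        atom = ent.atoms[idx]
        if free[idx] > 0:
            ent.set_atom(
                idx,
                Atom(atom.element, atom.charge, atom.isotope, atom.aromatic, free[idx]),
            )

    _add_stereo(rng, spec, ent)
    return ent


def _graph_distance(ent: MolecularEntity, a: int, b: int) -> int:
    import networkx as nx

    return nx.shortest_path_length(ent.to_nx(), a, b)


def _add_stereo(rng: random.Random, spec: FixtureSpec, ent: MolecularEntity) -> None:
    if spec.stereo_density <= 0:
        return
    # Tetrahedral centres: 4 distinct heavy branches, or 3 plus the
    # implicit-hydrogen sentinel as the fourth attachment.
    for idx in sorted(ent.atoms):
        atom = ent.atoms[idx]
        if atom.aromatic or atom.charge != 0:
            continue
        nbrs = sorted(ent.neighbours(idx))
        if any(not ent.bond(idx, w).is_default for w in nbrs):
            continue
        use_h = len(nbrs) == 3 and atom.hcount == 1
        if len(nbrs) != 4 and not use_h:
            continue
        certs = [_branch_certificate(ent, idx, w) for w in nbrs]
        if any(
            ent.atoms[w].element == "H" and len(ent.neighbours(w)) == 1 for w in nbrs
        ):
            continue
        if len(set(certs)) != len(certs):
            continue
        if rng.random() >= spec.stereo_density:
            continue
        neighbours = list(nbrs)
        if use_h:
            neighbours.append(IMPLICIT_H)
        parity = rng.choice((CLOCKWISE, COUNTERCLOCKWISE))
        ent.add_stereocentre(TetrahedralCentre(idx, tuple(neighbours), parity))

    # Cis/trans on acyclic double bonds with a substituent on each end.
    for key in sorted(ent.bonds):
        a, b = key
        bond = ent.bonds[key]
        if bond.order != 2 or bond.aromatic:
            continue
        if smallest_ring_through(ent, key) is not None:
            continue
        subs_a = sorted(
            x for x in ent.neighbours(a) - {b} if ent.bond(x, a).is_default
        )
        subs_b = sorted(
            y for y in ent.neighbours(b) - {a} if ent.bond(y, b).is_default
        )
        if not subs_a or not subs_b:
            continue
        if rng.random() >= spec.stereo_density:
            continue
        rel = rng.choice((CIS, TRANS))
        ent.add_bond_config(
            DoubleBondConfig((a, b), frozenset({(subs_a[0], subs_b[0], rel)}))
        )


def generate_entities(spec: FixtureSpec) -> EntitySet:
    """Generate a deterministic set of distinct synthetic entities."""
    spec.validate()
    rng = random.Random(spec.seed)
    entities = [_grow_molecule(rng, spec) for _ in range(spec.count)]
    return EntitySet(entities)


def generate_perturbed_pairs(
    spec: FixtureSpec,
) -> List[Tuple[EntitySet, EntitySet]]:
    """Pairs (original, perturbed) for the spec's perturbation.

    The second member of each pair is the original entity with one
    simplification applied — the controlled ground truth for
    perturbation-recovery checks.  Entities that vanish entirely under
    the perturbation are skipped.
    """
    spec.validate()
    if spec.perturbation is None:
        raise FixtureSpecError("spec has no perturbation")
    combo = SimplificationSet(frozenset({spec.perturbation}))
    pairs: List[Tuple[EntitySet, EntitySet]] = []
    for entity in generate_entities(spec):
        fragments = apply_simplifications(entity, combo)
        if not fragments:
            continue
        pairs.append((EntitySet([entity]), EntitySet(fragments)))
    return pairs


# ---------------------------------------------------------------------------
# Geometries
# ---------------------------------------------------------------------------

_SQUARE = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (-1.0, 0.0, 0.0), (0.0, -1.0, 0.0))
_S3 = 1.0 / math.sqrt(3.0)
# Paired with _SQUARE position-by-position so the interpolation never
# degenerates; this orientation encodes a counterclockwise centre.
_TETRA = (
    (_S3, _S3, _S3),
    (-_S3, _S3, -_S3),
    (-_S3, -_S3, _S3),
    (_S3, -_S3, -_S3),
)

_BOND_LENGTH = 2.0


def generate_geometry(
    entity: MolecularEntity,
    mode: str = "tetrahedral",
    t: Optional[float] = None,
    centre: Optional[int] = None,
) -> Dict[int, Tuple[float, float, float]]:
    """Idealised 3D coordinates around a four-coordinate centre.

    ``mode`` is ``"tetrahedral"``, ``"square_planar"`` or
    ``"interpolated"`` (with ``t`` in [0, 1] sweeping square-planar to
    tetrahedral).  If the centre carries a stereo descriptor, the
    tetrahedral arrangement matches its parity.  Other atoms get
    non-degenerate placeholder positions breadth-first from the placed
    core.
    """
    if centre is None:
        centre = next(
            (a for a in sorted(entity.atoms) if len(entity.neighbours(a)) == 4), None
        )
        if centre is None:
            raise MolGraphError("entity has no four-coordinate centre")
    nbrs: List[int]
    descriptor = entity.stereocentres.get(centre)
    if descriptor is not None:
        if LONE_PAIR in descriptor.neighbours:
            raise MolGraphError("cannot place a lone-pair attachment in space")
        nbrs = list(descriptor.neighbours)
    else:
        nbrs = sorted(entity.neighbours(centre))
    if len(nbrs) != 4:
        raise MolGraphError("geometry requires exactly 4 neighbours")

    if mode == "square_planar":
        t_val = 0.0
    elif mode == "tetrahedral":
        t_val = 1.0
    elif mode == "interpolated":
        if t is None or not (0.0 <= t <= 1.0):
            raise MolGraphError("interpolated mode needs t in [0, 1]")
        t_val = float(t)
    else:
        raise MolGraphError(f"unknown geometry mode {mode!r}")

    tetra = list(_TETRA)
    if descriptor is not None and descriptor.parity == CLOCKWISE:
        tetra[2], tetra[3] = tetra[3], tetra[2]

    coords: Dict[int, Tuple[float, float, float]] = {centre: (0.0, 0.0, 0.0)}
    for i, atom_idx in enumerate(nbrs):
        sq, te = _SQUARE[i], tetra[i]
        v = tuple((1.0 - t_val) * s + t_val * e for s, e in zip(sq, te))
        norm = math.sqrt(sum(c * c for c in v))
        coords[atom_idx] = tuple(_BOND_LENGTH * c / norm for c in v)

    # Remaining atoms: deterministic, non-coincident filler positions.
    queue = [centre] + nbrs
    placed = set(queue)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    while queue:
        u = queue.pop(0)
        ux, uy, uz = coords[u]
        for w in sorted(entity.neighbours(u)):
            if w in placed:
                continue
            angle = golden * (w + 1)
            z = math.cos(0.3 * (w + 1))
            r = math.sqrt(max(1e-6, 1.0 - z * z))
            coords[w] = (
                ux + 1.5 * r * math.cos(angle),
                uy + 1.5 * r * math.sin(angle),
                uz + 1.5 * z,
            )
            placed.add(w)
            queue.append(w)
    return coords
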