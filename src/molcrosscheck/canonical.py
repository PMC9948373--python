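"""Canonical labelling of coloured graphs and canonical entity keys.

The labeller is an individualisation–refinement search: stable colour
refinement (1-WL) partitions the vertices; non-singleton cells are broken
by individualising each candidate vertex in turn; the leaf whose
adjacency certificate is lexicographically smallest defines the canonical
order.  Discovered automorphisms prune candidate branches (orbit
pruning), which keeps highly symmetric graphs tractable.

Two coloured graphs are isomorphic exactly when their certificates are
byte-identical.  Entity keys are canonical SMILES written in the atom
order the labelling induces; whenever keys match, callers can re-verify
with :func:`verify_isomorphic`, an independent VF2-based check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from networkx.algorithms import isomorphism as nxiso

from .molgraph import ColoredGraph, MolecularEntity, to_colored_graph

__all__ = [
    "CanonicalLabelling",
    "canonical_labelling",
    "canonical_key",
    "verify_isomorphic",
]


@dataclass(frozen=True)
class CanonicalLabelling:
    """Result of canonicalising a coloured graph.

    ``permutation`` maps each vertex to its canonical rank (0..n-1);
    ``certificate`` is a byte string shared by all isomorphic graphs and
    by no others.
    """

    permutation: Dict[int, int]
    certificate: bytes


def _refine(adj: List[frozenset], cells: List[List[int]]) -> List[List[int]]:
    """Stable colour refinement: split cells by neighbour-cell multisets."""
    n = len(adj)
    while True:
        cell_of = [0] * n
        for ci, cell in enumerate(cells):
            for v in cell:
                cell_of[v] = ci
        new_cells: List[List[int]] = []
        changed = False
        for cell in cells:
            if len(cell) == 1:
                new_cells.append(cell)
                continue
            sig: Dict[int, Tuple] = {}
            for v in cell:
                counts: Dict[int, int] = {}
                for w in adj[v]:
                    c = cell_of[w]
                    counts[c] = counts.get(c, 0) + 1
                sig[v] = tuple(sorted(counts.items()))
            groups: Dict[Tuple, List[int]] = {}
            for v in cell:
                groups.setdefault(sig[v], []).append(v)
            if len(groups) == 1:
                new_cells.append(cell)
            else:
                changed = True
                for key in sorted(groups):
                    new_cells.append(groups[key])
        cells = new_cells
        if not changed:
            return cells


def _adjacency_bits(adj: List[frozenset], order: List[int]) -> bytes:
    """Upper-triangular adjacency of the reordered graph, packed into bytes."""
    n = len(order)
    pos = {v: i for i, v in enumerate(order)}
    bits = bytearray((n * (n - 1) // 2 + 7) // 8)
    k = 0
    for i in range(n):
        vi = order[i]
        nbrs = adj[vi]
        for j in range(i + 1, n):
            if order[j] in nbrs:
                bits[k >> 3] |= 0x80 >> (k & 7)
            k += 1
    return bytes(bits)


def _orbit_reps(n: int, generators: List[List[int]], fixed: List[int]) -> List[int]:
    """Union-find orbit labels under generators that fix ``fixed`` pointwise."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    fixed_set = set(fixed)
    for g in generators:
        if any(g[v] != v for v in fixed_set):
            continue
        for v in range(n):
            a, b = find(v), find(g[v])
            if a != b:
                parent[a] = b
    return [find(v) for v in range(n)]


def canonical_labelling(g: ColoredGraph) -> CanonicalLabelling:
    """Canonical vertex ranks and isomorphism-class certificate of ``g``."""
    n = g.n
    colour_key = [repr(c) for c in g.colors]
    if n == 0:
        return CanonicalLabelling({}, b"colored-graph:0:")
    adj = [frozenset(s) for s in g.adj]

    # Initial partition: cells ordered by colour value.  Refinement and
    # individualisation only ever split cells in place, so the colour
    # sequence along ranks is identical at every search leaf and the
    # certificates can be compared on adjacency alone.
    by_colour: Dict[str, List[int]] = {}
    for v in range(n):
        by_colour.setdefault(colour_key[v], []).append(v)
    initial = [by_colour[c] for c in sorted(by_colour)]

    best: Dict[str, object] = {"bits": None, "order": None}
    generators: List[List[int]] = []

    def descend(cells: List[List[int]], fixed: List[int]) -> None:
        cells = _refine(adj, cells)
        target = next((i for i, c in enumerate(cells) if len(c) > 1), None)
        if target is None:
            order = [c[0] for c in cells]
            bits = _adjacency_bits(adj, order)
            if best["bits"] is None or bits < best["bits"]:  # type: ignore[operator]
                best["bits"] = bits
                best["order"] = order
            elif bits == best["bits"]:
                # Equal certificates witness an automorphism; keep it for
                # orbit pruning of later branches.
                prev: List[int] = best["order"]  # type: ignore[assignment]
                perm = [0] * n
                for rank, v in enumerate(order):
                    perm[v] = prev[rank]
                generators.append(perm)
            return
        cell = cells[target]
        tried: set = set()
        for v in sorted(cell):
            # recomputed per candidate: generators accumulate during recursion
            reps = _orbit_reps(n, generators, fixed)
            if reps[v] in tried:
                continue
            tried.add(reps[v])
            split = (
                cells[:target]
                + [[v], [w for w in cell if w != v]]
                + cells[target + 1 :]
            )
            descend(split, fixed + [v])

    descend(initial, [])
    order: List[int] = best["order"]  # type: ignore[assignment]
    permutation = {v: rank for rank, v in enumerate(order)}
    header = "colored-graph:%d:%s:" % (
        n,
        "|".join(colour_key[v] for v in order),
    )
    certificate = header.encode() + best["bits"]  # type: ignore[operator]
    return CanonicalLabelling(permutation, certificate)


def canonical_key(entity: MolecularEntity) -> str:
    """Canonical SMILES key of a molecular entity.

    The entity is flattened to its coloured graph, canonically labelled,
    and written as SMILES in the induced atom order.  Equal keys imply
    isomorphic entities (and can be re-verified with
    :func:`verify_isomorphic`).
    """
    from .smiles_io import write_canonical_smiles

    g = to_colored_graph(entity)
    labelling = canonical_labelling(g)
    atoms = sorted(entity.atoms, key=lambda a: labelling.permutation[g.atom_vertex[a]])
    ranks = {a: i for i, a in enumerate(atoms)}
    return write_canonical_smiles(entity, ranks)


def verify_isomorphic(
    a: MolecularEntity, b: MolecularEntity
) -> Tuple[bool, Optional[Dict[int, int]]]:
    """Exact colour-respecting isomorphism test with a witness atom mapping.

    This is the safety re-check behind key matching: it runs VF2 on the
    coloured graphs, independently of the canonical labelling, and returns
    the atom-to-atom correspondence when the entities are isomorphic.
    """
    ga, gb = to_colored_graph(a), to_colored_graph(b)
    if sorted(map(repr, ga.colors)) != sorted(map(repr, gb.colors)):
        return False, None
    matcher = nxiso.GraphMatcher(
        ga.to_nx(), gb.to_nx(), node_match=nxiso.categorical_node_match("color", None)
    )
    if not matcher.is_isomorphic():
        return False, None
    vertex_map = matcher.mapping
    vertex_to_atom_b = {v: atom for atom, v in gb.atom_vertex.items()}
    atom_map = {
        atom: vertex_to_atom_b[vertex_map[v]] for atom, v in ga.atom_vertex.items()
    }
    return True, atom_map
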