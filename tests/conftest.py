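import random

import pytest

from molcrosscheck import EntitySet, FixtureSpec, generate_entities, parse_smiles
from molcrosscheck.molgraph import ColoredGraph


def entity_set(*smiles: str) -> EntitySet:
    entities = []
    for s in smiles:
        entities.extend(parse_smiles(s))
    return EntitySet(entities)


def shuffled_relabelling(entity, seed: int):
    """The same entity under a seeded random permutation of atom ids."""
    ids = sorted(entity.atoms)
    shuffled = ids[:]
    random.Random(seed).shuffle(shuffled)
    return entity.relabel(dict(zip(ids, shuffled)))


def random_colored_graph(rng: random.Random, max_vertices: int = 12) -> ColoredGraph:
    n = rng.randint(1, max_vertices)
    g = ColoredGraph()
    n_colours = rng.randint(1, 3)
    for _ in range(n):
        g.add_vertex(("c", rng.randrange(n_colours)))
    p = rng.choice([0.15, 0.3, 0.5])
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


def permuted_colored_graph(g: ColoredGraph, rng: random.Random) -> ColoredGraph:
    perm = list(range(g.n))
    rng.shuffle(perm)
    h = ColoredGraph()
    for _ in range(g.n):
        h.add_vertex(None)
    for i in range(g.n):
        h.colors[perm[i]] = g.colors[i]
    for u, nbrs in enumerate(g.adj):
        for v in nbrs:
            if u < v:
                h.add_edge(perm[u], perm[v])
    return h


@pytest.fixture(scope="session")
def fixture_corpus() -> EntitySet:
    """A small, diverse corpus of synthetic entities shared across tests."""
    return generate_entities(FixtureSpec(seed=2024, count=25))


@pytest.fixture(scope="session")
def stereo_corpus() -> EntitySet:
    """Fixture corpus with stereo descriptors on every eligible site."""
    return generate_entities(FixtureSpec(seed=77, count=25, stereo_density=1.0))
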