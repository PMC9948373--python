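"""Molecular graph model and stereo-to-subgraph encodings."""

import pytest

from networkx.algorithms import isomorphism as nxiso

from molcrosscheck.molgraph import (
    CIS,
    CLOCKWISE,
    COLOUR_DOT,
    COLOUR_ENUM,
    COUNTERCLOCKWISE,
    LONE_PAIR,
    TRANS,
    Atom,
    Bond,
    ConfigurationConflictError,
    DoubleBondConfig,
    MolGraphError,
    MolecularEntity,
    StereoEncodingError,
    TetrahedralCentre,
    drop_ring_cis_trans,
    encode_cis_trans,
    encode_tetrahedral,
    to_colored_graph,
)
from molcrosscheck.smiles_io import parse_one

from conftest import shuffled_relabelling


def colored_iso(g1, g2) -> bool:
    return nxiso.GraphMatcher(
        g1.to_nx(), g2.to_nx(), node_match=nxiso.categorical_node_match("color", None)
    ).is_isomorphic()


class TestTypes:
    def test_atom_invariants(self):
        with pytest.raises(MolGraphError):
            Atom("Xx")
        with pytest.raises(MolGraphError):
            Atom("C", hcount=-1)
        with pytest.raises(MolGraphError):
            Atom("C", isotope=0)
        assert Atom("*").element == "*"

    def test_bond_invariants(self):
        with pytest.raises(MolGraphError):
            Bond(order=0)
        assert Bond().is_default
        assert not Bond(order=2).is_default
        assert not Bond(aromatic=True).is_default

    def test_tetrahedral_centre_invariants(self):
        with pytest.raises(StereoEncodingError):
            TetrahedralCentre(0, (1, 2, 3, 3), CLOCKWISE)
        with pytest.raises(StereoEncodingError):
            TetrahedralCentre(0, (1, 2, 3, 4), "sideways")
        centre = TetrahedralCentre(0, (1, 2, 3, 4), COUNTERCLOCKWISE)
        assert centre.clockwise_order() == (1, 2, 4, 3)

    def test_self_bond_rejected(self):
        e = MolecularEntity()
        e.add_atom(Atom("C"))
        with pytest.raises(MolGraphError):
            e.add_bond(0, 0)


class TestCisTransEncoding:
    def test_fully_substituted_bond_yields_four_edges(self):
        entity = parse_one("F/C(Cl)=C(/Br)I")
        bond = sorted(entity.bond_configs)[0]
        edges = encode_cis_trans(entity, bond)
        assert len(edges) == 4
        # one relation per substituent pair, closed under consistency
        pair_rels = {(x, y): rel for x, y, rel in edges}
        assert len(pair_rels) == 4
        rels = sorted(pair_rels.values())
        assert rels.count(CIS) == 2 and rels.count(TRANS) == 2

    def test_mono_substituted_bond_yields_one_edge(self):
        entity = parse_one("F/C=C/F")
        bond = sorted(entity.bond_configs)[0]
        assert len(encode_cis_trans(entity, bond)) == 1

    def test_unconfigured_bond_yields_empty_set(self):
        entity = parse_one("C=C")
        bond = sorted(entity.bonds)[0]
        assert encode_cis_trans(entity, bond) == set()

    def test_conflicting_relations_rejected(self):
        entity = parse_one("FC(Cl)=C(Br)I")
        atoms = {a.element: i for i, a in entity.atoms.items()}
        bond = next(k for k, b in entity.bonds.items() if b.order == 2)
        with pytest.raises(ConfigurationConflictError):
            entity.add_bond_config(
                DoubleBondConfig(
                    bond,
                    frozenset(
                        {
                            (atoms["F"], atoms["Br"], CIS),
                            (atoms["F"], atoms["Br"], TRANS),
                        }
                    ),
                )
            )

    def test_same_side_pair_rejected(self):
        # Two substituents of one endpoint cannot both be cis to the same
        # partner across the bond.
        entity = parse_one("FC(Cl)=C(Br)I")
        atoms = {a.element: i for i, a in entity.atoms.items()}
        bond = next(k for k, b in entity.bonds.items() if b.order == 2)
        with pytest.raises(ConfigurationConflictError):
            entity.add_bond_config(
                DoubleBondConfig(
                    bond,
                    frozenset(
                        {
                            (atoms["F"], atoms["Br"], CIS),
                            (atoms["Cl"], atoms["Br"], CIS),
                        }
                    ),
                )
            )


class TestTetrahedralEncoding:
    def test_twelve_enumeration_vertices(self):
        entity = parse_one("N[C@](Br)(O)C")
        centre = next(iter(entity.stereocentres.values()))
        sub = encode_tetrahedral(entity, centre)
        enums = [v for v in sub.vertices if v[1] == COLOUR_ENUM]
        dots = [v for v in sub.vertices if v[1] == COLOUR_DOT]
        assert len(enums) == 12
        # order labels: chains of 1+2+3 dots per enumeration vertex
        assert len(dots) == 12 * 6

    def test_neighbour_order_invariance(self):
        entity = parse_one("N[C@](Br)(O)C")
        centre = next(iter(entity.stereocentres.values()))
        base = to_colored_graph(entity)
        # same spatial configuration, attachments listed differently:
        # swapping two attachments flips the handedness symbol
        a, b, c, d = centre.neighbours
        entity.stereocentres[centre.centre] = TetrahedralCentre(
            centre.centre,
            (b, a, c, d),
            CLOCKWISE if centre.parity == COUNTERCLOCKWISE else COUNTERCLOCKWISE,
        )
        assert colored_iso(base, to_colored_graph(entity))

    def test_mirror_image_not_isomorphic(self):
        entity = parse_one("N[C@](Br)(O)C")
        mirror = parse_one("N[C@@](Br)(O)C")
        assert not colored_iso(to_colored_graph(entity), to_colored_graph(mirror))

    def test_lone_pair_attachment_allowed(self):
        entity = parse_one("[S@](=O)(C)CC")
        centre = next(iter(entity.stereocentres.values()))
        assert LONE_PAIR in centre.neighbours
        sub = encode_tetrahedral(entity, centre)
        assert sum(1 for v in sub.vertices if v[1] == COLOUR_ENUM) == 12


class TestColoredGraph:
    def test_single_atom(self):
        e = MolecularEntity()
        e.add_atom(Atom("C", hcount=4))
        g = to_colored_graph(e)
        assert g.n == 1 and g.edge_count() == 0

    def test_default_bond_no_carrier(self):
        g = to_colored_graph(parse_one("CC"))
        assert g.n == 2 and g.edge_count() == 1

    def test_double_bond_carrier_vertex(self):
        g = to_colored_graph(parse_one("C=C"))
        assert g.n == 3 and g.edge_count() == 2
        carrier = [c for c in g.colors if c[0] == "bond"]
        assert carrier == [("bond", 2, False)]

    def test_hand_built_reference_graph(self):
        g = to_colored_graph(parse_one("C=C"))
        from molcrosscheck.molgraph import ColoredGraph

        ref = ColoredGraph()
        a = ref.add_vertex(("atom", "C", 0, None, False, 2))
        b = ref.add_vertex(("atom", "C", 0, None, False, 2))
        k = ref.add_vertex(("bond", 2, False))
        ref.add_edge(a, k)
        ref.add_edge(k, b)
        assert colored_iso(g, ref)

    def test_encoding_invariant_under_relabelling(self, stereo_corpus):
        for entity in list(stereo_corpus)[:6]:
            if len(entity) > 15:
                continue
            other = shuffled_relabelling(entity, seed=3)
            assert colored_iso(to_colored_graph(entity), to_colored_graph(other))


class TestRingCisTransCutoff:
    @pytest.mark.parametrize(
        "smiles,ring,kept",
        [
            ("C/1=C\\CCCCCC1", 8, False),   # 8-ring: descriptor dropped
            ("C/1=C\\CCCCCCC1", 9, True),   # 9-ring: descriptor kept
            ("F/C=C/F", None, True),        # acyclic: kept
        ],
    )
    def test_cutoff(self, smiles, ring, kept):
        entity = parse_one(smiles)
        assert bool(entity.bond_configs) == kept

    def test_configurable_cutoff(self):
        entity = parse_one("C/1=C\\CCCCCCC1")  # 9-ring
        assert entity.bond_configs
        drop_ring_cis_trans(entity, cutoff=9)
        assert not entity.bond_configs
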