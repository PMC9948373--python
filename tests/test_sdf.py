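"""SDF V2000 reading, chiral-volume perception, coordination bonds."""

import math
import random

import pytest

from molcrosscheck.canonical import canonical_key
from molcrosscheck.fixtures import generate_geometry
from molcrosscheck.molgraph import (
    CLOCKWISE,
    COUNTERCLOCKWISE,
    Atom,
    Bond,
    MolecularEntity,
    TetrahedralCentre,
)
from molcrosscheck.sdf_io import (
    DegenerateGeometryError,
    SdfParseError,
    chiral_volume,
    detect_tetrahedral,
    normalize_coordination_bonds,
    parse_sdf,
    record_to_entities,
    write_sdf,
)
from molcrosscheck.smiles_io import parse_one

METHANE_BLOCK = """methane
  test

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
"""

SQUARE = [(1.0, 0, 0), (0, 1.0, 0), (-1.0, 0, 0), (0, -1.0, 0)]
TETRA = [(1.0, 1, 1), (1, -1.0, -1), (-1, 1.0, -1), (-1, -1, 1.0)]
IDEAL_TETRA_VOLUME = 8.0 / (9.0 * math.sqrt(3.0))  # |det|/6 of unit corner vectors


class TestParseSdf:
    def test_minimal_methane(self):
        records = parse_sdf(METHANE_BLOCK)
        assert len(records) == 1
        atoms, bonds = records[0]
        assert len(atoms) == 1 and len(bonds) == 0
        assert atoms[0].element == "C"

    def test_two_concatenated_blocks(self):
        assert len(parse_sdf(METHANE_BLOCK * 2)) == 2

    def test_thousand_atom_block_rejected(self):
        bad = "t\n\n\n1000  0  0  0  0  0  0  0  0  0999 V2000\n"
        with pytest.raises(SdfParseError) as err:
            parse_sdf(bad)
        assert "999" in str(err.value)

    def test_short_atom_block_names_block_index(self):
        bad = METHANE_BLOCK + "t\n\n\n  2  0  0  0  0  0  0  0  0  0999 V2000\n"
        with pytest.raises(SdfParseError) as err:
            parse_sdf(bad)
        assert err.value.block == 2

    def test_m_chg_overrides_charge_column(self):
        block = (
            "t\n\n\n  1  0  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 N   0  3  0  0  0  0  0  0  0  0  0  0\n"
            "M  CHG  1   1  -1\n"
            "M  END\n$$$$\n"
        )
        atoms, _ = parse_sdf(block)[0]
        assert atoms[0].charge == -1

    def test_m_iso(self):
        block = (
            "t\n\n\n  1  0  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "M  ISO  1   1  13\n"
            "M  END\n$$$$\n"
        )
        atoms, _ = parse_sdf(block)[0]
        assert atoms[0].isotope == 13


class TestChiralVolume:
    def test_square_planar_is_flat(self):
        assert chiral_volume((0, 0, 0), SQUARE) == pytest.approx(0.0, abs=1e-12)

    def test_ideal_tetrahedron(self):
        assert chiral_volume((0, 0, 0), TETRA) == pytest.approx(
            IDEAL_TETRA_VOLUME, abs=1e-9
        )

    def test_scaling_invariance(self):
        scaled = [(10 * x, 10 * y, 10 * z) for x, y, z in TETRA]
        assert chiral_volume((0, 0, 0), scaled) == pytest.approx(
            chiral_volume((0, 0, 0), TETRA), abs=1e-9
        )

    def test_rigid_motion_invariance(self):
        shifted = [(x + 3, y - 1, z + 7) for x, y, z in TETRA]
        assert chiral_volume((3, -1, 7), shifted) == pytest.approx(
            IDEAL_TETRA_VOLUME, abs=1e-9
        )

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            chiral_volume((0, 0, 0), [(0, 0, 0)] + TETRA[1:])


class TestDetectTetrahedral:
    def entity(self):
        return parse_one("C(N)(O)(F)Cl")

    def test_square_planar_not_chiral(self):
        e = self.entity()
        coords = generate_geometry(e, "square_planar", centre=0)
        assert detect_tetrahedral(e, coords) == []

    def test_tetrahedral_detected(self):
        e = self.entity()
        coords = generate_geometry(e, "tetrahedral", centre=0)
        centres = detect_tetrahedral(e, coords)
        assert len(centres) == 1 and centres[0].centre == 0

    def test_three_neighbours_not_considered(self):
        e = parse_one("C(N)(O)F")
        coords = {i: (float(i), i * 0.7, i * i * 0.3) for i in e.atoms}
        assert detect_tetrahedral(e, coords) == []

    def test_identical_substituents_not_chiral(self):
        e = parse_one("C(F)(F)(Cl)Br")
        coords = generate_geometry(e, "tetrahedral", centre=0)
        assert detect_tetrahedral(e, coords) == []

    def test_threshold_switch_matches_volume_crossing(self):
        e = self.entity()
        detected, volumes = [], []
        for step in range(11):
            t = step / 10
            coords = generate_geometry(e, "interpolated", t=t, centre=0)
            nbrs = sorted(e.neighbours(0))
            volumes.append(chiral_volume(coords[0], [coords[n] for n in nbrs]))
            detected.append(bool(detect_tetrahedral(e, coords)))
        assert volumes == sorted(volumes)  # monotone in the distortion
        for vol, hit in zip(volumes, detected):
            assert hit == (vol > 0.25)

    def test_mirroring_flips_parity(self):
        e = self.entity()
        coords = generate_geometry(e, "tetrahedral", centre=0)
        mirrored = {k: (-x, y, z) for k, (x, y, z) in coords.items()}
        p1 = detect_tetrahedral(e, coords)[0].parity
        p2 = detect_tetrahedral(e, mirrored)[0].parity
        assert {p1, p2} == {CLOCKWISE, COUNTERCLOCKWISE}

    def test_parity_round_trip_through_geometry(self):
        for parity in (CLOCKWISE, COUNTERCLOCKWISE):
            e = self.entity()
            e.add_stereocentre(TetrahedralCentre(0, tuple(sorted(e.neighbours(0))), parity))
            coords = generate_geometry(e, "tetrahedral", centre=0)
            assert detect_tetrahedral(e, coords)[0].parity == parity


class TestCoordinationBonds:
    def build(self, metal_charge, ligand_charge):
        e = MolecularEntity()
        e.add_atom(Atom("Pt", charge=metal_charge))
        e.add_atom(Atom("O", charge=ligand_charge))
        e.add_bond(0, 1, Bond(order=1, coordination=True))
        return e

    @pytest.mark.parametrize(
        "qm,ql,order,out_m,out_l",
        [
            (2, -2, 2, 0, 0),
            (3, -1, 1, 2, 0),
            (2, 0, 1, 2, 0),
            (-2, 3, 2, 0, 1),
            (0, 0, 1, 0, 0),
            (1, 1, 1, 1, 1),  # same-sign charges untouched
        ],
    )
    def test_charge_arithmetic(self, qm, ql, order, out_m, out_l):
        e = normalize_coordination_bonds(self.build(qm, ql))
        assert e.bonds[(0, 1)].order == order
        assert not e.bonds[(0, 1)].coordination
        assert (e.atoms[0].charge, e.atoms[1].charge) == (out_m, out_l)

    def test_total_charge_conserved_randomised(self):
        rng = random.Random(17)
        for _ in range(100):
            e = MolecularEntity()
            m = e.add_atom(Atom("Fe", charge=rng.randint(-3, 3)))
            ligands = []
            for i in range(rng.randint(1, 4)):
                l = e.add_atom(Atom("O", charge=rng.randint(-3, 3)))
                e.add_bond(m, l, Bond(order=1, coordination=True))
                ligands.append(l)
            before = e.total_charge
            signs_before = {i: a.charge for i, a in e.atoms.items()}
            normalize_coordination_bonds(e)
            assert e.total_charge == before
            for idx, old in signs_before.items():
                new = e.atoms[idx].charge
                assert old * new >= 0  # sign never switches


class TestRecordConversion:
    def test_sdf_round_trip_preserves_key(self, fixture_corpus):
        for entity in list(fixture_corpus)[:8]:
            if entity.stereocentres or entity.bond_configs:
                continue  # geometry-free placement cannot encode stereo faithfully
            coords = {a: (float(a) * 1.3, a * 0.7 + 1, 0.2 * a * a) for a in entity.atoms}
            record = parse_sdf(write_sdf(entity, coords))[0]
            converted = record_to_entities(record)
            assert canonical_key(entity) in converted.keys()

    def test_coordination_bond_code_8(self):
        block = (
            "t\n\n\n  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 Pt  0  0  0  0  0  0  0  0  0  0  0  0\n"
            "    2.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "  1  2  8  0  0  0  0\n"
            "M  CHG  2   1   2   2  -2\n"
            "M  END\n$$$$\n"
        )
        entities = record_to_entities(parse_sdf(block)[0])
        entity = next(iter(entities))
        assert entity.bonds[(0, 1)].order == 2
        assert entity.total_charge == 0
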