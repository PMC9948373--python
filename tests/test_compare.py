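"""Simplification lattice, entity-set comparison and duplicate search."""

import pytest

from molcrosscheck.canonical import canonical_key
from molcrosscheck.compare import (
    Simplification,
    SimplificationSet,
    Verdict,
    all_combinations,
    apply_simplifications,
    compare_combinations,
    compare_entity_sets,
    find_duplicates,
)
from molcrosscheck.smiles_io import parse_one

from conftest import entity_set


def simplified_keys(entity, combo):
    return sorted(canonical_key(f) for f in apply_simplifications(entity, combo))


class TestBinEncoding:
    def test_empty_set(self):
        assert SimplificationSet.of().encoding == "0000000"

    def test_full_set(self):
        assert SimplificationSet.of(*Simplification).encoding == "1111111"

    def test_chiral_marker_is_least_significant(self):
        assert SimplificationSet.of("s@").encoding == "0000001"
        assert SimplificationSet.of("se").encoding == "1000000"

    def test_charges_and_chirality(self):
        # s@ is bit 1, s± bit 3, per the stated least-significant-bit rule
        assert SimplificationSet.of("s@", "s±").encoding == "0000101"

    def test_encoding_length_always_seven(self):
        assert all(len(c.encoding) == 7 for c in all_combinations())


class TestCombinationOrder:
    def test_exactly_128_combinations_starting_empty(self):
        combos = all_combinations()
        assert len(combos) == 128
        assert combos[0].members == frozenset()
        assert len({c.encoding for c in combos}) == 128

    def test_categories_partition_the_order(self):
        cats = [c.category for c in all_combinations()]
        assert cats == sorted(cats)
        assert cats.count(1) == 32 and cats.count(2) == 32 and cats.count(3) == 64

    def test_adjacent_pairs_strictly_ordered(self):
        combos = all_combinations()
        for a, b in zip(combos, combos[1:]):
            assert compare_combinations(a, b) == -1
            assert (a.category, len(a.members), a.value) < (
                b.category,
                len(b.members),
                b.value,
            )

    def test_singletons_ordered_by_position(self):
        assert SimplificationSet.of("s@") < SimplificationSet.of("sct")

    def test_hydrogens_deferred_past_category_one(self):
        big_cat1 = SimplificationSet.of("s@", "sct", "s±", "sb", "sa")
        assert big_cat1 < SimplificationSet.of("sh")

    def test_atom_types_always_last(self):
        with_se = [c for c in all_combinations() if Simplification.ATOM_TYPES in c.members]
        without = [c for c in all_combinations() if Simplification.ATOM_TYPES not in c.members]
        assert max(without) < min(with_se)


class TestApplySimplifications:
    def test_empty_combination_is_identity(self, fixture_corpus):
        for entity in list(fixture_corpus)[:5]:
            assert simplified_keys(entity, SimplificationSet.of()) == [
                canonical_key(entity)
            ]

    def test_chirality_stripping_merges_enantiomers(self):
        r = parse_one("N[C@](Br)(O)C")
        s = parse_one("N[C@@](Br)(O)C")
        combo = SimplificationSet.of("s@")
        assert simplified_keys(r, combo) == simplified_keys(s, combo)

    def test_aromatic_vs_kekule_reconciled_by_sa_sb(self):
        aromatic = parse_one("c1ccccc1")
        kekule = parse_one("C1=CC=CC=C1")
        combo = SimplificationSet.of("sa", "sb")
        assert simplified_keys(aromatic, combo) == simplified_keys(kekule, combo)
        # neither alone suffices
        for partial in (SimplificationSet.of("sa"), SimplificationSet.of("sb")):
            assert simplified_keys(aromatic, partial) != simplified_keys(kekule, partial)

    def test_hydrogen_removal_zeroes_counts_and_descriptors(self):
        entity = parse_one("N[C@@H](C)O")
        (stripped,) = apply_simplifications(entity, SimplificationSet.of("sh"))
        assert all(a.hcount == 0 for a in stripped.atoms.values())
        assert not stripped.stereocentres  # centre referenced its implicit H

    def test_atom_type_removal_wildcards_everything(self):
        entity = parse_one("[13CH3]Cl")
        (wild,) = apply_simplifications(entity, SimplificationSet.of("se"))
        assert all(a.element == "*" and a.isotope is None for a in wild.atoms.values())

    def test_never_cumulative(self):
        entity = parse_one("C[C@H](N)C(=O)[O-]")
        key_before = canonical_key(entity)
        apply_simplifications(entity, SimplificationSet.of(*Simplification))
        assert canonical_key(entity) == key_before

    def test_idempotence(self, stereo_corpus):
        for entity in list(stereo_corpus)[:5]:
            for combo in (
                SimplificationSet.of("s@", "s±"),
                SimplificationSet.of("sh"),
                SimplificationSet.of("se", "sb"),
            ):
                once = apply_simplifications(entity, combo)
                twice = [g for f in once for g in apply_simplifications(f, combo)]
                assert sorted(canonical_key(f) for f in once) == sorted(
                    canonical_key(g) for g in twice
                )


class TestCompareEntitySets:
    def test_equal_sets_identical(self, fixture_corpus):
        report = compare_entity_sets(fixture_corpus, fixture_corpus)
        assert report.verdict is Verdict.IDENTICAL
        assert report.minimal is None

    def test_racemate_vs_achiral_needs_chirality_stripping(self):
        racemate = entity_set("N[C@@H](C)C(=O)O", "N[C@H](C)C(=O)O")
        achiral = entity_set("NC(C)C(=O)O")
        report = compare_entity_sets(racemate, achiral)
        assert report.verdict is Verdict.SIMPLIFIED
        assert report.minimal == SimplificationSet.of("s@")
        assert len(report.collations) == 1
        assert len(report.collations[0].merged_keys) == 2

    def test_superfluous_entity_gives_subset(self):
        report = compare_entity_sets(entity_set("CCO", "O"), entity_set("CCO"))
        assert report.verdict is Verdict.SUBSET
        assert report.subset_side == "B"
        assert report.unmatched_a == [canonical_key(parse_one("O"))]

    def test_mismatch_when_nothing_reconciles(self):
        report = compare_entity_sets(entity_set("CCO"), entity_set("CCCCO"))
        assert report.verdict is Verdict.MISMATCH
        assert report.combinations_tried == 128

    def test_symmetry(self, stereo_corpus):
        cases = [
            (entity_set("N[C@@H](C)C(=O)O"), entity_set("NC(C)C(=O)O")),
            (entity_set("c1ccccc1"), entity_set("C1=CC=CC=C1")),
            (entity_set("CCO", "O"), entity_set("CCO")),
        ]
        for a, b in cases:
            fwd = compare_entity_sets(a, b)
            rev = compare_entity_sets(b, a)
            assert fwd.verdict == rev.verdict
            assert fwd.minimal == rev.minimal

    def test_minimality_by_exhaustive_recheck(self):
        a = entity_set("N[C@@H](/C=C/F)O")
        b = entity_set("NC(C=CF)O")
        report = compare_entity_sets(a, b)
        assert report.verdict is Verdict.SIMPLIFIED
        minimal = report.minimal
        for combo in all_combinations():
            if combo == minimal:
                break
            keys_a = {k for e in a for k in simplified_keys(e, combo)}
            keys_b = {k for e in b for k in simplified_keys(e, combo)}
            assert keys_a != keys_b, f"{combo} should not reconcile before {minimal}"

    def test_report_serialises(self):
        report = compare_entity_sets(entity_set("c1ccccc1"), entity_set("C1=CC=CC=C1"))
        payload = report.to_dict()
        assert payload["verdict"] == "isomorphic-with-simplifications"
        assert payload["minimal"]["bin"] == SimplificationSet.of("sa", "sb").encoding


class TestPerturbationRecovery:
    @pytest.mark.parametrize("simplification", list(Simplification))
    def test_single_perturbations_recovered_as_minimal(self, simplification):
        from molcrosscheck.fixtures import FixtureSpec, generate_perturbed_pairs

        spec = FixtureSpec(
            seed=31,
            count=10,
            stereo_density=1.0,
            charge_fraction=0.5,
            multiple_bond_fraction=0.5
            if simplification is Simplification.CIS_TRANS
            else 0.25,
            aromatic_fraction=1.0 if simplification is Simplification.AROMATICITY else 0.3,
            perturbation=simplification,
        )
        singleton = SimplificationSet(frozenset({simplification}))
        seen_nontrivial = False
        for original, perturbed in generate_perturbed_pairs(spec):
            report = compare_entity_sets(original, perturbed)
            if report.verdict is Verdict.IDENTICAL:
                continue  # the perturbation was invisible for this entity
            assert report.verdict is Verdict.SIMPLIFIED
            assert report.minimal == singleton
            seen_nontrivial = True
        assert seen_nontrivial, f"no visible {simplification.symbol} perturbation generated"


class TestFindDuplicates:
    def test_two_spellings_grouped(self):
        report = find_duplicates([("a", "CCO"), ("b", "OCC"), ("c", "CCC")])
        assert report.groups == [["a", "b"]]

    def test_identical_inputs_are_false_positives(self):
        report = find_duplicates([("a", "CCO"), ("b", "CCO"), ("c", "OCC")])
        assert report.false_positives == [["a", "b"]]
        assert report.groups == []

    def test_ring_eight_cis_trans_collapses(self):
        report = find_duplicates(
            [("with", "C/1=C\\CCCCCC1"), ("without", "C1=CCCCCCC1")]
        )
        assert report.groups == [["with", "without"]]

    def test_ring_nine_cis_trans_kept(self):
        report = find_duplicates(
            [("with", "C/1=C\\CCCCCCC1"), ("without", "C1=CCCCCCCC1")]
        )
        assert report.groups == []

    def test_diastereomers_not_duplicates(self):
        report = find_duplicates(
            [("r", "N[C@@H](C)C(=O)O"), ("s", "N[C@H](C)C(=O)O")]
        )
        assert report.groups == []

    def test_unparseable_records_skipped_with_count(self):
        report = find_duplicates([("ok", "CCO"), ("bad", "C1CC"), ("ok2", "OCC")])
        assert report.skipped == 1 and report.skipped_ids == ["bad"]
        assert report.groups == [["ok", "ok2"]]
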