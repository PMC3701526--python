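"""Signed circular gene orders: breakpoint distance vs an exhaustive oracle,
rotation/reflection invariances, and the planthopper rearrangement calls."""

import itertools

import numpy as np
import pytest

from mitocomp.gene_order import (GeneOrder, GeneOrderError, adjacency_set,
                                 breakpoint_distance, broken_adjacencies,
                                 canonical_rotation, diff_blocks,
                                 load_packaged_order, order_from_table,
                                 read_order_file, shared_derived_adjacencies,
                                 write_order_file)
from mitocomp.genome_io import Feature, FeatureTable
from tests_oracles import oracle_breakpoints


def _random_signed_order(rng, labels):
    perm = list(labels)
    rng.shuffle(perm)
    return GeneOrder(tuple((g, int(rng.choice([-1, 1]))) for g in perm))


class TestBreakpointDistance:
    def test_identical_orders(self):
        o = GeneOrder.from_strings(["cox1", "-trnQ", "nad2"])
        assert breakpoint_distance(o, o) == 0

    def test_matches_exhaustive_oracle_on_all_small_permutations(self):
        # every signed circular permutation of 4 labels vs a fixed reference
        labels = ["a", "b", "c", "d"]
        ref = GeneOrder(tuple((g, 1) for g in labels))
        for perm in itertools.permutations(labels):
            for signs in itertools.product([1, -1], repeat=4):
                o = GeneOrder(tuple(zip(perm, signs)))
                assert breakpoint_distance(o, ref) == oracle_breakpoints(o, ref)
                assert breakpoint_distance(ref, o) == oracle_breakpoints(ref, o)

    def test_matches_oracle_on_random_six_label_pairs(self):
        rng = np.random.default_rng(7)
        labels = list("abcdef")
        for _ in range(200):
            o1 = _random_signed_order(rng, labels)
            o2 = _random_signed_order(rng, labels)
            assert breakpoint_distance(o1, o2) == oracle_breakpoints(o1, o2)

    def test_symmetry_and_rotation_invariance(self):
        rng = np.random.default_rng(8)
        labels = list("abcdefgh")
        for _ in range(50):
            o1 = _random_signed_order(rng, labels)
            o2 = _random_signed_order(rng, labels)
            d = breakpoint_distance(o1, o2)
            assert breakpoint_distance(o2, o1) == d
            k = int(rng.integers(1, 8))
            rot = GeneOrder(o1.labels[k:] + o1.labels[:k])
            assert breakpoint_distance(rot, o2) == d

    def test_reflection_with_sign_flip_invariance(self):
        rng = np.random.default_rng(9)
        labels = list("abcdef")
        o1 = _random_signed_order(rng, labels)
        o2 = _random_signed_order(rng, labels)
        refl = GeneOrder(tuple((g, -s) for g, s in reversed(o1.labels)))
        assert breakpoint_distance(refl, o2) == breakpoint_distance(o1, o2)

    def test_unequal_label_sets_error(self):
        o1 = GeneOrder.from_strings(["cox1", "nad2"])
        o2 = GeneOrder.from_strings(["cox1", "nad3"])
        with pytest.raises(GeneOrderError, match="nad"):
            breakpoint_distance(o1, o2)


class TestPlanthopperOrders:
    def test_breakpoints_confined_to_the_two_rearranged_neighbourhoods(self):
        anc = load_packaged_order("ancestral_insect")
        delph = load_packaged_order("delphacid")
        hot = {"nad2", "trnW", "trnC", "trnY",        # trnC-trnW region
               "nad4L", "trnT", "trnP", "nad6", "cob"}  # nad6-trnP-trnT region
        broken = broken_adjacencies(delph, anc)
        assert broken, "the planthopper order must differ from the ancestral one"
        for x, y in broken:
            assert x[0] in hot and y[0] in hot

    def test_trnh_is_the_sole_displaced_gene_between_sbph_annotations(self):
        delph = load_packaged_order("delphacid")
        prior = load_packaged_order("sbph_prior")
        rep = diff_blocks(delph, prior)
        assert rep.displaced_genes == ("trnH",)

    def test_shared_derived_adjacencies_of_both_planthoppers(self):
        anc = load_packaged_order("ancestral_insect")
        delph = load_packaged_order("delphacid")
        prior = load_packaged_order("sbph_prior")
        derived = shared_derived_adjacencies([delph, prior], anc)
        genes = {g for adj in derived for g, _ in adj}
        assert "trnW" in genes
        assert {"nad6", "trnP", "trnT"} & genes


class TestDiffBlocks:
    def test_identical_orders_have_no_displaced_genes(self):
        o = load_packaged_order("delphacid")
        rep = diff_blocks(o, o)
        assert rep.breakpoint_count == 0 and rep.displaced_genes == ()
        assert rep.conserved_blocks == (o.labels,)

    def test_displaced_genes_flank_breakpoints(self):
        rng = np.random.default_rng(10)
        labels = list("abcdefgh")
        for _ in range(30):
            o1 = _random_signed_order(rng, labels)
            o2 = _random_signed_order(rng, labels)
            rep = diff_blocks(o1, o2)
            broken = broken_adjacencies(o1, o2)
            flanking = {g for adj in broken for g, _ in adj}
            assert set(rep.displaced_genes) <= flanking
            assert rep.breakpoint_count == breakpoint_distance(o1, o2)


class TestOrderFromTable:
    def _table(self, entries):
        feats = []
        pos = 1
        for name, ftype, strand, copy in entries:
            feats.append(Feature(name, ftype, pos, pos + 59,
                                 strand=strand, copy_index=copy))
            pos += 70
        return FeatureTable(genome_id="t", features=feats)

    def test_duplicated_trnc_collapses_to_flagged_single_entry(self):
        t = self._table([("cox1", "PCG", "J", 1),
                         ("trnC", "tRNA", "N", 1),
                         ("trnC", "tRNA", "N", 2),
                         ("trnC", "tRNA", "N", 3),
                         ("trnW", "tRNA", "J", 1)])
        o = order_from_table(t)
        assert o.to_strings() == ["cox1", "-trnC", "trnW"]
        assert o.duplicated == ("trnC",)

    def test_singleton(self):
        o = order_from_table(self._table([("cox1", "PCG", "J", 1)]))
        assert o.to_strings() == ["cox1"]

    def test_control_region_excluded_by_default(self):
        t = self._table([("cox1", "PCG", "J", 1), ("CR", "control_region", "J", 1)])
        assert order_from_table(t).to_strings() == ["cox1"]
        assert order_from_table(t, include_control_region=True).to_strings() == \
            ["cox1", "CR"]

    def test_rotated_table_gives_rotated_order(self, default_genome):
        from mitocomp.genome_io import rotate_table
        genome, table = default_genome
        o1 = order_from_table(table)
        g2, t2 = rotate_table(table, genome, 5000)
        o2 = order_from_table(t2)
        assert adjacency_set(o1) == adjacency_set(o2)
        assert canonical_rotation(o1).to_strings() == canonical_rotation(o2).to_strings()


class TestCanonicalRotation:
    def test_identity_when_anchor_first(self):
        o = GeneOrder.from_strings(["cox1", "nad2", "-trnQ"])
        assert canonical_rotation(o).labels == o.labels

    def test_double_rotation_is_identity(self):
        o = GeneOrder.from_strings(["nad2", "cox1", "-trnQ"])
        r = canonical_rotation(o, "cox1")
        assert canonical_rotation(r, "cox1").labels == r.labels

    def test_equals_bruteforce_rotation(self):
        o = GeneOrder.from_strings(["nad2", "-trnQ", "cox1", "trnW"])
        r = canonical_rotation(o, "cox1")
        expected = None
        for k in range(len(o.labels)):
            cand = o.labels[k:] + o.labels[:k]
            if cand[0][0] == "cox1":
                expected = cand
        assert r.labels == expected

    def test_missing_anchor_errors(self):
        with pytest.raises(GeneOrderError):
            canonical_rotation(GeneOrder.from_strings(["nad2"]), "cox1")


def test_order_file_round_trip(tmp_path):
    orders = {"x": GeneOrder.from_strings(["cox1", "-trnQ", "nad2"], source_id="x")}
    write_order_file(orders, tmp_path / "o.order")
    back = read_order_file(tmp_path / "o.order")
    assert back["x"].labels == orders["x"].labels


def test_synthetic_genome_realises_packaged_order(default_genome):
    genome, table = default_genome
    o = order_from_table(table)
    ref = load_packaged_order("delphacid")
    assert breakpoint_distance(o, ref) == 0
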