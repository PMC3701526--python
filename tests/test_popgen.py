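"""Population analyses: planted-parameter recovery, pairwise oracles,
minimum-spanning-network properties and indel/divergence accounting."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mitocomp.popgen import (AlignedSet, FragmentMap, PopgenError, Segment,
                             build_network, call_variable_sites,
                             classify_mutation, collapse_haplotypes,
                             indel_report, nucleotide_diversity,
                             pairwise_gene_divergence)
from mitocomp.synthetic import (GenomeSpec, IndelSpec, default_survey_spec,
                                make_mitogenome, make_population, mutate_genome)


class TestCallVariableSites:
    def test_identical_sequences_have_none(self):
        a = AlignedSet(ids=["a", "b"], seqs=["ACGT", "ACGT"])
        assert call_variable_sites(a) == []

    def test_planted_sites_recovered_exactly(self, survey_spec, survey_population):
        planted = sorted({p for h in survey_spec.haplotypes for p, _ in h.mutations})
        got = [v.position for v in call_variable_sites(survey_population)]
        assert got == planted
        assert len(got) == 16

    def test_matches_column_scan_oracle(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGTN"), 80, p=[0.3, 0.3, 0.15, 0.15, 0.1]))
                for _ in range(12)]
        a = AlignedSet(ids=[f"s{i}" for i in range(12)], seqs=seqs)
        want = []
        for j in range(80):
            col = {s[j] for s in seqs} - {"N", "-"}
            if len(col) >= 2:
                want.append(j + 1)
        assert [v.position for v in call_variable_sites(a)] == want

    def test_length_mismatch_errors(self):
        with pytest.raises(PopgenError):
            AlignedSet(ids=["a", "b"], seqs=["ACGT", "ACG"])


class TestCollapseHaplotypes:
    def test_all_identical_collapse_to_one(self):
        a = AlignedSet(ids=list("abc"), seqs=["ACGT"] * 3)
        t = collapse_haplotypes(a)
        assert len(t.haplotypes) == 1 and t.haplotypes[0].count == 3

    def test_planted_survey_frequencies_recovered(self, survey_population):
        # 309 individuals in 16 haplotypes led by 178/93/18
        t = collapse_haplotypes(survey_population)
        counts = [h.count for h in t.haplotypes]
        assert counts[:3] == [178, 93, 18]
        assert len(counts) == 16
        assert counts[3:] == [2] * 7 + [1] * 6

    def test_counts_conserve_sample_size(self, survey_population):
        t = collapse_haplotypes(survey_population)
        assert sum(h.count for h in t.haplotypes) == len(survey_population) == 309

    def test_numbering_descending_with_first_occurrence_ties(self):
        a = AlignedSet(ids=list("abcd"), seqs=["AAAA", "AAAT", "AAAT", "TAAA"])
        t = collapse_haplotypes(a)
        assert t.haplotypes[0].members == ("b", "c")
        # tie between the two singletons: first occurrence wins
        assert t.haplotypes[1].members == ("a",)
        assert t.haplotypes[2].members == ("d",)


class TestClassifyMutation:
    def test_published_nonsynonymous_codon_mapping(self, survey_spec):
        # positions 277 and 391 fall in codons 93 and 131 of the nad5 frame
        m1 = classify_mutation(277, survey_spec.reference, "T", survey_spec.fmap)
        assert (m1.codon_number, m1.codon_position) == (93, 1)
        assert m1.aa_change == "M93L"
        m2 = classify_mutation(391, survey_spec.reference, "A", survey_spec.fmap)
        assert (m2.codon_number, m2.codon_position) == (131, 1)
        assert m2.aa_change == "D131N"

    def test_fourfold_third_position_is_synonymous(self, survey_spec):
        # codon 15 was planted as GGA (Gly); position 45 is its third base
        m = classify_mutation(45, survey_spec.reference, "G", survey_spec.fmap)
        assert m.synonymous is True and m.aa_change is None

    def test_frame_consistency_between_neighbouring_codons(self, survey_spec):
        ref = survey_spec.reference

        def codon_at(pos):
            alt = "A" if ref[pos - 1] != "A" else "C"
            return classify_mutation(pos, ref, alt, survey_spec.fmap).codon_number
        for p in (10, 100, 300):
            assert codon_at(p + 3) == codon_at(p) + 1

    def test_noncoding_segments_labelled(self, survey_spec):
        ref = survey_spec.reference
        alt = "A" if ref[544] != "A" else "C"
        m = classify_mutation(545, ref, alt, survey_spec.fmap)
        assert m.kind == "noncoding" and m.segment == "intergenic"
        m2 = classify_mutation(500, ref, "A" if ref[499] != "A" else "C",
                               survey_spec.fmap)
        assert m2.segment == "trnH"

    def test_outside_fragment_errors(self, survey_spec):
        with pytest.raises(PopgenError):
            classify_mutation(643, survey_spec.reference, "A", survey_spec.fmap)


class TestBuildNetwork:
    def test_single_haplotype(self):
        a = AlignedSet(ids=["a"], seqs=["ACGT"])
        net = build_network(collapse_haplotypes(a))
        assert len(net.nodes) == 1 and net.edges == ()

    def test_star_topology_from_star_data(self):
        # one central haplotype plus k single-step neighbours at distinct sites
        center = "A" * 10
        seqs = [center] * 5
        for i in range(4):
            s = list(center)
            s[i] = "T"
            seqs.append("".join(s))
        a = AlignedSet(ids=[f"s{i}" for i in range(len(seqs))], seqs=seqs)
        net = build_network(collapse_haplotypes(a))
        assert len(net.edges) == 4
        assert all("Haplo1" in (e.h1, e.h2) for e in net.edges)
        assert all(e.weight == 1 for e in net.edges)

    def test_edge_labels_equal_hamming_distance(self, survey_population):
        t = collapse_haplotypes(survey_population)
        net = build_network(t)
        sig = {h.name: h.signature for h in t.haplotypes}
        for e in net.edges:
            d = sum(x != y for x, y in zip(sig[e.h1], sig[e.h2]))
            assert e.weight == len(e.positions) == d

    def test_network_spans_and_matches_networkx_mst_weight(self):
        rng = np.random.default_rng(3)
        seqs = list({"".join(rng.choice(list("AT"), 12)) for _ in range(10)})
        a = AlignedSet(ids=[f"s{i}" for i in range(len(seqs))], seqs=seqs)
        t = collapse_haplotypes(a)
        net = build_network(t)
        g = nx.Graph()
        for h1, h2 in itertools.combinations(t.haplotypes, 2):
            w = sum(x != y for x, y in zip(h1.signature, h2.signature))
            g.add_edge(h1.name, h2.name, weight=w)
        mst_w = sum(d["weight"] for _, _, d in
                    nx.minimum_spanning_tree(g).edges(data=True))
        sub = nx.Graph()
        sub.add_nodes_from(h.name for h in t.haplotypes)
        for e in net.edges:
            sub.add_edge(e.h1, e.h2, weight=e.weight)
        assert nx.is_connected(sub)
        sub_mst_w = sum(d["weight"] for _, _, d in
                        nx.minimum_spanning_tree(sub).edges(data=True))
        assert sub_mst_w == mst_w
        # every retained edge belongs to at least one minimum spanning tree
        for e in net.edges:
            below = nx.Graph()
            below.add_nodes_from(g.nodes)
            below.add_edges_from((u, v) for u, v, d in g.edges(data=True)
                                 if d["weight"] < e.weight)
            assert not nx.has_path(below, e.h1, e.h2) or \
                nx.node_connected_component(below, e.h1) != \
                nx.node_connected_component(below, e.h2)


class TestNucleotideDiversity:
    def test_identical_set_is_zero(self):
        a = AlignedSet(ids=list("ab"), seqs=["ACGT" * 5] * 2)
        assert nucleotide_diversity(a) == 0

    def test_two_sequences_one_difference(self):
        s = "A" * 100
        a = AlignedSet(ids=list("ab"), seqs=[s, "T" + s[1:]])
        assert nucleotide_diversity(a) == pytest.approx(0.01)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGTN"), 50, p=[0.3, 0.3, 0.15, 0.15, 0.1]))
                for _ in range(8)]
        a = AlignedSet(ids=[f"s{i}" for i in range(8)], seqs=seqs)
        dsum, n = 0.0, 0
        for s1, s2 in itertools.combinations(seqs, 2):
            ok = [(x, y) for x, y in zip(s1, s2) if "N" not in (x, y)]
            dsum += sum(x != y for x, y in ok) / len(ok)
            n += 1
        assert nucleotide_diversity(a) == pytest.approx(dsum / n)

    def test_survey_diversity_is_small(self, survey_population):
        # sparse planted variation across 309 individuals: pi well below 0.01
        assert 0 < nucleotide_diversity(survey_population) < 0.01


class TestPairwiseGeneDivergence:
    def test_genome_vs_itself_all_zero(self, default_genome):
        genome, table = default_genome
        rep = pairwise_gene_divergence(genome, table, genome, table)
        assert all(g.substitutions == 0 for g in rep.per_gene)
        assert rep.excluded == ()

    def test_planted_substitution_counts_recovered(self, default_genome):
        genome, table = default_genome
        subs = {"rrnS": 6, "rrnL": 2, "cox1": 4, "nad3": 1}
        pair = mutate_genome(genome, table, subs, seed=5)
        rep = pairwise_gene_divergence(genome, table, pair.genome, pair.table)
        for gene, n in subs.items():
            g = next(x for x in rep.per_gene if x.gene == gene)
            assert g.substitutions == n

    def test_rrna_rate_magnitudes(self, default_genome):
        # 6 substitutions in the 747-bp small rRNA: rate about 0.8%;
        # 2 in the 1219-bp large rRNA: about 0.16%
        genome, table = default_genome
        pair = mutate_genome(genome, table, {"rrnS": 6, "rrnL": 2}, seed=6)
        rep = pairwise_gene_divergence(genome, table, pair.genome, pair.table)
        assert rep.rate_of("rrnS") == pytest.approx(6 / 747)
        assert rep.rate_of("rrnS") == pytest.approx(0.008, rel=0.01)
        assert rep.rate_of("rrnL") == pytest.approx(2 / 1219)

    def test_length_variant_genes_excluded_with_reason(self, default_genome):
        genome, table = default_genome
        indels = [IndelSpec("nad5", "deletion", 57, "start"),
                  IndelSpec("atp8", "deletion", 60, "end")]
        pair = mutate_genome(genome, table, indels=indels, seed=7)
        rep = pairwise_gene_divergence(genome, table, pair.genome, pair.table)
        excluded = dict(rep.excluded)
        assert set(excluded) == {"nad5", "atp8"}
        assert "length differs" in excluded["nad5"]

    def test_no_shared_genes_errors(self, default_genome):
        genome, table = default_genome
        from mitocomp.genome_io import FeatureTable
        with pytest.raises(PopgenError):
            pairwise_gene_divergence(genome, table, genome,
                                     FeatureTable(genome_id="x", features=[]))


class TestIndelReport:
    def test_no_gaps(self):
        assert indel_report("ACGT", "ACGT") == []

    def test_planted_indel_lengths_recovered(self, default_genome):
        # the published two-individual comparison: deletions of 57/21/55/21/60 bp
        # and one 84-bp insertion across five genes
        genome, table = default_genome
        indels = [IndelSpec("nad5", "deletion", 57, "start"),
                  IndelSpec("nad4", "deletion", 21, "end"),
                  IndelSpec("nad6", "insertion", 84, "start"),
                  IndelSpec("nad6", "deletion", 55, "end"),
                  IndelSpec("nad2", "deletion", 21, "end"),
                  IndelSpec("atp8", "deletion", 60, "end")]
        pair = mutate_genome(genome, table, indels=indels, seed=8)
        events = indel_report(pair.aligned_a, pair.aligned_b)
        assert sorted((e.kind, e.length) for e in events) == sorted([
            ("deletion", 57), ("deletion", 21), ("insertion", 84),
            ("deletion", 55), ("deletion", 21), ("deletion", 60)])

    def test_event_lengths_sum_to_gap_count(self, default_genome):
        genome, table = default_genome
        indels = [IndelSpec("nad5", "deletion", 10, "start"),
                  IndelSpec("cox1", "insertion", 7, "end")]
        pair = mutate_genome(genome, table, indels=indels, seed=9)
        events = indel_report(pair.aligned_a, pair.aligned_b)
        total = sum(e.length for e in events)
        assert total == pair.aligned_a.count("-") + pair.aligned_b.count("-")

    def test_length_mismatch_errors(self):
        with pytest.raises(PopgenError):
            indel_report("ACGT", "ACG")


class TestFragmentMap:
    def test_segments_must_be_contiguous(self):
        with pytest.raises(PopgenError):
            FragmentMap(segments=(Segment("a", 1, 10), Segment("b", 12, 20)))

    def test_segment_lookup(self):
        fm = FragmentMap(segments=(Segment("a", 1, 10), Segment("b", 11, 20)))
        assert fm.segment_at(10).name == "a" and fm.segment_at(11).name == "b"
        assert fm.length == 20
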