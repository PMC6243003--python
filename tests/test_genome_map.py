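"""Cluster, tandem and segmental duplication calling."""

from familyscope.genome_map import (
    GenomicLocus,
    clusters_to_bed,
    find_clusters,
    find_segmental,
    find_tandem,
)


def loc(gene, seq, start, end=None):
    return GenomicLocus(gene, seq, start, end if end is not None else start + 2000)


class TestClusters:
    def test_two_genes_150kb_apart_cluster(self):
        assert find_clusters([loc("a", "chr1", 0), loc("b", "chr1", 150_000)]) == [["a", "b"]]

    def test_two_genes_250kb_apart_do_not(self):
        assert find_clusters([loc("a", "chr1", 0), loc("b", "chr1", 250_000)]) == []

    def test_chaining_at_180kb_gaps(self):
        loci = [loc("a", "chr1", 0), loc("b", "chr1", 180_000), loc("c", "chr1", 360_000)]
        assert find_clusters(loci) == [["a", "b", "c"]]

    def test_chaining_agrees_with_brute_force_window_rule(self):
        # Oracle: a maximal set of genes is a cluster iff sorted consecutive
        # start gaps all fit the window; enumerate all windows of positions.
        positions = [0, 50_000, 260_000, 300_000, 390_000, 700_000]
        loci = [loc(f"g{i}", "chr1", p) for i, p in enumerate(positions)]
        expected = []
        i = 0
        while i < len(positions):
            j = i
            while j + 1 < len(positions) and positions[j + 1] - positions[j] <= 200_000:
                j += 1
            if j > i:
                expected.append([f"g{k}" for k in range(i, j + 1)])
            i = j + 1
        assert find_clusters(loci) == expected

    def test_different_chromosomes_never_cluster(self):
        assert find_clusters([loc("a", "chr1", 0), loc("b", "chr2", 1000)]) == []

    def test_translation_invariance(self):
        loci = [loc("a", "chr1", 10_000), loc("b", "chr1", 120_000), loc("c", "chr1", 500_000)]
        shifted = [loc(l.gene_id, l.seq_id, l.start + 7_777_777, l.end + 7_777_777) for l in loci]
        assert find_clusters(loci) == find_clusters(shifted)

    def test_bed_output(self):
        loci = {"a": loc("a", "chr1", 100), "b": loc("b", "chr1", 5000)}
        bed = clusters_to_bed([["a", "b"]], loci)
        assert bed == "chr1\t100\t7000\tcluster_1\n"


class TestTandem:
    def test_adjacent_pair_zero_spacers(self):
        wrky = [loc("a", "chr1", 0), loc("b", "chr1", 40_000)]
        (p,) = find_tandem(wrky, wrky)
        assert (p.gene_a, p.gene_b, p.distance, p.n_spacer_genes) == ("a", "b", 40_000, 0)

    def test_three_spacers_within_window_still_tandem(self):
        wrky = [loc("a", "chr1", 0), loc("b", "chr1", 90_000)]
        spacers = [loc(f"s{i}", "chr1", 10_000 + 20_000 * i) for i in range(3)]
        (p,) = find_tandem(wrky, wrky + spacers)
        assert p.n_spacer_genes == 3

    def test_four_spacers_disqualify(self):
        wrky = [loc("a", "chr1", 0), loc("b", "chr1", 90_000)]
        spacers = [loc(f"s{i}", "chr1", 10_000 + 15_000 * i) for i in range(4)]
        assert find_tandem(wrky, wrky + spacers) == []

    def test_120kb_apart_is_not_tandem(self):
        wrky = [loc("a", "chr1", 0), loc("b", "chr1", 120_000)]
        assert find_tandem(wrky, wrky) == []

    def test_window_boundary_inclusive(self):
        wrky = [loc("a", "chr1", 0), loc("b", "chr1", 100_000)]
        assert len(find_tandem(wrky, wrky)) == 1

    def test_off_by_one_window_perturbations_flip_the_call(self):
        # A pair exactly 100 kb apart is tandem at the default window but
        # not at 99 kb; a 101 kb window additionally admits a 101 kb pair.
        pair_100 = [loc("a", "chr1", 0), loc("b", "chr1", 100_000)]
        pair_101 = [loc("c", "chr2", 0), loc("d", "chr2", 101_000)]
        wrky = pair_100 + pair_101
        at_default = {(p.gene_a, p.gene_b) for p in find_tandem(wrky, wrky)}
        at_99 = {(p.gene_a, p.gene_b) for p in find_tandem(wrky, wrky, tandem_window=99_000)}
        at_101 = {(p.gene_a, p.gene_b) for p in find_tandem(wrky, wrky, tandem_window=101_000)}
        assert at_default == {("a", "b")}
        assert at_99 == set()
        assert at_101 == {("a", "b"), ("c", "d")}

    def test_partially_overlapping_gene_not_a_spacer(self):
        wrky = [loc("a", "chr1", 0, 5000), loc("b", "chr1", 50_000, 55_000)]
        overlapping = loc("s", "chr1", 4000, 10_000)  # overlaps gene a
        (p,) = find_tandem(wrky, wrky + [overlapping])
        assert p.n_spacer_genes == 0


class TestSegmental:
    def test_identical_pair_on_different_chromosomes(self):
        seqs = {"a": "MKWVRAAA" * 10, "b": "MKWVRAAA" * 10}
        loci = {"a": loc("a", "chr2", 0), "b": loc("b", "chr3", 0)}
        (p,) = find_segmental(seqs, loci)
        assert p.identity == 100.0 and p.coverage == 100.0

    def test_half_identical_pair_excluded(self):
        seqs = {"a": "MKWVR" * 12, "b": "MDEFG" * 12}
        loci = {"a": loc("a", "chr2", 0), "b": loc("b", "chr3", 0)}
        assert find_segmental(seqs, loci) == []

    def test_nearby_same_chromosome_pair_not_segmental(self):
        seqs = {"a": "MKWVRAAA" * 10, "b": "MKWVRAAA" * 10}
        loci = {"a": loc("a", "chr2", 0), "b": loc("b", "chr2", 50_000)}
        assert find_segmental(seqs, loci) == []

    def test_planted_block_duplication_recovered(self, bundle_small, result_small):
        got = sorted((p.gene_a, p.gene_b) for p in result_small.duplication.segmental_pairs)
        assert got == sorted(bundle_small.spec.segmental_pairs)


class TestAgainstPlantedTruth:
    def test_clusters_and_tandem_recovered_exactly(self, bundle_small, result_small):
        rep = result_small.duplication
        assert rep.clusters == bundle_small.spec.clusters
        got = [(p.gene_a, p.gene_b, p.distance, p.n_spacer_genes) for p in rep.tandem_pairs]
        assert got == bundle_small.spec.tandem_pairs

    def test_every_tandem_pair_lies_in_some_cluster(self, result_small):
        rep = result_small.duplication
        members = [set(c) for c in rep.clusters]
        for p in rep.tandem_pairs:
            assert any({p.gene_a, p.gene_b} <= c for c in members)
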