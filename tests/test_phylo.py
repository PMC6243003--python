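"""Alignment, p-distances, neighbor joining and bootstrap."""

import io
import itertools

import dendropy
import numpy as np
import pytest
from Bio import Align
from dendropy.calculate import treecompare

from familyscope import phylo


def brute_force_best_score(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Enumerate all global alignments recursively (tiny inputs only)."""

    best = -np.inf

    def rec(i, j, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s)
        if i < len(a):
            rec(i + 1, j, score + gap)
        if j < len(b):
            rec(i, j + 1, score + gap)

    rec(0, 0, 0.0)
    return best


def random_additive_matrix(rng, n):
    """A distance matrix realized by a random tree with positive branches."""
    import collections
    import heapq

    adj = collections.defaultdict(dict)
    core = "I0"
    for leaf in ("L0", "L1", "L2"):
        adj[core][leaf] = adj[leaf][core] = float(round(rng.uniform(0.1, 2.0), 3))
    internal = 1
    for k in range(3, n):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid = f"I{internal}"
        internal += 1
        del adj[u][v], adj[v][u]
        x = float(rng.uniform(0.05, max(w - 0.05, 0.06)))
        x = min(x, w - 0.01)
        adj[u][mid] = adj[mid][u] = x
        adj[v][mid] = adj[mid][v] = w - x
        leaf = f"L{k}"
        adj[mid][leaf] = adj[leaf][mid] = float(round(rng.uniform(0.1, 2.0), 3))
    leaves = [f"L{i}" for i in range(n)]
    D = np.zeros((n, n))
    for i, a in enumerate(leaves):
        dist = {a: 0.0}
        pq = [(0.0, a)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist.get(u, np.inf):
                continue
            for v, w in adj[u].items():
                if d + w < dist.get(v, np.inf):
                    dist[v] = d + w
                    heapq.heappush(pq, (d + w, v))
        for j, b in enumerate(leaves):
            D[i, j] = dist[b]
    return leaves, D


class TestPairwiseAlign:
    def test_identical_sequences_align_gap_free(self):
        aln, score = phylo.pairwise_align("MKWVR", "MKWVR")
        assert aln.rows == ["MKWVR", "MKWVR"]
        assert score == 5.0
        assert phylo.identity_and_coverage(aln) == (100.0, 100.0)

    def test_acd_vs_ad_single_gap(self):
        aln, score = phylo.pairwise_align("ACD", "AD", match=1, mismatch=-1, gap=-1)
        assert score == 1.0
        assert sum(r.count("-") for r in aln.rows) == 1

    def test_score_symmetry(self):
        for a, b in [("MKV", "MV"), ("ACDEF", "AF"), ("WW", "WWWW")]:
            _, s1 = phylo.pairwise_align(a, b)
            _, s2 = phylo.pairwise_align(b, a)
            assert s1 == s2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            phylo.pairwise_align("", "A")

    @pytest.mark.parametrize("seed", range(10))
    def test_optimality_against_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        letters = list("ACDE")
        a = "".join(rng.choice(letters, size=rng.integers(1, 5)))
        b = "".join(rng.choice(letters, size=rng.integers(1, 5)))
        _, score = phylo.pairwise_align(a, b)
        assert score == brute_force_best_score(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_score_agrees_with_biopython_aligner(self, seed):
        rng = np.random.default_rng(100 + seed)
        letters = list("ACDEFGHIKL")
        a = "".join(rng.choice(letters, size=rng.integers(3, 30)))
        b = "".join(rng.choice(letters, size=rng.integers(3, 30)))
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )
        _, score = phylo.pairwise_align(a, b)
        assert score == aligner.score(a, b)
        assert phylo.alignment_score(a, b) == score

    def test_degapping_recovers_inputs(self):
        aln, _ = phylo.pairwise_align("MKVWRKY", "MVWRY")
        assert aln.degapped(0) == "MKVWRKY"
        assert aln.degapped(1) == "MVWRY"


class TestProgressiveAlign:
    def test_identical_inputs_gap_free(self):
        aln = phylo.progressive_align(["MKWVR"] * 4)
        assert all(r == "MKWVR" for r in aln.rows)

    def test_single_substitution_family(self):
        seqs = ["MKWVRAAA", "MKWVRAAA", "MKWVDAAA"]
        aln = phylo.progressive_align(seqs)
        diff_cols = [
            i for i in range(aln.n_sites)
            if len({r[i] for r in aln.rows}) > 1
        ]
        assert diff_cols == [4]

    def test_degapping_invariant_on_random_inputs(self):
        rng = np.random.default_rng(5)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = [
            "".join(rng.choice(letters, size=rng.integers(5, 25)))
            for _ in range(6)
        ]
        aln = phylo.progressive_align(seqs)
        for i, s in enumerate(seqs):
            assert aln.degapped(i) == s

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            phylo.progressive_align(["MKV"])


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = phylo.Alignment(["a", "b"], ["MKV", "MKV"])
        assert phylo.p_distance(aln).matrix[0, 1] == 0.0

    def test_all_sites_differ(self):
        aln = phylo.Alignment(["a", "b"], ["AAA", "CCC"])
        assert phylo.p_distance(aln).matrix[0, 1] == 1.0

    def test_one_of_three_comparable_sites(self):
        aln = phylo.Alignment(["a", "b"], ["AAC", "AAG"])
        assert phylo.p_distance(aln).matrix[0, 1] == pytest.approx(1 / 3)

    def test_gap_columns_excluded(self):
        aln = phylo.Alignment(["a", "b"], ["A-C", "AGC"])
        assert phylo.p_distance(aln).matrix[0, 1] == 0.0

    def test_no_comparable_sites_raises(self):
        aln = phylo.Alignment(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError, match="comparable"):
            phylo.p_distance(aln)


class TestNeighborJoining:
    def test_four_taxon_additive_tree_recovered_exactly(self):
        # Tree ((A:1,B:2):1,(C:3,D:1)): path lengths are additive.
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
        got = tree.leaf_distances()
        for i, j in itertools.combinations(range(4), 2):
            key = tuple(sorted((ids[i], ids[j])))
            assert got[key] == pytest.approx(D[i, j], abs=1e-9)
        assert frozenset({"A", "B"}) in tree.bipartitions() or frozenset({"C", "D"}) in tree.bipartitions()

    def test_three_taxon_closed_form(self):
        ids = ["A", "B", "C"]
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids, D))
        got = tree.leaf_distances()
        assert got[("A", "B")] == pytest.approx(2.0)
        assert got[("A", "C")] == pytest.approx(4.0)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(
                phylo.DistanceMatrix(["a", "b"], np.zeros((2, 2)))
            )

    def test_label_permutation_gives_same_unrooted_tree(self):
        leaves, D = random_additive_matrix(np.random.default_rng(4), 6)
        tree1 = phylo.neighbor_joining(phylo.DistanceMatrix(leaves, D))
        perm = [3, 0, 5, 1, 4, 2]
        ids2 = [leaves[p] for p in perm]
        D2 = D[np.ix_(perm, perm)]
        tree2 = phylo.neighbor_joining(phylo.DistanceMatrix(ids2, D2))
        assert tree1.bipartitions() == tree2.bipartitions()
        d1, d2 = tree1.leaf_distances(), tree2.leaf_distances()
        for key in d1:
            assert d1[key] == pytest.approx(d2[key], abs=1e-9)

    @pytest.mark.parametrize("trial", range(50))
    def test_additive_six_taxon_matrices_recovered_to_1e9(self, trial):
        leaves, D = random_additive_matrix(np.random.default_rng(trial), 6)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(leaves, D))
        got = tree.leaf_distances()
        for i, j in itertools.combinations(range(6), 2):
            key = tuple(sorted((leaves[i], leaves[j])))
            assert abs(got[key] - D[i, j]) < 1e-9

    def test_topology_agrees_with_dendropy_nj(self):
        leaves, D = random_additive_matrix(np.random.default_rng(77), 7)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(leaves, D))
        csv = "," + ",".join(leaves) + "\n" + "\n".join(
            leaves[i] + "," + ",".join(str(D[i, j]) for j in range(len(leaves)))
            for i in range(len(leaves))
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=","
        )
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(
            data=tree.newick(), schema="newick", taxon_namespace=tns
        )
        t2 = dendropy.Tree.get(
            data=pdm.nj_tree().as_string(schema="newick"),
            schema="newick",
            taxon_namespace=tns,
        )
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert treecompare.symmetric_difference(t1, t2) == 0

    def test_degenerate_matrix_flagged(self):
        tree = phylo.neighbor_joining(
            phylo.DistanceMatrix(list("ABCD"), np.zeros((4, 4)))
        )
        assert tree.degenerate


class TestBootstrap:
    def _signal_alignment(self):
        rows = [
            "AAAACCCCGGGG",
            "AAAACCCCGGGA",
            "TTTTCCCCGGGG",
            "TTTTCCCCGGGA",
        ]
        return phylo.Alignment(list("abcd"), rows)

    def test_supports_within_range_and_deterministic(self):
        aln = self._signal_alignment()
        t1 = phylo.bootstrap(aln, n_replicates=200, seed=9)
        t2 = phylo.bootstrap(aln, n_replicates=200, seed=9)
        assert t1.newick() == t2.newick()
        supports = [
            n.support
            for n in _walk(t1.root)
            if n.support is not None
        ]
        assert supports and all(0 <= s <= 100 for s in supports)

    def test_strong_clade_gets_high_support(self):
        aln = self._signal_alignment()
        tree = phylo.bootstrap(aln, n_replicates=200, seed=3)
        # (a,b) vs (c,d) is supported by four invariant columns.
        supports = [n.support for n in _walk(tree.root) if n.support is not None]
        assert max(supports) >= 90

    def test_more_signal_never_lowers_support(self):
        weak_rows = ["AACC", "AACA", "TTCC", "TTCA"]
        strong_rows = [r + r[:2] * 3 for r in weak_rows]  # more split columns
        weak = phylo.Alignment(list("abcd"), weak_rows)
        strong = phylo.Alignment(list("abcd"), strong_rows)
        med_weak = np.median(
            [max(_supports(phylo.bootstrap(weak, 100, seed=s))) for s in range(5)]
        )
        med_strong = np.median(
            [max(_supports(phylo.bootstrap(strong, 100, seed=s))) for s in range(5)]
        )
        assert med_strong >= med_weak

    def test_fewer_than_four_rows_rejected(self):
        aln = phylo.Alignment(list("abc"), ["AA", "AC", "CC"])
        with pytest.raises(ValueError):
            phylo.bootstrap(aln, 10, seed=0)


class TestNearestReference:
    def test_query_equal_to_a_reference(self):
        refs = [("r1", "IIa", "MKWVR"), ("r2", "IIb", "MDEFG")]
        label, margin = phylo.nearest_reference("MKWVR", refs)
        assert label == "IIa" and margin >= 0

    def test_single_reference_returns_its_label(self):
        label, margin = phylo.nearest_reference("MKV", [("r", "IId", "MKWWW")])
        assert label == "IId" and margin == np.inf

    def test_tie_broken_lexicographically_with_zero_margin(self):
        refs = [("r_b", "IIe", "MKWVR"), ("r_a", "IId", "MKWVR")]
        label, margin = phylo.nearest_reference("MKWVR", refs)
        assert label == "IId" and margin == 0.0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            phylo.nearest_reference("MKV", [])


def _walk(node):
    yield node
    for child, _ in node.children:
        yield from _walk(child)


def _supports(tree):
    return [n.support for n in _walk(tree.root) if n.support is not None] or [0.0]
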