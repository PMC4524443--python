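"""Guide trees, pairwise/progressive alignment, conserved blocks."""

import random

import numpy as np
import pytest

from homeolocus.homology import DEFAULT_SCHEME
from homeolocus.msa import (
    BlockFilterParams,
    Msa,
    TreeNode,
    build_guide_tree,
    kmer_distance_matrix,
    pairwise_align_global,
    progressive_align,
    select_conserved_blocks,
)
from homeolocus.seqio import AlignedSet, SeqRecord


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestKmerDistance:
    def test_identical_zero(self):
        recs = [SeqRecord("a", "ACGTACGTAC"), SeqRecord("b", "ACGTACGTAC")]
        d = kmer_distance_matrix(recs)
        assert d[0, 1] == 0.0

    def test_disjoint_one(self):
        recs = [SeqRecord("a", "A" * 20), SeqRecord("b", "C" * 20)]
        assert kmer_distance_matrix(recs)[0, 1] == 1.0

    def test_recovers_true_grouping(self):
        rng = random.Random(3)
        base = _random_seq(rng, 400)

        def diverge(seq, rate):
            out = list(seq)
            for i in range(len(out)):
                if rng.random() < rate:
                    out[i] = rng.choice("ACGT".replace(out[i], ""))
            return "".join(out)

        recs = [
            SeqRecord("close1", diverge(base, 0.01)),
            SeqRecord("close2", diverge(base, 0.01)),
            SeqRecord("far", diverge(base, 0.10)),
        ]
        d = kmer_distance_matrix(recs)
        assert d[0, 1] < d[0, 2] and d[0, 1] < d[1, 2]

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            kmer_distance_matrix([SeqRecord("a", "ACG"), SeqRecord("b", "ACGTACGT")])


def _upgma_oracle(dist):
    """Independent naive UPGMA: clusters as frozensets of leaf indices."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    shape = {i: i for i in range(n)}
    nid = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        pairs = [(d[(min(a, b), max(a, b))], a, b)
                 for ia, a in enumerate(keys) for b in keys[ia + 1:]]
        _, a, b = min(pairs)
        shape[nid] = frozenset({shape[a], shape[b]})
        clusters[nid] = clusters[a] | clusters[b]
        sizes[nid] = sizes[a] + sizes[b]
        for m in keys:
            if m in (a, b):
                continue
            dm = (sizes[a] * d[(min(a, m), max(a, m))]
                  + sizes[b] * d[(min(b, m), max(b, m))]) / (sizes[a] + sizes[b])
            d[(min(m, nid), max(m, nid))] = dm
        del clusters[a], clusters[b]
        nid += 1
    return shape[nid - 1]


def _tree_shape(node: TreeNode):
    if node.leaf is not None:
        return node.leaf
    return frozenset(_tree_shape(c) for c in node.children)


class TestGuideTree:
    def test_two_leaves(self):
        tree = build_guide_tree(np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert sorted(tree.leaves()) == [0, 1]
        assert tree.height == pytest.approx(0.2)

    def test_forced_topology(self):
        d = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [0.4, 0.4, 0.0]])
        tree = build_guide_tree(d)
        assert _tree_shape(tree) == frozenset({frozenset({0, 1}), 2})

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_naive_upgma(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = 6
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        assert _tree_shape(build_guide_tree(d)) == _upgma_oracle(d)

    def test_invalid_matrix(self):
        with pytest.raises(ValueError, match="invalid distance matrix"):
            build_guide_tree(np.array([[0.0, 1.0], [0.5, 0.0]]))


def _enumerate_global(a, b, match=2, mismatch=-3, go=5, ge=2):
    """Brute-force global alignment score: enumerate every op path with
    run-aware affine gap costs (gap of length L costs go + ge*L)."""
    best = [-float("inf")]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            rec(i + 1, j, "D", score - (ge if prev == "D" else go + ge))
        if j < len(b):
            rec(i, j + 1, "I", score - (ge if prev == "I" else go + ge))

    rec(0, 0, None, 0)
    return best[0]


class TestPairwiseGlobal:
    def test_identity(self):
        ra, rb, score = pairwise_align_global("ACGTACGT", "ACGTACGT")
        assert ra == rb == "ACGTACGT"
        assert score == 2 * 8

    def test_single_gap_example(self):
        ra, rb, score = pairwise_align_global("ACGT", "AGT")
        assert rb.count("-") == 1 and ra.count("-") == 0
        assert score == _enumerate_global("ACGT", "AGT")

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = random.Random(200 + trial)
        a = _random_seq(rng, rng.randrange(1, 9))
        b = _random_seq(rng, rng.randrange(1, 9))
        _, _, score = pairwise_align_global(a, b)
        assert score == _enumerate_global(a, b)

    def test_affine_prefers_single_gap_run(self):
        rng = random.Random(7)
        base = _random_seq(rng, 60)
        with_ins = base[:30] + "TTT" + base[30:]
        ra, rb, _ = pairwise_align_global(base, with_ins)
        assert ra.count("-") == 3
        gap_start = ra.index("-")
        assert ra[gap_start:gap_start + 3] == "---"
        assert ra.replace("-", "") == base

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align_global("", "ACGT")


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        recs = [SeqRecord(f"s{i}", "ACGTACGTACGT") for i in range(3)]
        msa = progressive_align(recs)
        assert all("-" not in rseq for _, rseq in msa.aln.rows)

    def test_planted_deletion_shows_as_gap_run(self):
        rng = random.Random(31)
        base = _random_seq(rng, 300)
        records = [
            SeqRecord("a", base),
            SeqRecord("b", base),
            SeqRecord("c", base[:100] + base[105:]),  # 5 bp deletion
        ]
        msa = progressive_align(records)
        rows = dict(msa.aln.rows)
        assert rows["c"].count("-") == 5
        assert "-----" in rows["c"]
        assert rows["a"].count("-") == 0

    def test_two_sequences_equal_pairwise(self):
        rng = random.Random(32)
        a, b = _random_seq(rng, 50), _random_seq(rng, 48)
        msa = progressive_align([SeqRecord("a", a), SeqRecord("b", b)])
        ra, rb, _ = pairwise_align_global(a, b)
        rows = dict(msa.aln.rows)
        assert rows["a"] == ra and rows["b"] == rb

    def test_dealignment_round_trip(self):
        rng = random.Random(33)
        base = _random_seq(rng, 200)
        records = []
        for i in range(4):
            seq = list(base)
            for j in range(len(seq)):
                if rng.random() < 0.03:
                    seq[j] = rng.choice("ACGT")
            if i == 2:
                seq = seq[:50] + seq[53:]
            records.append(SeqRecord(f"s{i}", "".join(seq)))
        msa = progressive_align(records)
        back = {r.id: r.seq for r in msa.aln.dealign()}
        assert back == {r.id: r.seq for r in records}

    def test_tree_must_cover_records(self):
        recs = [SeqRecord("a", "ACGTACGT"), SeqRecord("b", "ACGTACGT")]
        bad_tree = TreeNode(0.1, children=(TreeNode(0, leaf=0), TreeNode(0, leaf=2)))
        with pytest.raises(ValueError, match="tree does not cover"):
            progressive_align(recs, tree=bad_tree)


def _mk_msa(rows):
    return Msa(AlignedSet(rows), query_id="q")


class TestConservedBlocks:
    def test_all_identical(self):
        msa = _mk_msa([("a", "ACGT" * 15), ("b", "ACGT" * 15)])
        blocks = select_conserved_blocks(msa)
        assert [b.col_interval for b in blocks] == [(0, 60)]

    def test_gap_column_splits(self):
        left = "ACGTACGTACGTACG"  # 15 cols
        right = "TGCATGCATGCATGC"
        msa = _mk_msa([
            ("a", left + "A" + right),
            ("b", left + "-" + right),
        ])
        blocks = select_conserved_blocks(msa)
        assert [b.col_interval for b in blocks] == [(0, 15), (16, 31)]

    def test_short_block_dropped(self):
        msa = _mk_msa([("a", "ACGTA" + "-" + "ACGTACGTACGTACG"),
                       ("b", "ACGTA" + "-" + "ACGTACGTACGTACG")])
        blocks = select_conserved_blocks(msa)
        assert [b.col_interval for b in blocks] == [(6, 21)]

    def test_planted_mosaic(self):
        rng = random.Random(41)
        cons1 = _random_seq(rng, 30)
        cons2 = _random_seq(rng, 25)
        # divergent stretch: all three rows differ at every column
        trios = [rng.sample("ACGT", 3) for _ in range(12)]
        div_a = "".join(t[0] for t in trios)
        div_b = "".join(t[1] for t in trios)
        div_c = "".join(t[2] for t in trios)
        msa = _mk_msa([
            ("a", cons1 + div_a + cons2),
            ("b", cons1 + div_b + cons2),
            ("c", cons1 + div_c + cons2),
        ])
        p = BlockFilterParams(max_nonconserved_run=8)
        blocks = select_conserved_blocks(msa, p)
        ivs = [b.col_interval for b in blocks]
        assert len(ivs) == 2
        assert abs(ivs[0][1] - 30) <= 1 and abs(ivs[1][0] - 42) <= 1

    def test_every_block_column_meets_predicate(self):
        rng = random.Random(43)
        rows = []
        base = _random_seq(rng, 120)
        for i in range(4):
            seq = list(base)
            for j in range(len(seq)):
                if rng.random() < 0.1:
                    seq[j] = rng.choice("ACGT")
            rows.append((f"s{i}", "".join(seq)))
        msa = _mk_msa(rows)
        p = BlockFilterParams()
        blocks = select_conserved_blocks(msa, p)
        prev_end = -1
        for b in blocks:
            lo, hi = b.col_interval
            assert lo > prev_end
            prev_end = hi
            assert hi - lo >= p.min_block_len
            for c in range(lo, hi):
                col = msa.aln.column(c)
                assert "-" not in col
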