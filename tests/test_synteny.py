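"""Collinear-block chaining and syntenic depth.

Chain optimality is checked against a brute-force oracle that enumerates all
monotone anchor subsets on small instances.
"""

from collections import Counter
from itertools import combinations

import numpy as np
import pytest

import paleowgd as pw
from paleowgd.genome import AnnotatedGenome, Gene
from paleowgd.homology import HomologPair
from paleowgd.synteny import detect_blocks, depth_ratio, syntenic_depth

MATCH, GAPP = 50.0, 1.0


def _toy_genomes(order_b, n=None, label_a="A", label_b="B"):
    """Two one-chromosome genomes; genome B's gene order is a permutation of
    A's. Homolog pairs link A_i to B_i with identity 1."""
    n = n or len(order_b)
    cds = "ATGGCTGCTGCTGCTGCTGCTGCTGCTTAT"
    ga, gb = AnnotatedGenome(label_a), AnnotatedGenome(label_b)
    for i in range(n):
        ga.add(Gene(f"a{i}", "c1", 1 + 1000 * i, 30 + 1000 * i, "+", cds))
    for pos, i in enumerate(order_b):
        gb.add(Gene(f"b{i}", "c1", 1 + 1000 * pos, 30 + 1000 * pos, "+", cds))
    pairs = [
        HomologPair(f"a{i}", f"b{i}", label_a, label_b, 100.0, 1.0, "cross_genome")
        for i in range(n)
    ]
    return ga, gb, pairs


def chain_oracle(anchors, max_gap):
    """Max chain score over exhaustive subset enumeration (either orientation)."""
    best = 0.0
    n = len(anchors)
    for k in range(1, n + 1):
        for sub in combinations(sorted(anchors), k):
            for sign in (1, -1):
                ok = True
                score = MATCH
                for (ra1, rb1), (ra2, rb2) in zip(sub, sub[1:]):
                    dra, drb = ra2 - ra1, sign * (rb2 - rb1)
                    if dra < 1 or drb < 1 or dra > max_gap or drb > max_gap:
                        ok = False
                        break
                    score += MATCH - GAPP * ((dra - 1) + (drb - 1))
                if ok:
                    best = max(best, score)
    return best


class TestDetectBlocks:
    def test_perfect_collinearity_single_plus_block(self):
        ga, gb, pairs = _toy_genomes([0, 1, 2, 3, 4, 5])
        blocks = detect_blocks(pairs, ga, gb, max_gap=25, min_anchors=5)
        assert len(blocks) == 1
        (b,) = blocks
        assert b.orientation == "+"
        assert b.n_anchors() == 6
        assert b.score == 6 * MATCH

    def test_internal_inversion_hand_enumerated(self):
        # A order 0..5, B carries the middle three genes inverted.  The best
        # chain is the plus chain (0,0),(2,2),(4,4),(5,5) bridging the
        # inversion (score 4*50 - 4 = 196); the leftover minus chain
        # (1,?),(3,?) has 2 anchors < min_anchors and is discarded.
        ga, gb, pairs = _toy_genomes([0, 3, 2, 1, 4, 5])
        blocks = detect_blocks(pairs, ga, gb, max_gap=25, min_anchors=3)
        assert len(blocks) == 1
        (b,) = blocks
        assert b.orientation == "+"
        # two co-optimal 4-anchor bridges exist (via a1 or via a2); either way
        # the score is 4*50 - 4 and the flanks a0, a4, a5 are chained
        assert b.n_anchors() == 4
        assert b.score == 4 * MATCH - 4 * GAPP
        chained = {c[0] for c in b.anchor_coords}
        assert {"a0", "a4", "a5"} <= chained
        # with min_anchors=2 the inverted remnant surfaces as a minus block
        blocks2 = detect_blocks(pairs, ga, gb, max_gap=25, min_anchors=2)
        assert sorted(b.orientation for b in blocks2) == ["+", "-"]

    def test_unknown_gene_id_rejected(self):
        ga, gb, pairs = _toy_genomes([0, 1, 2])
        pairs.append(HomologPair("aX", "b0", "A", "B", 1.0, 1.0, "cross_genome"))
        with pytest.raises(ValueError, match="aX"):
            detect_blocks(pairs, ga, gb)

    def test_chain_score_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            ra = sorted(rng.choice(40, size=n, replace=False).tolist())
            rb = rng.choice(40, size=n, replace=False).tolist()
            anchors = list(zip(ra, rb))
            ga, gb, pairs = _toy_genomes([0])  # rebuilt below
            ga, gb = AnnotatedGenome("A"), AnnotatedGenome("B")
            cds = "ATGGCTGCTGCTGCTGCTGCTGCTGCTTAT"
            for r in range(41):
                ga.add(Gene(f"a{r}", "c1", 1 + 1000 * r, 30 + 1000 * r, "+", cds))
                gb.add(Gene(f"b{r}", "c1", 1 + 1000 * r, 30 + 1000 * r, "+", cds))
            pairs = [HomologPair(f"a{x}", f"b{y}", "A", "B", 100.0, 1.0,
                                 "cross_genome") for x, y in anchors]
            blocks = detect_blocks(pairs, ga, gb, max_gap=10, min_anchors=1)
            best_block = max(b.score for b in blocks)
            assert best_block == chain_oracle(anchors, max_gap=10)

    def test_raising_min_anchors_never_adds_blocks(self):
        ga, gb, pairs = _toy_genomes([0, 3, 2, 1, 4, 5, 6, 9, 8, 7, 10, 11])
        counts = [len(detect_blocks(pairs, ga, gb, min_anchors=k))
                  for k in (1, 2, 3, 5, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_raising_max_gap_never_loses_anchors(self):
        rng = np.random.default_rng(7)
        perm = rng.permutation(20).tolist()
        ga, gb, pairs = _toy_genomes(perm)
        totals = []
        for gap in (1, 2, 5, 10, 25):
            blocks = detect_blocks(pairs, ga, gb, max_gap=gap, min_anchors=1)
            totals.append(sum(b.n_anchors() for b in blocks))
        assert totals == sorted(totals)


class TestDepth:
    def test_single_block_depth_one(self):
        ga, gb, pairs = _toy_genomes([0, 1, 2, 3, 4, 5])
        blocks = detect_blocks(pairs, ga, gb, min_anchors=5)
        prof = syntenic_depth(blocks, ga)
        assert prof.modal_depth == 1
        assert set(prof.counts.values()) == {1}
        assert prof.covered_fraction == 1.0

    def test_depth_ratio_identical_genomes(self):
        ga, gb, pairs = _toy_genomes([0, 1, 2, 3, 4, 5])
        blocks = detect_blocks(pairs, ga, gb, min_anchors=5)
        assert depth_ratio(blocks, ga, gb) == (1, 1)

    def test_loss_free_wgd_self_depth(self, loss_free_wgd, loss_free_pairs):
        """After one loss-free WGD, each gene's region pairs with exactly its
        duplicate region: modal self-depth 2^1 - 1 = 1."""
        genome, _ = loss_free_wgd
        blocks = detect_blocks(loss_free_pairs, genome, genome)
        prof = syntenic_depth(blocks, genome)
        assert prof.modal_depth == 1
        assert prof.covered_fraction > 0.95
        # every gene is anchored in exactly one block
        anchored = Counter()
        for b in blocks:
            for ga_, _ra, gb_, _rb in b.anchor_coords:
                anchored[ga_] += 1
                anchored[gb_] += 1
        assert set(anchored.values()) == {1}

    def test_ks_window_requires_median_ks(self):
        ga, gb, pairs = _toy_genomes([0, 1, 2, 3, 4, 5])
        blocks = detect_blocks(pairs, ga, gb, min_anchors=5)
        with pytest.raises(ValueError, match="median_ks"):
            syntenic_depth(blocks, ga, ks_window=(0.0, 1.0))
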