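"""Collinear-block detection and syntenic depth ratios.

Homolog pairs are chained in gene-rank space (0-based order index per
chromosome) by sparse dynamic programming, per chromosome pair and
orientation: a chain's anchors must be strictly co-monotone (plus) or
anti-monotone (minus) with consecutive rank gaps of at most ``max_gap`` on
both chromosomes, and the chain score is
``match_score * n_anchors - gap_penalty * sum(rank gaps)``.  Chains are
extracted best-score-first, each homolog pair joining at most one block,
and chains shorter than ``min_anchors`` are discarded.  Defaults mirror
MCScanX (MATCH_SIZE=5, gaps up to 25 ranks, match 50, unit gap penalty).

Syntenic depth counts, per gene of a reference genome, how many blocks'
anchor spans cover that gene; the modal depth over covered genes summarizes
the ratio (a 1:4 depth against an outgroup is the classic footprint of two
rounds of WGD).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .genome import AnnotatedGenome
from .homology import HomologPair

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearBlock",
    "DepthProfile",
    "detect_blocks",
    "syntenic_depth",
    "depth_ratio",
    "write_block_table",
    "write_depth_table",
    "write_dotplot_table",
]

DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GAP = 25
DEFAULT_MATCH_SCORE = 50.0
DEFAULT_GAP_PENALTY = 1.0
TANDEM_RANK_DISTANCE = 2


@dataclass
class CollinearBlock:
    """A chained run of homolog pairs between two chromosomes."""

    block_id: int
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # '+' (ranks co-increasing) or '-'
    score: float
    anchors: list[HomologPair]
    # per-anchor (gene_on_a, rank_a, gene_on_b, rank_b), ordered along chrom_a
    anchor_coords: list[tuple[str, int, str, int]]
    median_ks: float | None = None

    def n_anchors(self) -> int:
        return len(self.anchors)

    def span(self, side: str) -> tuple[int, int]:
        """(min_rank, max_rank) of the block's anchors on side 'a' or 'b'."""
        ranks = [c[1] if side == "a" else c[3] for c in self.anchor_coords]
        return min(ranks), max(ranks)


@dataclass
class DepthProfile:
    """Per-gene syntenic block coverage of a reference genome."""

    reference: str
    counts: dict[str, int]  # gene_id -> number of covering blocks
    modal_depth: int
    covered_fraction: float


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

@njit(cache=True)
def _chain_dp(ra, rb, max_gap, match_score, gap_penalty):
    """Best-chain DP over anchors sorted by (ra, rb).

    Returns (score, parent, length) arrays; parent=-1 starts a chain."""
    n = len(ra)
    score = np.empty(n)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.ones(n, dtype=np.int64)
    lo = 0
    for i in range(n):
        score[i] = match_score
        while ra[lo] < ra[i] - max_gap:
            lo += 1
        for j in range(lo, i):
            dra = ra[i] - ra[j]
            drb = rb[i] - rb[j]
            if dra < 1 or drb < 1 or dra > max_gap or drb > max_gap:
                continue
            s = score[j] + match_score - gap_penalty * ((dra - 1) + (drb - 1))
            if s > score[i] or (s == score[i] and parent[i] != -1 and length[j] + 1 > length[i]):
                score[i] = s
                parent[i] = j
                length[i] = length[j] + 1
    return score, parent, length


def _best_chain(anchors: list[tuple[int, int, int]], max_gap: int,
                min_anchors: int, match_score: float, gap_penalty: float):
    """Best-scoring chain of length >= min_anchors, or None.

    Anchors are (ra, rb_signed, payload_index), already sorted."""
    if len(anchors) < min_anchors:
        return None
    ra = np.array([a[0] for a in anchors], dtype=np.int64)
    rb = np.array([a[1] for a in anchors], dtype=np.int64)
    score, parent, length = _chain_dp(ra, rb, max_gap, match_score, gap_penalty)
    best = -1
    for i in range(len(anchors)):
        if length[i] >= min_anchors and (best == -1 or score[i] > score[best]):
            best = i
    if best == -1:
        return None
    idxs = []
    i = best
    while i != -1:
        idxs.append(i)
        i = parent[i]
    idxs.reverse()
    return float(score[best]), [anchors[i] for i in idxs]


def _tandem_collapse(anchors, which: int):
    """Collapse anchors that share one partner gene while the other genes sit
    within TANDEM_RANK_DISTANCE ranks of each other (tandem arrays), keeping
    the best-scoring representative.  ``which`` is the collapsing side (0 for
    the a-side rank, 1 for the b-side rank)."""
    # anchors are (ra, rb, gene_a, gene_b, pair)
    partner_idx, rank_idx = (3, 0) if which == 0 else (2, 1)
    by_partner: dict[str, list] = {}
    for anc in anchors:
        by_partner.setdefault(anc[partner_idx], []).append(anc)
    kept = []
    for group in by_partner.values():
        group.sort(key=lambda a: a[rank_idx])
        cluster: list = []
        for anc in group:
            if cluster and anc[rank_idx] - cluster[-1][rank_idx] > TANDEM_RANK_DISTANCE:
                kept.append(max(cluster, key=lambda a: (a[4].score, a[0], a[1])))
                cluster = []
            cluster.append(anc)
        if cluster:
            kept.append(max(cluster, key=lambda a: (a[4].score, a[0], a[1])))
    return kept


def detect_blocks(
    pairs: Iterable[HomologPair],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    match_score: float = DEFAULT_MATCH_SCORE,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    _id_start: int = 0,
) -> list[CollinearBlock]:
    """Chain homolog pairs between two genomes (or a genome against itself)
    into collinear blocks.

    For a self comparison the trivial identity diagonal does not exist
    (homology search never emits self-hits) and tandem pairs (same chromosome,
    rank distance <= 2) are excluded; mirrored duplicates are avoided by
    canonicalizing each anchor to the upper triangle.
    """
    self_cmp = genome_a.label == genome_b.label
    ranks_a = genome_a.ranks()
    ranks_b = genome_b.ranks()
    wanted = {genome_a.label, genome_b.label}

    # (ra, rb, gene_a, gene_b, pair) per chromosome pair
    per_cp: dict[tuple[str, str], list] = {}
    for p in pairs:
        if {p.genome_a, p.genome_b} != wanted:
            continue
        if self_cmp and p.relation != "paralog":
            continue
        if not self_cmp and p.relation == "paralog":
            continue
        if p.genome_a == genome_a.label:
            ga, gb = p.gene_a, p.gene_b
        else:
            ga, gb = p.gene_b, p.gene_a
        if ga not in ranks_a:
            raise ValueError(f"unknown gene id {ga!r} in genome {genome_a.label}")
        if gb not in ranks_b:
            raise ValueError(f"unknown gene id {gb!r} in genome {genome_b.label}")
        (ca, ra), (cb, rb) = ranks_a[ga], ranks_b[gb]
        if self_cmp:
            if ca == cb and abs(ra - rb) <= TANDEM_RANK_DISTANCE:
                continue  # tandem pair
            if (cb, rb) < (ca, ra):  # canonical upper triangle
                ca, ra, ga, cb, rb, gb = cb, rb, gb, ca, ra, ga
        per_cp.setdefault((ca, cb), []).append((ra, gb, rb, ga, p))

    blocks: list[CollinearBlock] = []
    bid = _id_start
    for (ca, cb) in sorted(per_cp):
        # layout per anchor: (ra, rb, rb_key_for_sign, gene_a, gene_b, pair)
        anchors = [(ra, rb, ga, gb, p) for (ra, gb, rb, ga, p) in per_cp[(ca, cb)]]
        anchors = _tandem_collapse(anchors, which=0)
        anchors = _tandem_collapse(anchors, which=1)
        anchors.sort(key=lambda a: (a[0], a[1]))
        alive = list(range(len(anchors)))
        while True:
            # best chain in either orientation; ties favour '+'
            candidates = []
            for orientation, sign in (("+", 1), ("-", -1)):
                items = sorted((anchors[i][0], sign * anchors[i][1], i) for i in alive)
                found = _best_chain(items, max_gap, min_anchors, match_score,
                                    gap_penalty)
                if found is not None:
                    candidates.append((found[0], orientation, found[1]))
            if not candidates:
                break
            score, orientation, chain = max(candidates, key=lambda c: (c[0], c[1] == "+"))
            chosen = [anchors[i] for (_ra, _rb, i) in chain]
            bid += 1
            blocks.append(
                CollinearBlock(
                    block_id=bid,
                    genome_a=genome_a.label,
                    genome_b=genome_b.label,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    score=score,
                    anchors=[a[4] for a in chosen],
                    anchor_coords=[(a[2], a[0], a[3], a[1]) for a in chosen],
                )
            )
            used = {i for (_ra, _rb, i) in chain}
            alive = [i for i in alive if i not in used]
    logger.info("synteny: %s vs %s -> %d blocks", genome_a.label, genome_b.label,
                len(blocks))
    return blocks


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def _block_passes_window(block: CollinearBlock, ks_window) -> bool:
    if ks_window is None:
        return True
    if block.median_ks is None:
        raise ValueError(
            f"ks_window requested but block {block.block_id} has no median_ks"
        )
    lo, hi = ks_window
    return lo <= block.median_ks <= hi


def syntenic_depth(
    blocks: Sequence[CollinearBlock],
    reference: AnnotatedGenome,
    ks_window: tuple[float, float] | None = None,
) -> DepthProfile:
    """Per-gene block coverage of ``reference``.

    A block covers the reference genes lying inside its anchor span (first to
    last anchor rank on the reference chromosome).  In a self comparison both
    sides of each block cover the reference.  ``ks_window`` restricts counting
    to blocks whose ``median_ks`` falls inside the closed interval.
    """
    ranks = reference.ranks()
    label = reference.label
    # chrom -> rank -> gene_id
    gene_at: dict[str, dict[int, str]] = {}
    for gid, (chrom, r) in ranks.items():
        gene_at.setdefault(chrom, {})[r] = gid
    counts: Counter[str] = Counter()
    for b in blocks:
        if label not in (b.genome_a, b.genome_b):
            raise ValueError(
                f"block {b.block_id} does not involve reference genome {label}"
            )
        if not _block_passes_window(b, ks_window):
            continue
        sides = []
        if b.genome_a == label:
            sides.append(("a", b.chrom_a))
        if b.genome_b == label:
            sides.append(("b", b.chrom_b))
        for side, chrom in sides:
            lo, hi = b.span(side)
            lookup = gene_at.get(chrom, {})
            for r in range(lo, hi + 1):
                gid = lookup.get(r)
                if gid is not None:
                    counts[gid] += 1
    covered = [c for c in counts.values() if c >= 1]
    if covered:
        freq = Counter(covered)
        modal = sorted(freq, key=lambda d: (-freq[d], d))[0]
    else:
        modal = 0
    return DepthProfile(
        reference=label,
        counts=dict(counts),
        modal_depth=modal,
        covered_fraction=len(covered) / max(1, reference.n_genes()),
    )


def depth_ratio(
    blocks: Sequence[CollinearBlock],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    ks_window: tuple[float, float] | None = None,
) -> tuple[int, int]:
    """Modal syntenic depths (on genome_a, on genome_b) — the ratio statement.

    ``(4, 1)`` read as genome_b-regions-per-genome_a-gene : vice versa, e.g.
    an outgroup against a twice-duplicated ingroup."""
    da = syntenic_depth(blocks, genome_a, ks_window)
    db = syntenic_depth(blocks, genome_b, ks_window)
    return da.modal_depth, db.modal_depth


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_block_table(blocks: Sequence[CollinearBlock], path) -> None:
    lines = ["block_id\tgenome_a\tgenome_b\tchrom_a\tchrom_b\torientation\tscore"
             "\tn_anchors\tmedian_ks\tanchors"]
    for b in blocks:
        anchor_str = ",".join(f"{ga}|{gb}" for ga, _ra, gb, _rb in b.anchor_coords)
        ks = "" if b.median_ks is None else f"{b.median_ks:.4f}"
        lines.append(
            f"{b.block_id}\t{b.genome_a}\t{b.genome_b}\t{b.chrom_a}\t{b.chrom_b}"
            f"\t{b.orientation}\t{b.score:g}\t{b.n_anchors()}\t{ks}\t{anchor_str}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_depth_table(profile: DepthProfile, path) -> None:
    lines = ["gene_id\tdepth"]
    for gid in sorted(profile.counts):
        lines.append(f"{gid}\t{profile.counts[gid]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_dotplot_table(blocks: Sequence[CollinearBlock], path,
                        ks_by_pair: dict | None = None) -> None:
    """Anchor coordinates (+ optional Ks) in rank space, for external plotting."""
    lines = ["block_id\tchrom_a\trank_a\tgene_a\tchrom_b\trank_b\tgene_b\tks"]
    for b in blocks:
        for ga, ra, gb, rb in b.anchor_coords:
            ks = ""
            if ks_by_pair is not None:
                est = ks_by_pair.get((ga, gb)) or ks_by_pair.get((gb, ga))
                if est is not None:
                    ks = f"{est:.4f}" if isinstance(est, float) else f"{est.ks:.4f}"
            lines.append(f"{b.block_id}\t{b.chrom_a}\t{ra}\t{ga}\t{b.chrom_b}\t{rb}\t{gb}\t{ks}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
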