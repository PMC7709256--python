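"""Within- and between-genome homolog detection by exact protein alignment.

Every gene's translated CDS is compared against every gene of each target
genome with full global Needleman-Wunsch/Gotoh dynamic programming (BLOSUM62,
affine gaps) — no heuristic seeding, so scores are provably optimal.  A numba
kernel batched across equal-length targets makes the all-vs-all pass feasible
at desk scale (millions of pairs on one CPU); candidate pairs that survive
reciprocal top-n selection are then re-aligned with Biopython to obtain the
aligned pair and percent identity.

A gap of length L scores -(gap_open + (L-1)*gap_extend).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from Bio import Align
from Bio.Align import substitution_matrices

from .genome import AnnotatedGenome

logger = logging.getLogger(__name__)

__all__ = ["HomologPair", "align_proteins", "find_homolog_pairs", "all_vs_all_scores",
           "write_pair_table", "PROTEIN_ALPHABET"]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


def _blosum62_with_neutral_x() -> tuple[np.ndarray, "substitution_matrices.Array"]:
    """BLOSUM62 over the 20 amino acids, with X scoring 0 against everything."""
    bl = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            mat[i, j] = 0 if "X" in (a, b) else int(bl[a][b])
    arr = substitution_matrices.Array(PROTEIN_ALPHABET, dims=2)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            arr[a, b] = float(mat[i, j])
    return mat, arr


_SUBMAT_NP, _SUBMAT_BIO = _blosum62_with_neutral_x()
_NEG = np.int32(-(1 << 29))


@dataclass(frozen=True)
class HomologPair:
    """A scored gene-gene match; stored once in canonical order."""

    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str
    score: float
    identity: float
    relation: str  # 'paralog' | 'cross_genome'

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.relation == "paralog" and self.gene_a == self.gene_b:
            raise ValueError("a paralog pair needs two distinct genes")


def _canonical(gene_a, gene_b, genome_a, genome_b, score, identity) -> HomologPair:
    relation = "paralog" if genome_a == genome_b else "cross_genome"
    if (genome_a, gene_a) > (genome_b, gene_b):
        gene_a, gene_b = gene_b, gene_a
        genome_a, genome_b = genome_b, genome_a
    return HomologPair(gene_a, gene_b, genome_a, genome_b, score, identity, relation)


# ---------------------------------------------------------------------------
# alignment kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nw_score_profile(a, bprof, m, go, ge, Mp, Ixp, Iyp, Mc, Ixc, Iyc):
    """Gotoh global score of encoded query `a` vs a (21, m) target profile."""
    n = len(a)
    Mp[0] = 0; Ixp[0] = _NEG; Iyp[0] = _NEG
    for j in range(1, m + 1):
        Mp[j] = _NEG
        Ixp[j] = _NEG
        Iyp[j] = -go - (j - 1) * ge
    for i in range(1, n + 1):
        prow = bprof[a[i - 1]]
        Mc[0] = _NEG
        Ixc[0] = -go - (i - 1) * ge
        Iyc[0] = _NEG
        for j in range(1, m + 1):
            bp = Mp[j - 1]
            if Ixp[j - 1] > bp: bp = Ixp[j - 1]
            if Iyp[j - 1] > bp: bp = Iyp[j - 1]
            Mc[j] = bp + prow[j - 1]
            x = Mp[j] - go
            if Ixp[j] - ge > x: x = Ixp[j] - ge
            if Iyp[j] - go > x: x = Iyp[j] - go
            Ixc[j] = x
            y = Mc[j - 1] - go
            if Iyc[j - 1] - ge > y: y = Iyc[j - 1] - ge
            if Ixc[j - 1] - go > y: y = Ixc[j - 1] - go
            Iyc[j] = y
        Mp, Mc = Mc, Mp
        Ixp, Ixc = Ixc, Ixp
        Iyp, Iyc = Iyc, Iyp
    r = Mp[m]
    if Ixp[m] > r: r = Ixp[m]
    if Iyp[m] > r: r = Iyp[m]
    return r


@njit(cache=True)
def _nw_score_block(q, P, m, go, ge, Mp, Ixp, Iyp, Mc, Ixc, Iyc, out):
    """Gotoh global scores of query `q` against K equal-length targets in
    lockstep; P is a (21, m, K) profile block, state arrays are (m+1, K)."""
    n = len(q)
    K = out.shape[0]
    for k in range(K):
        Mp[0, k] = 0; Ixp[0, k] = _NEG; Iyp[0, k] = _NEG
    for j in range(1, m + 1):
        g = -go - (j - 1) * ge
        for k in range(K):
            Mp[j, k] = _NEG; Ixp[j, k] = _NEG; Iyp[j, k] = g
    for i in range(1, n + 1):
        c = q[i - 1]
        gi = -go - (i - 1) * ge
        for k in range(K):
            Mc[0, k] = _NEG; Ixc[0, k] = gi; Iyc[0, k] = _NEG
        for j in range(1, m + 1):
            for k in range(K):
                bp = Mp[j - 1, k]
                if Ixp[j - 1, k] > bp: bp = Ixp[j - 1, k]
                if Iyp[j - 1, k] > bp: bp = Iyp[j - 1, k]
                Mc[j, k] = bp + P[c, j - 1, k]
                x = Mp[j, k] - go
                if Ixp[j, k] - ge > x: x = Ixp[j, k] - ge
                if Iyp[j, k] - go > x: x = Iyp[j, k] - go
                Ixc[j, k] = x
                y = Mc[j - 1, k] - go
                if Iyc[j - 1, k] - ge > y: y = Iyc[j - 1, k] - ge
                if Ixc[j - 1, k] - go > y: y = Ixc[j - 1, k] - go
                Iyc[j, k] = y
        Mp, Mc = Mc, Mp
        Ixp, Ixc = Ixc, Ixp
        Iyp, Iyc = Iyc, Iyp
    for k in range(K):
        r = Mp[m, k]
        if Ixp[m, k] > r: r = Ixp[m, k]
        if Iyp[m, k] > r: r = Iyp[m, k]
        out[k] = r


def _encode(seq: str, what: str = "sequence") -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r} in {what}") from None


_BLOCK = 256  # targets per lockstep batch; keeps DP state L2-resident


def all_vs_all_scores(
    queries: Sequence[str],
    targets: Sequence[str],
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> np.ndarray:
    """Exact global alignment scores for every query x target pair (int32)."""
    enc_q = [_encode(s) for s in queries]
    enc_t = [_encode(s) for s in targets]
    out = np.empty((len(queries), len(targets)), dtype=np.int32)
    # bucket targets by length so each bucket runs in lockstep
    by_len: dict[int, list[int]] = {}
    for j, e in enumerate(enc_t):
        by_len.setdefault(len(e), []).append(j)
    for m, idxs in sorted(by_len.items()):
        for lo in range(0, len(idxs), _BLOCK):
            block = idxs[lo:lo + _BLOCK]
            K = len(block)
            B = np.stack([enc_t[j] for j in block]).astype(np.int64)  # (K, m)
            P = np.ascontiguousarray(_SUBMAT_NP[:, B.T])  # (21, m, K)
            bufs = [np.empty((m + 1, K), np.int32) for _ in range(6)]
            col = np.empty(K, np.int32)
            cols = np.array(block)
            for i, q in enumerate(enc_q):
                _nw_score_block(q, P, m, gap_open, gap_extend, *bufs, col)
                out[i, cols] = col
    return out


def align_proteins(
    seq_a: str,
    seq_b: str,
    substitution_matrix=None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> tuple[float, float, tuple[str, str]]:
    """Optimal global alignment of two protein sequences.

    Returns (score, identity, (aligned_a, aligned_b)) where identity is
    matches over aligned columns (double-gap columns cannot occur in a global
    pairwise alignment).  Empty sequences and characters outside the 20-letter
    alphabet + X are rejected.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    _encode(seq_a, "seq_a"), _encode(seq_b, "seq_b")  # validation
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = (
        _SUBMAT_BIO if substitution_matrix is None else substitution_matrix
    )
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aligner.mode = "global"
    aln = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    identity = matches / len(row_a)
    return float(aln.score), identity, (row_a, row_b)


# ---------------------------------------------------------------------------
# homolog pair search
# ---------------------------------------------------------------------------

def _top_n_rows(scores: np.ndarray, top_n: int, self_cmp: bool) -> set[tuple[int, int]]:
    """(i, j) pairs where j is among row i's top_n scores.

    Rows/columns are in lexicographic gene-id order, so breaking score ties by
    index is the deterministic id tie-break."""
    nA, nB = scores.shape
    keep: set[tuple[int, int]] = set()
    idx = np.arange(nB)
    for i in range(nA):
        order = np.lexsort((idx, -scores[i]))
        picked = 0
        for j in order[: top_n + (1 if self_cmp else 0)]:
            if self_cmp and i == j:
                continue
            keep.add((i, int(j)))
            picked += 1
            if picked >= top_n:
                break
    return keep


def _top_n_sets(scores: np.ndarray, top_n: int, self_cmp: bool):
    """Reciprocal top-n candidate pairs: (i, j) kept iff j is among i's top_n
    row scores AND i is among j's top_n column scores."""
    rows = _top_n_rows(scores, top_n, self_cmp)
    cols = {(i, j) for j, i in _top_n_rows(scores.T, top_n, self_cmp)}
    return rows & cols


def find_homolog_pairs(
    genomes: Sequence[AnnotatedGenome],
    min_identity: float = 0.3,
    top_n_hits: int = 5,
    genome_pairs: Sequence[tuple[str, str]] | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> list[HomologPair]:
    """All-vs-all homolog search over a set of genomes.

    For each unordered genome pair (self pairs included, yielding paralogs)
    the reciprocal top-n best-scoring partners per gene are retained, pairs
    below ``min_identity`` dropped, and the result deduplicated in canonical
    order.  ``genome_pairs`` restricts which genome pairs are compared.
    """
    by_label = {g.label: g for g in genomes}
    if len(by_label) != len(genomes):
        raise ValueError("genome labels must be unique")
    prots = {g.label: g.proteins() for g in genomes}
    labels = [g.label for g in genomes]
    if genome_pairs is None:
        genome_pairs = [
            (labels[i], labels[j]) for i in range(len(labels)) for j in range(i, len(labels))
        ]
    pairs: dict[tuple[str, str, str, str], HomologPair] = {}
    for la, lb in genome_pairs:
        ids_a = sorted(prots[la])
        ids_b = sorted(prots[lb])
        seqs_a = [prots[la][g] for g in ids_a]
        seqs_b = [prots[lb][g] for g in ids_b]
        if not ids_a or not ids_b:
            continue
        logger.info("homology: %s vs %s (%d x %d genes)", la, lb, len(ids_a), len(ids_b))
        scores = all_vs_all_scores(seqs_a, seqs_b, gap_open, gap_extend)
        keep = _top_n_sets(scores, top_n_hits, self_cmp=(la == lb))
        for i, j in sorted(keep):
            if la == lb and i >= j:
                continue  # symmetric matrix: count each pair once
            _score, identity, _ = align_proteins(
                seqs_a[i], seqs_b[j], gap_open=gap_open, gap_extend=gap_extend
            )
            if identity < min_identity:
                continue
            hp = _canonical(ids_a[i], ids_b[j], la, lb, float(scores[i, j]), identity)
            pairs[(hp.genome_a, hp.gene_a, hp.genome_b, hp.gene_b)] = hp
    return [pairs[k] for k in sorted(pairs)]


def write_pair_table(pairs: Sequence[HomologPair], path) -> None:
    lines = ["gene_a\tgene_b\tgenome_a\tgenome_b\tscore\tidentity\trelation"]
    for p in pairs:
        lines.append(
            f"{p.gene_a}\t{p.gene_b}\t{p.genome_a}\t{p.genome_b}"
            f"\t{p.score:g}\t{p.identity:.4f}\t{p.relation}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
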