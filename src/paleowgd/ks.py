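"""Codon alignment and Nei-Gojobori (NG86) Ka/Ks estimation.

The NG86 counting method, as implemented in PAML's yn00 output columns:

* synonymous sites per codon position = synonymous one-step changes / valid
  one-step changes (changes to or from stop codons excluded), summed over the
  three positions and averaged over the two sequences;
* observed differences per codon pair are averaged over every substitution
  pathway (permutation of the differing positions) that does not pass through
  a stop codon, each single step classified synonymous iff it preserves the
  amino acid;
* proportions pS = Sd/S and pN = Nd/N receive the Jukes-Cantor multiple-hit
  correction d = -(3/4) ln(1 - (4/3) p), undefined (saturated) once p >= 3/4.

Codon alignments are obtained by globally aligning the translated proteins
and back-translating; columns containing a gap are removed.  Standard genetic
code only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from statistics import median
from typing import Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .homology import align_proteins
from .genome import translate_cds

__all__ = ["CodonAlignment", "KsEstimate", "codon_align", "ng86", "pair_ks",
           "block_median_ks", "annotate_block_ks", "write_ks_table"]

_NTS = "ACGT"
_STOPS = set(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)

MIN_USABLE_ANCHORS = 3  # a block with fewer non-saturated anchors is uninformative


def _codon_sites(codon: str) -> float:
    """NG86 synonymous sites of one codon (stop-excluded denominator)."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in _STOPS:
                continue
            valid += 1
            if _AA[alt] == _AA[codon]:
                syn += 1
        if valid:
            total += syn / valid
    return total


_SYN_SITES = {c: _codon_sites(c) for c in _AA}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over substitution pathways.

    Pathways crossing a stop codon are discarded; if every pathway crosses a
    stop (possible only for some 3-difference pairs), all pathways are used
    and stop-crossing steps count as nonsynonymous."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                blocked = True
                nd += 1.0
            elif cur in _STOPS:
                blocked = True
                nd += 1.0
            elif _AA[nxt] == _AA[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((blocked, sd, nd))
    open_paths = [(s, n) for b, s, n in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for _b, s, n in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


@dataclass
class CodonAlignment:
    """Gap-free paired codon columns for one gene pair."""

    gene_a: str
    gene_b: str
    codons_a: list[str]
    codons_b: list[str]

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows must have equal length")
        for c in self.codons_a + self.codons_b:
            if len(c) != 3 or "-" in c or c in _STOPS:
                raise ValueError(f"bad codon column {c!r}")


@dataclass
class KsEstimate:
    """NG86 site/difference counts and Jukes-Cantor-corrected rates."""

    gene_a: str
    gene_b: str
    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    ka: float | None
    ks: float | None
    saturated: bool  # pS >= 3/4: the Ks correction is undefined


def codon_align(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b") -> CodonAlignment:
    """Protein-guided codon alignment of two CDS; gap columns dropped."""
    prot_a = translate_cds(cds_a, gene_a)
    prot_b = translate_cds(cds_b, gene_b)
    _score, _ident, (row_a, row_b) = align_proteins(prot_a, prot_b)
    codons_a, codons_b = [], []
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            codons_a.append(cds_a[3 * ia:3 * ia + 3])
            codons_b.append(cds_b[3 * ib:3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return CodonAlignment(gene_a, gene_b, codons_a, codons_b)


def _jc_correct(p: float) -> float | None:
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def ng86(alignment: CodonAlignment) -> KsEstimate:
    """Nei-Gojobori Ka/Ks for one codon alignment (standard genetic code)."""
    n = alignment.n_codons
    s_a = sum(_SYN_SITES[c] for c in alignment.codons_a)
    s_b = sum(_SYN_SITES[c] for c in alignment.codons_b)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n - S
    Sd = Nd = 0.0
    for c1, c2 in zip(alignment.codons_a, alignment.codons_b):
        if c1 == c2:
            continue
        key = (c1, c2)
        if key not in _PAIR_CACHE:
            _PAIR_CACHE[key] = _pathway_counts(c1, c2)
        sd, nd = _PAIR_CACHE[key]
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = _jc_correct(pS)
    ka = _jc_correct(pN)
    return KsEstimate(
        gene_a=alignment.gene_a, gene_b=alignment.gene_b, n_codons=n,
        N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, ka=ka, ks=ks,
        saturated=ks is None,
    )


def pair_ks(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b") -> KsEstimate:
    """Convenience: codon-align two CDS and run NG86."""
    return ng86(codon_align(cds_a, cds_b, gene_a, gene_b))


def block_median_ks(block, estimates: Mapping[tuple[str, str], KsEstimate]) -> float | None:
    """Median Ks over a block's anchor pairs, saturated anchors excluded.

    Returns None (uninformative) when fewer than three usable anchors remain.
    The even-count median is the mean of the central pair."""
    values = []
    for ga, _ra, gb, _rb in block.anchor_coords:
        est = estimates.get((ga, gb)) or estimates.get((gb, ga))
        if est is None:
            raise ValueError(f"anchor {ga}/{gb} of block {block.block_id} "
                             "has no Ks estimate")
        if not est.saturated:
            values.append(est.ks)
    if len(values) < MIN_USABLE_ANCHORS:
        return None
    return float(median(values))


def annotate_block_ks(blocks: Sequence, estimates: Mapping[tuple[str, str], KsEstimate]) -> None:
    """Fill ``median_ks`` on every block (None when uninformative)."""
    for b in blocks:
        b.median_ks = block_median_ks(b, estimates)


def write_ks_table(estimates: Mapping[tuple[str, str], KsEstimate], path) -> None:
    lines = ["gene_a\tgene_b\tn_codons\tN\tS\tNd\tSd\tpN\tpS\tka\tks\tsaturated"]
    for key in sorted(estimates):
        e = estimates[key]
        ka = "" if e.ka is None else f"{e.ka:.4f}"
        ks = "" if e.ks is None else f"{e.ks:.4f}"
        lines.append(
            f"{e.gene_a}\t{e.gene_b}\t{e.n_codons}\t{e.N:.4f}\t{e.S:.4f}"
            f"\t{e.Nd:.4f}\t{e.Sd:.4f}\t{e.pN:.6f}\t{e.pS:.6f}\t{ka}\t{ks}"
            f"\t{int(e.saturated)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
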