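"""Syntenic-anchor gene trees: lineage-specific vs. shared WGD classification.

From three genomes — an outgroup O with no WGD, a mid genome M with one WGD
(up to 2 syntenic copies per ancestral gene) and an ingroup I with two WGDs
(up to 4 copies) — 1:2:4 anchor groups are assembled from the collinear
blocks, a neighbor-joining tree is built per group from p-distances on the
concatenated (outgroup-guided, complete-deletion) codon alignment, rooted on
the outgroup gene, and classified:

* ``lineage_specific`` — the M copies are monophyletic AND the I copies are
  monophyletic: every duplication happened after the O/M/I speciations;
* ``shared`` — some clade joins one M copy with a strict subset of the I
  copies, the footprint of a duplication predating the M/I split;
* ``unresolved`` — anything else.

The fraction of groups in each category is the support statistic for the
hypothesis that the WGDs are lineage-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .genome import AnnotatedGenome, translate_cds
from .homology import align_proteins
from .synteny import CollinearBlock

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorGroup",
    "TopologyCall",
    "extract_anchor_groups",
    "build_group_tree",
    "classify_topology",
    "summarize_support",
    "run_topology_test",
    "write_call_table",
]

MIN_MID_GENES = 2
MIN_IN_GENES = 3
MAX_MID_GENES = 2
MAX_IN_GENES = 4


@dataclass
class AnchorGroup:
    """One outgroup gene with its syntenic M and I copies (1:2:4 pattern)."""

    outgroup_gene: str
    mid_genes: list[str]
    in_genes: list[str]
    provenance: list[int] = field(default_factory=list)  # block ids

    def all_genes(self) -> list[str]:
        return [self.outgroup_gene] + list(self.mid_genes) + list(self.in_genes)

    def informative(self) -> bool:
        return (MIN_MID_GENES <= len(self.mid_genes) <= MAX_MID_GENES
                and MIN_IN_GENES <= len(self.in_genes) <= MAX_IN_GENES)


@dataclass
class TopologyCall:
    group: AnchorGroup
    tree: TreeNode | None
    call: str  # 'lineage_specific' | 'shared' | 'unresolved'


def extract_anchor_groups(
    blocks: Sequence[CollinearBlock],
    outgroup: str,
    mid: str,
    ingroup: str,
) -> list[AnchorGroup]:
    """Assemble anchor groups by transitive closure over block anchors that
    share the same outgroup-side gene; uninformative groups (fewer than 2 M
    or 3 I copies) and over-full groups (beyond the 1:2:4 pattern) dropped."""
    partners: dict[str, dict[str, set[str]]] = {}
    prov: dict[str, set[int]] = {}
    for b in blocks:
        genomes = {b.genome_a, b.genome_b}
        if outgroup not in genomes:
            continue
        other = (genomes - {outgroup}).pop() if len(genomes) == 2 else None
        if other not in (mid, ingroup):
            continue
        o_side = "a" if b.genome_a == outgroup else "b"
        for ga, _ra, gb, _rb in b.anchor_coords:
            og, pg = (ga, gb) if o_side == "a" else (gb, ga)
            partners.setdefault(og, {"mid": set(), "in": set()})
            partners[og]["mid" if other == mid else "in"].add(pg)
            prov.setdefault(og, set()).add(b.block_id)
    groups = []
    for og in sorted(partners):
        g = AnchorGroup(
            outgroup_gene=og,
            mid_genes=sorted(partners[og]["mid"]),
            in_genes=sorted(partners[og]["in"]),
            provenance=sorted(prov[og]),
        )
        if g.informative():
            groups.append(g)
    logger.info("anchor groups: %d informative of %d outgroup genes with synteny",
                len(groups), len(partners))
    return groups


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

def _concatenated_columns(group: AnchorGroup, cds_by_gene: Mapping[str, str]) -> dict[str, str]:
    """Outgroup-guided codon matrix under complete deletion.

    Each member protein is globally aligned to the outgroup protein; only
    outgroup codon positions where every member aligns a residue are kept."""
    o = group.outgroup_gene
    cds_o = cds_by_gene[o]
    prot_o = translate_cds(cds_o, o)
    n_pos = len(prot_o)
    member_codons: dict[str, list[str | None]] = {}
    for g in group.all_genes():
        if g == o:
            member_codons[g] = [cds_o[3 * i:3 * i + 3] for i in range(n_pos)]
            continue
        cds_g = cds_by_gene[g]
        prot_g = translate_cds(cds_g, g)
        _s, _i, (row_o, row_g) = align_proteins(prot_o, prot_g)
        cols: list[str | None] = [None] * n_pos
        io = ig = 0
        for x, y in zip(row_o, row_g):
            if x != "-" and y != "-":
                cols[io] = cds_g[3 * ig:3 * ig + 3]
            if x != "-":
                io += 1
            if y != "-":
                ig += 1
        member_codons[g] = cols
    keep = [i for i in range(n_pos)
            if all(member_codons[g][i] is not None for g in group.all_genes())]
    if not keep:
        raise ValueError(f"group {o}: no codon columns shared by all members")
    return {g: "".join(member_codons[g][i] for i in keep) for g in group.all_genes()}


def build_group_tree(group: AnchorGroup, cds_by_gene: Mapping[str, str]) -> TreeNode:
    """Neighbor-joining tree from p-distances on the concatenated alignment.

    Leaf order (hence any NJ tie-break) is lexicographic on gene id; the
    returned tree is unrooted in the NJ sense — classification treats the
    outgroup leaf's edge as the root.
    """
    genes = sorted(group.all_genes())
    if len(genes) < 4:
        raise ValueError("need at least 4 leaves for a meaningful NJ tree")
    seqs = _concatenated_columns(group, cds_by_gene)
    L = len(seqs[genes[0]])
    mat = np.zeros((len(genes), len(genes)))
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = seqs[genes[i]], seqs[genes[j]]
            p = sum(1 for x, y in zip(a, b) if x != y) / L
            mat[i, j] = mat[j, i] = p
    dm = DistanceMatrix(mat, ids=genes)
    return nj(dm)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _outgroup_rooted_clades(tree: TreeNode, outgroup_gene: str) -> set[frozenset]:
    """Leaf sets of all clades when the tree is rooted on the outgroup edge."""
    leaves = {t.name for t in tree.tips()}
    if outgroup_gene not in leaves:
        raise ValueError(f"outgroup gene {outgroup_gene!r} not a leaf of the tree")
    clades: set[frozenset] = set()
    for node in tree.traverse(include_self=False):
        below = frozenset(t.name for t in node.tips()) if not node.is_tip() \
            else frozenset([node.name])
        side = below if outgroup_gene not in below else frozenset(leaves - below)
        if 0 < len(side) < len(leaves) and outgroup_gene not in side:
            clades.add(side)
    return clades


def classify_topology(tree: TreeNode, group: AnchorGroup) -> TopologyCall:
    """Monophyly-based call; invariant to leaf relabeling within M and I sets."""
    mids = frozenset(group.mid_genes)
    ins = frozenset(group.in_genes)
    clades = _outgroup_rooted_clades(tree, group.outgroup_gene)
    if mids in clades and ins in clades:
        return TopologyCall(group, tree, "lineage_specific")
    for c in clades:
        c_mids = c & mids
        c_ins = c & ins
        if len(c_mids) == 1 and c == c_mids | c_ins and 0 < len(c_ins) < len(ins):
            return TopologyCall(group, tree, "shared")
    return TopologyCall(group, tree, "unresolved")


def summarize_support(calls: Sequence[TopologyCall]) -> dict[str, float]:
    """Fractions per category over all calls; they sum to one."""
    if not calls:
        raise ValueError("no topology calls to summarize")
    out = {"lineage_specific": 0.0, "shared": 0.0, "unresolved": 0.0}
    for c in calls:
        out[c.call] += 1.0
    return {k: v / len(calls) for k, v in out.items()}


def run_topology_test(
    groups: Sequence[AnchorGroup],
    cds_by_gene: Mapping[str, str],
) -> list[TopologyCall]:
    """Build and classify a tree for every informative anchor group."""
    calls = []
    for g in groups:
        try:
            tree = build_group_tree(g, cds_by_gene)
        except ValueError as exc:
            logger.warning("group %s: %s -> unresolved", g.outgroup_gene, exc)
            calls.append(TopologyCall(g, None, "unresolved"))
            continue
        calls.append(classify_topology(tree, g))
    return calls


def parse_newick(newick: str) -> TreeNode:
    return TreeNode.read(StringIO(newick))


def write_call_table(calls: Sequence[TopologyCall], path) -> None:
    lines = ["group\tcall\tmid_genes\tin_genes\ttree"]
    for c in calls:
        nwk = ""
        if c.tree is not None:
            buf = StringIO()
            c.tree.write(buf)
            nwk = buf.getvalue().strip()
        lines.append(
            f"{c.group.outgroup_gene}\t{c.call}\t{','.join(c.group.mid_genes)}"
            f"\t{','.join(c.group.in_genes)}\t{nwk}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
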