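"""Annotated-genome container and FASTA/GFF3 round-trip.

The whole pipeline operates on :class:`AnnotatedGenome`: ordered protein-coding
genes per chromosome, each carrying its CDS in coding orientation.  Coordinates
follow GFF3 (1-based, inclusive, genes non-overlapping); synteny works in
gene-rank space (0-based order index per chromosome), which this module
precomputes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = ["Gene", "AnnotatedGenome", "read_genome", "write_genome", "translate_cds"]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    cds: str  # nucleotides, coding orientation (already reverse-complemented for '-')

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def translate_cds(cds: str, gene_id: str = "?") -> str:
    """Translate a CDS (standard code), rejecting frame violations and internal stops.

    A single trailing stop codon is tolerated and trimmed.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"gene {gene_id}: CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError(f"gene {gene_id}: internal stop codon in CDS")
    return prot


@dataclass
class AnnotatedGenome:
    """Ordered genes per chromosome with CDS sequences."""

    label: str
    genes: dict[str, Gene] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rank_cache: dict[str, tuple[str, int]] | None = None

    def add(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        self._rank_cache = None

    def chromosomes(self) -> dict[str, list[Gene]]:
        """Genes grouped by chromosome, ordered by start coordinate."""
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: (g.start, g.gene_id))
        return dict(sorted(by_chrom.items()))

    def ranks(self) -> dict[str, tuple[str, int]]:
        """gene_id -> (chrom, 0-based rank along the chromosome)."""
        if self._rank_cache is None:
            self._rank_cache = {
                g.gene_id: (chrom, i)
                for chrom, genes in self.chromosomes().items()
                for i, g in enumerate(genes)
            }
        return self._rank_cache

    def n_genes(self) -> int:
        return len(self.genes)

    def proteins(self) -> dict[str, str]:
        """Translated CDS per gene; untranslatable genes skipped with a warning."""
        out: dict[str, str] = {}
        for gid, g in self.genes.items():
            try:
                out[gid] = translate_cds(g.cds, gid)
            except ValueError as exc:
                logger.warning("skipping untranslatable gene: %s", exc)
        return out


# ---------------------------------------------------------------------------
# GFF3 + FASTA round trip
# ---------------------------------------------------------------------------

def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genome(fasta_path: str | Path, gff_path: str | Path, label: str | None = None) -> AnnotatedGenome:
    """Build an :class:`AnnotatedGenome` from a CDS FASTA and a GFF3 of gene features.

    The FASTA holds one record per gene (coding orientation), keyed by the
    gene's ``ID`` attribute.  Minus-strand genes therefore already store the
    reverse complement of the genomic slice.  Overlapping gene models are
    resolved by keeping the longer CDS (logged).  CDS features carrying a
    ``Parent`` that matches no gene are an error naming the offending line.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    if label is None:
        label = fasta_path.stem
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    genome = AnnotatedGenome(label=label)
    seen_ids: set[str] = set()
    rows: list[tuple[str, int, int, str, str]] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            a = _parse_gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError(f"{gff_path}:{lineno}: gene feature without ID")
                seen_ids.add(gid)
                rows.append((gid, int(start), int(end), chrom, strand))
            elif ftype in ("mRNA", "CDS"):
                parent = a.get("Parent")
                if parent is not None and parent not in seen_ids:
                    raise ValueError(
                        f"{gff_path}:{lineno}: unknown Parent {parent!r} in line: {line}"
                    )

    # resolve overlaps within a chromosome, keeping the longer CDS
    by_chrom: dict[str, list[tuple[str, int, int, str, str]]] = {}
    for gid, start, end, chrom, strand in rows:
        if gid not in seqs:
            raise ValueError(f"gene {gid} in GFF has no CDS record in {fasta_path}")
        by_chrom.setdefault(chrom, []).append((gid, start, end, chrom, strand))
    kept: list[tuple[str, int, int, str, str]] = []
    for chrom, items in by_chrom.items():
        items.sort(key=lambda r: (r[1], r[0]))
        prev = None
        for item in items:
            if prev is not None and item[1] <= prev[2]:
                keep, drop = (item, prev) if len(seqs[item[0]]) > len(seqs[prev[0]]) else (prev, item)
                logger.warning(
                    "overlapping gene models %s/%s on %s: keeping longer CDS %s",
                    prev[0], item[0], chrom, keep[0],
                )
                prev = keep
            else:
                if prev is not None:
                    kept.append(prev)
                prev = item
        if prev is not None:
            kept.append(prev)

    for gid, start, end, chrom, strand in kept:
        genome.add(Gene(gid, chrom, start, end, strand, seqs[gid]))
    return genome


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write the CDS FASTA and GFF3 that :func:`read_genome` round-trips."""
    records = []
    gff_lines = ["##gff-version 3"]
    for chrom, genes in genome.chromosomes().items():
        for g in genes:
            records.append(SeqRecord(Seq(g.cds), id=g.gene_id, description=""))
            gff_lines.append(
                "\t".join(
                    [chrom, "paleowgd", "gene", str(g.start), str(g.end), ".",
                     g.strand, ".", f"ID={g.gene_id}"]
                )
            )
    SeqIO.write(records, str(fasta_path), "fasta")
    Path(gff_path).write_text("\n".join(gff_lines) + "\n")
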