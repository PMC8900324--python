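"""Gene annotations: RefSeq-style BED reading and strand-aware anchors.

Coordinates are 0-based, half-open throughout (BED native).  A gene's
transcription start site (TSS) is its 5' genomic base: ``start`` on the
plus strand and ``end - 1`` on the minus strand; the cleavage (polyA)
site is the opposite end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError

__all__ = ["GeneAnnotation", "read_annotations", "keep_longest_isoform"]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene isoform on a genome.

    Parameters
    ----------
    gene_id : str
        Identifier (BED ``name`` field); isoforms may share it.
    chrom : str
    start, end : int
        Half-open genomic span; ``start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Sorted, non-overlapping half-open exon intervals within
        ``[start, end)``.  Defaults to a single exon spanning the gene.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        prev_end = self.start
        for (s, e) in self.exons:
            if s < prev_end or e > self.end or e <= s:
                raise ValidationError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene or overlapping"
                )
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic base of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cleavage_site(self) -> int:
        """Genomic base of the annotated polyA / cleavage site."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Half-open intervals between consecutive exons."""
        out = []
        for (a, b) in zip(self.exons[:-1], self.exons[1:]):
            if b[0] > a[1]:
                out.append((a[1], b[0]))
        return tuple(out)

    def exons_5to3(self) -> tuple[tuple[int, int], ...]:
        """Exons ordered in the direction of transcription."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


def _parse_bed_line(fields: list[str], lineno: int) -> GeneAnnotation:
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
        name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
        strand = fields[5] if len(fields) > 5 else "+"
    except (IndexError, ValueError) as exc:
        raise ParseError(f"malformed BED fields: {exc}", lineno) from None
    if strand in ("−",):  # unicode minus occasionally found in tables
        strand = "-"
    exons: tuple[tuple[int, int], ...] = ()
    if len(fields) >= 12:
        try:
            count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"malformed BED12 blocks: {exc}", lineno) from None
        if len(sizes) != count or len(offsets) != count:
            raise ParseError(
                f"blockCount={count} disagrees with blockSizes/blockStarts", lineno
            )
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    try:
        return GeneAnnotation(name, chrom, start, end, strand, exons)
    except ValidationError as exc:
        raise ParseError(str(exc), lineno) from None


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED6/BED12 annotation table into :class:`GeneAnnotation` records.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.  Errors
    name the offending line number.
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_parse_bed_line(line.split(), lineno))
    return genes


def keep_longest_isoform(genes: Iterable[GeneAnnotation]) -> list[GeneAnnotation]:
    """Retain only the longest isoform per gene_id (ties: leftmost start)."""
    best: dict[str, GeneAnnotation] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None or (g.length, -g.start) > (cur.length, -cur.start):
            best[g.gene_id] = g
    return sorted(best.values(), key=lambda g: (g.chrom, g.start))
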