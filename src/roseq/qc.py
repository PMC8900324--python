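"""Library QC statistics for run-on sequencing data.

Implements the formula-defined metrics used to characterise enrichment
(GRO vs PRO) and library-preparation (LIG/CIRC/RPR/TSRT) signatures:

* pausing index: promoter-proximal read density over gene-body density,
* exon/intron log ratio (mRNA contamination),
* gene/intergenic read ratio,
* short-read TSS ratio,
* positional nucleotide composition and prep sequence signatures,
* library complexity.

Reads are passed as a DataFrame with columns ``chrom, start, end,
strand`` (half-open intervals) and optionally ``sequence``.  Unless
noted otherwise a read is assigned to a region by its 5' end — ``start``
on '+' and ``end - 1`` on '-' — which prevents double counting across
region boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneAnnotation
from .errors import ValidationError

__all__ = [
    "PauseWindows",
    "pause_index",
    "pause_index_from_counts",
    "pause_indices",
    "exon_intron_ratio",
    "gene_intergenic_ratio",
    "short_read_tss_ratio",
    "positional_nucleotide_composition",
    "prep_signature_scores",
    "library_complexity",
]

logger = logging.getLogger(__name__)

MIN_PI_GENE_LENGTH = 2000  # genes shorter than this are excluded from PI


@dataclass(frozen=True)
class PauseWindows:
    """Window scheme for the pausing index.

    Default: paused region -50..+250 around the TSS (L1 = 300 bp), gene
    body +251 to the annotated cleavage site.  The alternate
    featureCounts-style scheme (-20..+80, body +81 to polyA - 1000) is
    available via :meth:`alternate`.
    """

    pause_upstream: int = 50
    pause_downstream: int = 250
    body_start_offset: int = 251
    body_end_offset_from_polya: int = 0

    @classmethod
    def alternate(cls) -> "PauseWindows":
        return cls(pause_upstream=20, pause_downstream=80,
                   body_start_offset=81, body_end_offset_from_polya=1000)

    @property
    def L1(self) -> int:
        return self.pause_upstream + self.pause_downstream

    def body_length(self, gene: GeneAnnotation) -> int:
        return gene.length - self.body_start_offset - self.body_end_offset_from_polya

    def genomic_regions(self, gene: GeneAnnotation):
        """((pause_start, pause_end), (body_start, body_end)), half-open."""
        if gene.strand == "+":
            tss = gene.tss
            pause = (tss - self.pause_upstream, tss + self.pause_downstream)
            body = (tss + self.body_start_offset,
                    gene.end - self.body_end_offset_from_polya)
        else:
            tss = gene.tss
            pause = (tss - self.pause_downstream + 1, tss + self.pause_upstream + 1)
            body = (gene.start + self.body_end_offset_from_polya,
                    tss - self.body_start_offset + 1)
        return pause, body


def _five_prime(reads: pd.DataFrame) -> np.ndarray:
    return np.where(reads["strand"].to_numpy() == "+",
                    reads["start"].to_numpy(),
                    reads["end"].to_numpy() - 1)


def _count_5p_in(reads: pd.DataFrame, chrom: str, strand: str,
                 start: int, end: int) -> int:
    mask = (reads["chrom"].to_numpy() == chrom) & (reads["strand"].to_numpy() == strand)
    pos = _five_prime(reads)[mask]
    return int(np.count_nonzero((pos >= start) & (pos < end)))


def pause_index_from_counts(pause_count: float, L1: float,
                            body_count: float, L2: float) -> float:
    """PI = (pause_count / L1) / (body_count / L2); NaN if body empty."""
    if L1 <= 0 or L2 <= 0:
        raise ValidationError("window lengths must be positive")
    if body_count <= 0:
        return math.nan
    return (pause_count / L1) / (body_count / L2)


def pause_index(gene: GeneAnnotation, reads: pd.DataFrame,
                windows: PauseWindows | None = None) -> float:
    """Pausing index of one gene from sense-strand reads.

    Reads are assigned by 5' end.  Returns NaN (undefined-PI sentinel)
    when the gene body holds no reads; raises for genes shorter than
    2 kb, which the windows cannot accommodate meaningfully.
    """
    windows = windows or PauseWindows()
    if gene.length < MIN_PI_GENE_LENGTH:
        raise ValidationError(
            f"{gene.gene_id}: length {gene.length} < {MIN_PI_GENE_LENGTH} bp"
        )
    (ps, pe), (bs, be) = windows.genomic_regions(gene)
    pause_count = _count_5p_in(reads, gene.chrom, gene.strand, ps, pe)
    body_count = _count_5p_in(reads, gene.chrom, gene.strand, bs, be)
    return pause_index_from_counts(pause_count, windows.L1,
                                   body_count, windows.body_length(gene))


def pause_indices(genes: Iterable[GeneAnnotation], reads: pd.DataFrame,
                  windows: PauseWindows | None = None) -> pd.Series:
    """PI per gene; short genes are dropped, undefined PIs are NaN."""
    windows = windows or PauseWindows()
    out = {}
    for g in genes:
        if g.length < MIN_PI_GENE_LENGTH:
            continue
        out[g.gene_id] = pause_index(g, reads, windows)
    return pd.Series(out, dtype=float)


def _rpkm(count: float, length_bp: int, total_reads: int) -> float:
    return count / (length_bp / 1e3) / (total_reads / 1e6)


def exon_intron_ratio(
    reads: pd.DataFrame,
    genes: Iterable[GeneAnnotation],
    total_mapped_reads: int | None = None,
    min_rpkm: float = 1.0,
    log_base: float = 2.0,
) -> tuple[pd.Series, float]:
    """Per-gene log2(exonic RPKM / intronic RPKM) and their median.

    The first exon (5'-most) of every gene is excluded to avoid the
    initiation peak.  Genes with whole-gene RPKM below ``min_rpkm``,
    without introns, or with zero reads in either compartment are
    dropped.  Reads are assigned by 5' end, sense strand.
    """
    if total_mapped_reads is None:
        total_mapped_reads = len(reads)
    if total_mapped_reads <= 0:
        raise ValidationError("total_mapped_reads must be positive")
    ratios = {}
    for g in genes:
        exons = g.exons_5to3()[1:]  # drop the first (5'-most) exon
        introns = g.introns
        if not exons or not introns:
            continue
        exon_len = sum(e - s for s, e in exons)
        intron_len = sum(e - s for s, e in introns)
        exon_count = sum(
            _count_5p_in(reads, g.chrom, g.strand, s, e) for s, e in exons
        )
        intron_count = sum(
            _count_5p_in(reads, g.chrom, g.strand, s, e) for s, e in introns
        )
        gene_rpkm = _rpkm(exon_count + intron_count, exon_len + intron_len,
                          total_mapped_reads)
        if gene_rpkm < min_rpkm:
            continue
        if intron_count == 0 or exon_count == 0:
            logger.info("exon_intron_ratio: %s has an empty compartment, dropped",
                        g.gene_id)
            continue
        ratio = _rpkm(exon_count, exon_len, total_mapped_reads) / _rpkm(
            intron_count, intron_len, total_mapped_reads
        )
        ratios[g.gene_id] = math.log(ratio, log_base)
    series = pd.Series(ratios, dtype=float)
    if series.empty:
        raise ValidationError("no genes retained for exon/intron ratio")
    return series, float(series.median())


def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    intervals.sort()
    starts, ends = [], []
    for s, e in intervals:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def gene_intergenic_ratio(
    reads: pd.DataFrame, genes: Iterable[GeneAnnotation]
) -> float:
    """Reads overlapping the strand-agnostic gene-annotation union divided
    by reads entirely outside it.

    A read is genic if it overlaps the union by at least 1 bp.  Returns
    ``inf`` when every read is genic.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    merged = {c: _merge_intervals(iv) for c, iv in by_chrom.items()}
    genic = 0
    total = len(reads)
    if total == 0:
        raise ValidationError("no reads")
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()
        # read [rs, re) overlaps some [s_i, e_i) iff an interval with
        # s_i < re has e_i > rs; intervals are disjoint and sorted.
        idx = np.searchsorted(starts, re_, "left") - 1
        ok = idx >= 0
        genic += int(np.count_nonzero(ok & (ends[np.clip(idx, 0, None)] > rs)))
    intergenic = total - genic
    if intergenic == 0:
        return math.inf
    return genic / intergenic


def short_read_tss_ratio(
    reads: pd.DataFrame,
    genes: Iterable[GeneAnnotation],
    max_len: int = 30,
    tss_window: int = 20,
) -> float:
    """Fraction of short reads whose 5' end lies near a same-strand TSS.

    Short means length <= ``max_len`` (reads over 30 bp are filtered
    out); near means within +/- ``tss_window`` bp of an annotated TSS.
    """
    lengths = (reads["end"] - reads["start"]).to_numpy()
    short = reads[lengths <= max_len]
    if len(short) == 0:
        raise ValidationError("no short reads after length filter")
    tss_by_key: dict[tuple[str, str], list[int]] = {}
    for g in genes:
        tss_by_key.setdefault((g.chrom, g.strand), []).append(g.tss)
    near = 0
    five = _five_prime(short)
    chroms = short["chrom"].to_numpy()
    strands = short["strand"].to_numpy()
    for key, tss_list in tss_by_key.items():
        tss = np.sort(np.asarray(tss_list))
        mask = (chroms == key[0]) & (strands == key[1])
        pos = five[mask]
        lo = np.searchsorted(tss, pos - tss_window, "left")
        hi = np.searchsorted(tss, pos + tss_window, "right")
        near += int(np.count_nonzero(hi > lo))
    return near / len(short)


def positional_nucleotide_composition(
    sequences: Sequence[str],
) -> pd.DataFrame:
    """Per-position base fractions across reads (columns A, C, G, T, N).

    Position ``p`` is computed over reads of length > p only, so rows
    always sum to 1 even with ragged read lengths.
    """
    seqs = [s.upper() for s in sequences if s]
    if not seqs:
        raise ValidationError("no sequences provided")
    max_len = max(len(s) for s in seqs)
    bases = "ACGTN"
    counts = np.zeros((max_len, len(bases)), dtype=float)
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        for j, b in enumerate(bases):
            hits = np.flatnonzero(arr == ord(b))
            counts[hits, j] += 1
        other = ~np.isin(arr, np.frombuffer(bases.encode(), dtype=np.uint8))
        counts[np.flatnonzero(other), len(bases) - 1] += 1  # fold unknowns into N
    totals = counts.sum(axis=1, keepdims=True)
    frac = counts / totals
    return pd.DataFrame(frac, columns=list(bases),
                        index=pd.RangeIndex(max_len, name="position"))


def prep_signature_scores(
    sequences: Sequence[str],
    polya_min: int = 8,
    cend_min: int = 3,
    window: int = 5,
) -> tuple[float, float]:
    """(polyA_fraction, terminal_C_fraction) of the read pool.

    polyA: read ends with >= ``polya_min`` consecutive A (circularization
    prep signature).  terminal C: >= ``cend_min`` C within the final
    ``window`` nt (template-switch RT signature).  Empty input gives
    (0, 0).
    """
    if not sequences:
        return 0.0, 0.0
    n_polya = n_cend = 0
    for s in sequences:
        s = s.upper()
        tail = len(s) - len(s.rstrip("A"))
        if tail >= polya_min:
            n_polya += 1
        if s[-window:].count("C") >= cend_min:
            n_cend += 1
    n = len(sequences)
    return n_polya / n, n_cend / n


def library_complexity(reads: pd.DataFrame) -> tuple[float, int]:
    """(unique_read_fraction, unique_bases_covered).

    Unique reads are distinct (chrom, start, end, strand) tuples;
    covered bases are the strand-agnostic union of read intervals.
    """
    if len(reads) == 0:
        raise ValidationError("no reads")
    uniq = reads.drop_duplicates(["chrom", "start", "end", "strand"])
    frac = len(uniq) / len(reads)
    covered = 0
    for _, sub in uniq.groupby("chrom", sort=False):
        starts, ends = _merge_intervals(
            list(zip(sub["start"].tolist(), sub["end"].tolist()))
        )
        covered += int((ends - starts).sum())
    return frac, covered


@dataclass
class QCReport:
    """Bundle of the per-library QC metrics."""

    pause_indices: pd.Series
    exon_intron_log_ratios: pd.Series
    exon_intron_median: float
    gene_intergenic: float
    short_read_tss: float
    nucleotide_composition: pd.DataFrame | None = None
    polya_fraction: float | None = None
    terminal_c_fraction: float | None = None
    unique_read_fraction: float | None = None
    unique_bases_covered: int | None = None
    extras: dict = field(default_factory=dict)
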