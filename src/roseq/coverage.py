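"""Per-base coverage tracks, bedGraph I/O and count normalizations.

A :class:`CoverageTrack` stores dense per-base, per-strand read coverage
for one library.  Minus-strand bedGraphs may follow the IGV convention of
negative values; magnitudes are stored either way.

Normalizations implemented here:

* min-max scaling of a gene's coverage vector to [0, 1] (the wavelet
  input),
* TPM (transcripts per million): per-gene count rates normalized so the
  library sums to 1e6,
* CPM scaling is applied where profiles are built (see
  :mod:`roseq.metagene`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneAnnotation
from .errors import DegenerateSignalError, ParseError, ValidationError

__all__ = [
    "CoverageTrack",
    "GeneCoverage",
    "GeneStats",
    "read_bedgraph",
    "write_bedgraph",
    "extract_gene_coverage",
    "minmax_normalize",
    "compute_tpm",
    "count_reads_in_genes",
    "gene_stats",
    "select_stable_genes",
]


@dataclass
class CoverageTrack:
    """Dense per-base coverage for one strand of one library.

    Attributes
    ----------
    data : dict
        chromosome name -> float64 array of non-negative per-base counts.
    strand : str
        ``"+"`` or ``"-"``.
    total_mapped_reads : int
        Library depth used for CPM/RPKM scaling.
    """

    data: dict[str, np.ndarray] = field(default_factory=dict)
    strand: str = "+"
    total_mapped_reads: int = 0

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom])

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values on ``[start, end)``; out-of-bounds positions are zero.

        Returns a fresh array of length ``end - start``.
        """
        if chrom not in self.data:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        arr = self.data[chrom]
        out = np.zeros(end - start, dtype=float)
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


@dataclass
class GeneCoverage:
    """Sense-strand coverage over a gene window, oriented 5'->3'."""

    values: np.ndarray
    clipped: bool = False

    def __len__(self) -> int:
        return len(self.values)


def read_bedgraph(
    path: str | Path,
    strand: str = "+",
    total_mapped_reads: int = 0,
    chrom_sizes: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Expand a 4-column bedGraph into a dense per-base track.

    Overlapping intervals are summed.  On the minus strand, negative
    values (IGV convention) are stored as magnitudes; negative values on
    the plus strand are rejected.  When ``chrom_sizes`` is given,
    intervals extending past the declared length are an error; otherwise
    chromosome lengths are inferred from the furthest interval end.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError("expected 4 bedGraph columns", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3].replace("−", "-"))
            except ValueError as exc:
                raise ParseError(f"non-numeric bedGraph field: {exc}", lineno)
            if end <= start:
                raise ParseError(f"empty interval {start}..{end}", lineno)
            if value < 0:
                if strand != "-":
                    raise ParseError(
                        "negative coverage value on plus-strand track", lineno
                    )
                value = -value
            if chrom_sizes is not None and end > chrom_sizes.get(chrom, 0):
                raise ValidationError(
                    f"line {lineno}: interval end {end} beyond declared length "
                    f"of {chrom} ({chrom_sizes.get(chrom, 0)})"
                )
            intervals.setdefault(chrom, []).append((start, end, value))

    data: dict[str, np.ndarray] = {}
    for chrom, rows in intervals.items():
        length = (
            chrom_sizes[chrom] if chrom_sizes is not None else max(e for _, e, _ in rows)
        )
        arr = np.zeros(length, dtype=float)
        for s, e, v in rows:
            arr[s:e] += v
        data[chrom] = arr
    if chrom_sizes is not None:
        for chrom, length in chrom_sizes.items():
            data.setdefault(chrom, np.zeros(length, dtype=float))
    return CoverageTrack(data=data, strand=strand, total_mapped_reads=total_mapped_reads)


def write_bedgraph(track: CoverageTrack, path: str | Path, signed: bool = False) -> None:
    """Write a track as run-length-encoded bedGraph (zero runs omitted).

    With ``signed=True`` a minus-strand track is written with negative
    values (IGV convention).
    """
    sign = -1.0 if (signed and track.strand == "-") else 1.0
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            # run boundaries wherever the value changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{sign * v:g}\n")


def extract_gene_coverage(
    plus: CoverageTrack,
    minus: CoverageTrack,
    gene: GeneAnnotation,
    upstream: int = 0,
    downstream: int = 0,
) -> GeneCoverage:
    """Sense-strand coverage over a gene, reported 5'->3'.

    ``upstream`` bases precede the TSS and ``downstream`` bases follow
    the cleavage site in the direction of transcription; minus-strand
    genes are reversed so index 0 is the most 5' position.  Windows
    overhanging the chromosome are zero-filled and flagged.
    """
    track = plus if gene.strand == "+" else minus
    if gene.chrom not in track.data:
        raise ValidationError(f"unknown chromosome {gene.chrom!r}")
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.end + downstream
    else:
        lo, hi = gene.start - downstream, gene.end + upstream
    values = track.get(gene.chrom, lo, hi)
    clipped = lo < 0 or hi > track.chrom_length(gene.chrom)
    if gene.strand == "-":
        values = values[::-1]
    return GeneCoverage(values=values, clipped=clipped)


def minmax_normalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Scale a coverage vector to [0, 1]: ``(x - min) / (max - min)``.

    Raises :class:`DegenerateSignalError` for constant input; callers
    are expected to exclude such genes.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 positions to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSignalError("constant signal has zero dynamic range")
    return (x - lo) / (hi - lo)


def compute_tpm(
    counts_per_gene: Mapping[str, float], lengths: Mapping[str, float]
) -> dict[str, float]:
    """Transcripts-per-million from per-gene counts and lengths (bp).

    ``TPM_g = 1e6 * (count_g / length_g) / sum_h (count_h / length_h)``;
    the result sums to 1e6.
    """
    rates = {}
    for g, c in counts_per_gene.items():
        length = lengths[g]
        if length <= 0:
            raise ValidationError(f"{g}: non-positive length {length}")
        rates[g] = c / length
    total = sum(rates.values())
    if total <= 0:
        raise ValidationError("all gene counts are zero; TPM undefined")
    return {g: 1e6 * r / total for g, r in rates.items()}


def count_reads_in_genes(
    reads: pd.DataFrame,
    genes: Iterable[GeneAnnotation],
    same_strand: bool = True,
) -> dict[str, int]:
    """Count reads per gene by 5'-end position over the gene body.

    ``reads`` needs columns chrom/start/end/strand.  A read's 5' end is
    ``start`` on '+' and ``end - 1`` on '-'.
    """
    five = np.where(reads["strand"].to_numpy() == "+",
                    reads["start"].to_numpy(),
                    reads["end"].to_numpy() - 1)
    chroms = reads["chrom"].to_numpy()
    strands = reads["strand"].to_numpy()
    # pre-sort 5' positions per (chrom, strand) for binary search
    sorted_pos: dict[tuple[str, str], np.ndarray] = {}
    for key in set(zip(chroms, strands)):
        mask = (chroms == key[0]) & (strands == key[1])
        sorted_pos[key] = np.sort(five[mask])
    counts: dict[str, int] = {}
    for g in genes:
        n = 0
        keys = [(g.chrom, g.strand)] if same_strand else [
            (g.chrom, "+"), (g.chrom, "-")
        ]
        for key in keys:
            pos = sorted_pos.get(key)
            if pos is not None:
                n += int(np.searchsorted(pos, g.end, "left")
                         - np.searchsorted(pos, g.start, "left"))
        counts[g.gene_id] = n
    return counts


@dataclass
class GeneStats:
    """Cross-sample TPM summary for one gene."""

    gene_id: str
    tpm: dict[str, float]
    mean_tpm: float
    cv: float


def gene_stats(tpm_table: pd.DataFrame) -> list[GeneStats]:
    """Per-gene mean TPM and coefficient of variation across samples.

    ``tpm_table`` is genes x samples.  CV uses the population standard
    deviation (ddof=0) divided by the mean; genes with zero mean get
    cv = 0 by convention (they are never selected anyway).
    """
    if tpm_table.shape[1] < 2:
        raise ValidationError("CV needs at least 2 samples")
    stats = []
    means = tpm_table.mean(axis=1)
    sds = tpm_table.std(axis=1, ddof=0)
    for g in tpm_table.index:
        m = float(means[g])
        cv = float(sds[g] / m) if m > 0 else 0.0
        stats.append(GeneStats(g, tpm_table.loc[g].to_dict(), m, cv))
    return stats


def select_stable_genes(
    stats: Iterable[GeneStats], cv_max: float = 0.55, tpm_min: float = 150.0
) -> list[str]:
    """Genes with cv < cv_max and mean TPM > tpm_min (strict on both).

    The default thresholds pick ubiquitously, highly transcribed genes
    whose coverage shape is comparable across libraries.
    """
    return [s.gene_id for s in stats if s.cv < cv_max and s.mean_tpm > tpm_min]
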