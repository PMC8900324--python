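"""TSS-anchored, CPM-normalized average coverage profiles.

A metagene averages per-gene coverage in a fixed window around the TSS
(oriented 5'->3'), after scaling each library to counts-per-million so
profiles are comparable across depths.  Gene filters follow the usual
run-on QC practice: drop short genes, genes with substantial upstream
signal (likely run-through from a neighbour), and barely transcribed
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotations import GeneAnnotation
from .coverage import CoverageTrack
from .errors import ValidationError

__all__ = ["MetageneProfile", "filter_genes_for_metagene", "build_metagene",
           "peak_position", "average_profiles"]

logger = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    """Average CPM profile around the TSS.

    ``sense``/``antisense`` have length upstream + downstream + 1 with
    index ``upstream`` at the TSS.
    """

    upstream: int
    downstream: int
    sense: np.ndarray
    antisense: np.ndarray
    n_genes: int
    filters_applied: dict = field(default_factory=dict)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.upstream, self.downstream + 1)


def filter_genes_for_metagene(
    genes: Iterable[GeneAnnotation],
    plus: CoverageTrack,
    minus: CoverageTrack,
    tpm: dict[str, float] | None = None,
    min_len: int = 2000,
    upstream_window: int = 2000,
    upstream_cov_frac: float = 0.01,
    tpm_min: float = 0.01,
) -> list[GeneAnnotation]:
    """Apply the metagene gene filters; returns the retained genes.

    Removes genes shorter than ``min_len``, genes with more than
    ``upstream_cov_frac`` of the ``upstream_window`` bases covered on
    the sense strand (upstream contamination), and genes below
    ``tpm_min`` TPM.  Raises with per-filter attrition counts if
    nothing survives.
    """
    genes = list(genes)
    attrition = {"input": len(genes), "short": 0, "upstream_signal": 0,
                 "low_tpm": 0, "retained": 0}
    kept = []
    for g in genes:
        if g.length < min_len:
            attrition["short"] += 1
            continue
        track = plus if g.strand == "+" else minus
        if g.strand == "+":
            up = track.get(g.chrom, g.tss - upstream_window, g.tss)
        else:
            up = track.get(g.chrom, g.tss + 1, g.tss + 1 + upstream_window)
        if np.count_nonzero(up) / upstream_window > upstream_cov_frac:
            attrition["upstream_signal"] += 1
            continue
        if tpm is not None and tpm.get(g.gene_id, 0.0) < tpm_min:
            attrition["low_tpm"] += 1
            continue
        kept.append(g)
    attrition["retained"] = len(kept)
    logger.info("metagene filters: %s", attrition)
    if not kept:
        raise ValidationError(f"no genes retained; attrition: {attrition}")
    return kept


def build_metagene(
    plus: CoverageTrack,
    minus: CoverageTrack,
    genes: Sequence[GeneAnnotation],
    upstream: int = 1000,
    downstream: int = 3000,
    filters_applied: dict | None = None,
) -> MetageneProfile:
    """Average sense/antisense CPM around the TSS over a gene set.

    Each gene contributes equal weight; windows overhanging a
    chromosome are zero-filled (and logged).  CPM scaling uses each
    track's ``total_mapped_reads``.
    """
    if not genes:
        raise ValidationError("empty gene set")
    total = plus.total_mapped_reads or 1
    scale = 1e6 / total
    width = upstream + downstream + 1
    sense_sum = np.zeros(width)
    anti_sum = np.zeros(width)
    for g in genes:
        sense_track = plus if g.strand == "+" else minus
        anti_track = minus if g.strand == "+" else plus
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream + 1
            s = sense_track.get(g.chrom, lo, hi)
            a = anti_track.get(g.chrom, lo, hi)
        else:
            lo, hi = g.tss - downstream, g.tss + upstream + 1
            s = sense_track.get(g.chrom, lo, hi)[::-1]
            a = anti_track.get(g.chrom, lo, hi)[::-1]
        if lo < 0 or hi > sense_track.chrom_length(g.chrom):
            logger.info("metagene: window for %s clipped", g.gene_id)
        sense_sum += s
        anti_sum += a
    n = len(genes)
    return MetageneProfile(
        upstream=upstream,
        downstream=downstream,
        sense=sense_sum * scale / n,
        antisense=anti_sum * scale / n,
        n_genes=n,
        filters_applied=filters_applied or {},
    )


def average_profiles(profiles: Sequence[MetageneProfile]) -> MetageneProfile:
    """Equal-weight average of per-sample profiles (same window)."""
    if not profiles:
        raise ValidationError("no profiles")
    first = profiles[0]
    if any((p.upstream, p.downstream) != (first.upstream, first.downstream)
           for p in profiles):
        raise ValidationError("profiles have mismatched windows")
    return MetageneProfile(
        upstream=first.upstream,
        downstream=first.downstream,
        sense=np.mean([p.sense for p in profiles], axis=0),
        antisense=np.mean([p.antisense for p in profiles], axis=0),
        n_genes=first.n_genes,
        filters_applied={"averaged_over": len(profiles)},
    )


def peak_position(profile: MetageneProfile) -> int:
    """Offset (bp from TSS) of the sense-profile maximum.

    Ties are broken toward the TSS (smallest |offset|; upstream loses
    to downstream at equal distance only if it appears later — the
    smaller absolute offset wins, then the smaller offset).
    """
    y = profile.sense
    if np.all(y == y[0]):
        raise ValidationError("constant profile has no peak")
    offsets = profile.offsets
    top = np.flatnonzero(y == y.max())
    cand = offsets[top]
    order = np.lexsort((cand, np.abs(cand)))
    return int(cand[order[0]])
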