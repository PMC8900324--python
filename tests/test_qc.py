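import math

import numpy as np
import pytest

from conftest import mkreads
from roseq.annotations import GeneAnnotation
from roseq.errors import ValidationError
from roseq.qc import (
    PauseWindows,
    exon_intron_ratio,
    gene_intergenic_ratio,
    library_complexity,
    pause_index,
    pause_index_from_counts,
    positional_nucleotide_composition,
    prep_signature_scores,
    short_read_tss_ratio,
)


# ------------------------------------------------------------ pause index

def test_pause_index_formula():
    assert pause_index_from_counts(30, 300, 60, 3000) == pytest.approx(5.0)
    # uniform density: pause and body rates equal -> PI = 1
    assert pause_index_from_counts(30, 300, 300, 3000) == pytest.approx(1.0)
    assert math.isnan(pause_index_from_counts(30, 300, 0, 3000))


def test_default_windows_match_convention():
    w = PauseWindows()
    assert (w.pause_upstream, w.pause_downstream, w.L1) == (50, 250, 300)
    g = GeneAnnotation("g", "chr1", 1000, 4000, "+")
    (ps, pe), (bs, be) = w.genomic_regions(g)
    assert (ps, pe) == (950, 1250)
    assert (bs, be) == (1251, 4000)
    assert w.body_length(g) == 3000 - 251


def test_pause_index_counts_sense_5prime_ends_and_scales_invariantly():
    g = GeneAnnotation("g", "chr1", 1000, 4000, "+")
    pause_reads = [("chr1", 1000 + i, 1030 + i, "+") for i in range(30)]
    body_reads = [("chr1", 1300 + 7 * i, 1340 + 7 * i, "+") for i in range(60)]
    anti = [("chr1", 1000, 1030, "-")] * 50  # wrong strand, ignored
    reads = mkreads(pause_reads + body_reads + anti)
    pi = pause_index(g, reads)
    assert pi == pytest.approx((30 / 300) / (60 / (3000 - 251)))
    doubled = mkreads((pause_reads + body_reads) * 2)
    assert pause_index(g, doubled) == pytest.approx(pi)


def test_pause_index_minus_strand_geometry():
    g = GeneAnnotation("g", "chr1", 1000, 4000, "-")  # TSS at 3999
    # one read with 5' end exactly at the TSS and one deep in the body
    reads = mkreads([("chr1", 3970, 4000, "-"), ("chr1", 1500, 1540, "-")])
    pi = pause_index(g, reads)
    assert pi == pytest.approx((1 / 300) / (1 / (3000 - 251)))


def test_pause_index_rejects_short_genes():
    g = GeneAnnotation("g", "chr1", 0, 1999, "+")
    with pytest.raises(ValidationError):
        pause_index(g, mkreads([("chr1", 0, 30, "+")]))


# ------------------------------------------------------- exon/intron ratio

def _three_exon_gene():
    return GeneAnnotation(
        "g", "chr1", 0, 3000, "+",
        exons=((0, 500), (1000, 1500), (2500, 3000)),
    )


def test_exon_intron_log2_of_fourfold_rpkm_is_two():
    g = _three_exon_gene()
    # exons 2+3: 1000 bp; introns: 1500 bp. 4:1 RPKM => 4000:1500 counts ratio
    exon = [("chr1", 1000 + i % 500, 1040 + i % 500, "+") for i in range(800)]
    intron = [("chr1", 500 + i % 490, 540 + i % 490, "+") for i in range(300)]
    reads = mkreads(exon + intron)
    ratios, median = exon_intron_ratio(reads, [g], total_mapped_reads=len(reads))
    # RPKM ratio = (800/1000) / (300/1500) = 4 -> log2 = 2
    assert ratios["g"] == pytest.approx(2.0)
    assert median == pytest.approx(2.0)


def test_exon_intron_equal_rpkm_gives_zero_and_first_exon_is_ignored():
    g = _three_exon_gene()
    exon = [("chr1", 1000 + i % 500, 1040, "+") for i in range(200)]
    intron = [("chr1", 500 + i % 500, 560, "+") for i in range(300)]
    first_exon_pileup = [("chr1", 10, 40, "+")] * 5000  # must not matter
    reads = mkreads(exon + intron + first_exon_pileup)
    ratios, _ = exon_intron_ratio(reads, [g], total_mapped_reads=len(reads))
    # (200/1000)/(300/1500) = 1 -> log2 = 0
    assert ratios["g"] == pytest.approx(0.0)


def test_exon_intron_low_rpkm_gene_excluded():
    g = _three_exon_gene()
    reads = mkreads([("chr1", 1100, 1140, "+"), ("chr1", 600, 640, "+")])
    # whole-gene RPKM = 2 / 2.5kb / (2e6/1e6) ... with a huge depth it is << 1
    with pytest.raises(ValidationError):
        exon_intron_ratio(reads, [g], total_mapped_reads=10_000_000)


# ---------------------------------------------------- gene/intergenic ratio

def test_gene_intergenic_examples():
    g = GeneAnnotation("g", "chr1", 1000, 2000, "+")
    genic = [("chr1", 1100, 1140, "+")] * 80
    inter = [("chr1", 5000, 5040, "-")] * 20
    assert gene_intergenic_ratio(mkreads(genic + inter), [g]) == pytest.approx(4.0)
    assert gene_intergenic_ratio(mkreads(genic), [g]) == math.inf
    # 1-bp overlap counts as genic; reads on either strand count
    edge = mkreads([("chr1", 961, 1001, "-"), ("chr1", 900, 1000, "+")])
    assert gene_intergenic_ratio(edge, [g]) == pytest.approx(1.0)


def test_gene_intergenic_matches_known_fraction(small_genome):
    annos, sizes = small_genome
    rng = np.random.default_rng(0)
    # place reads explicitly: f genic, rest in gaps, fully contained
    f = 0.75
    n = 2000
    genic_rows = []
    for i in range(int(n * f)):
        g = annos[int(rng.integers(len(annos)))]
        s = int(rng.integers(g.start, g.end - 20))
        genic_rows.append(("chr1", s, s + 20, "+"))
    inter_rows = []
    spans = [(annos[i].end, annos[i + 1].start) for i in range(len(annos) - 1)]
    while len(inter_rows) < n - int(n * f):
        lo, hi = spans[int(rng.integers(len(spans)))]
        if hi - lo > 40:
            s = int(rng.integers(lo, hi - 20))
            inter_rows.append(("chr1", s, s + 20, "+"))
    ratio = gene_intergenic_ratio(mkreads(genic_rows + inter_rows), annos)
    assert ratio == pytest.approx(f / (1 - f))


# ------------------------------------------------------ short-read TSS ratio

def test_short_read_tss_ratio_examples():
    g = GeneAnnotation("g", "chr1", 1000, 4000, "+")
    near = [("chr1", 1005, 1030, "+")] * 3
    far = [("chr1", 2000 + 50 * i, 2025 + 50 * i, "+") for i in range(7)]
    long_read = [("chr1", 1001, 1032, "+")]  # 31 bp: filtered entirely
    reads = mkreads(near + far + long_read)
    assert short_read_tss_ratio(reads, [g]) == pytest.approx(0.3)
    assert short_read_tss_ratio(mkreads(near), [g]) == 1.0
    with pytest.raises(ValidationError):
        short_read_tss_ratio(mkreads(long_read), [g])


def test_short_read_tss_ratio_requires_same_strand():
    g = GeneAnnotation("g", "chr1", 1000, 4000, "+")
    wrong = mkreads([("chr1", 1005, 1030, "-"), ("chr1", 2000, 2025, "+")])
    assert short_read_tss_ratio(wrong, [g]) == 0.0


# ----------------------------------------------- composition & signatures

def test_nucleotide_composition_examples():
    m = positional_nucleotide_composition(["AAAA", "AAAC"])
    assert m.loc[3, "A"] == 0.5 and m.loc[3, "C"] == 0.5
    single = positional_nucleotide_composition(["ACGT"])
    assert np.allclose(np.diag(single[["A", "C", "G", "T"]]), 1.0)
    ragged = positional_nucleotide_composition(["AA", "AAG"])
    assert ragged.loc[2, "G"] == 1.0  # computed over the one long read
    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)


def test_prep_signature_thresholds():
    polya = "ACGT" * 4 + "A" * 8       # exactly 8 terminal A
    cend = "ACGTACGTACG" + "GCCCT"     # 3 C in final 5
    neither = "ACGTACGT"
    pa, cf = prep_signature_scores([polya, cend, neither])
    assert pa == pytest.approx(1 / 3)
    assert cf == pytest.approx(1 / 3)
    assert prep_signature_scores([]) == (0.0, 0.0)


# ------------------------------------------------------------- complexity

def test_library_complexity_union_semantics():
    dup = mkreads([("chr1", 0, 50, "+")] * 10)
    frac, bases = library_complexity(dup)
    assert frac == pytest.approx(0.1)
    assert bases == 50
    disjoint = mkreads([("chr1", 0, 50, "+"), ("chr1", 100, 150, "-")])
    assert library_complexity(disjoint) == (1.0, 100)
    overlapping = mkreads([("chr1", 0, 50, "+"), ("chr1", 0, 50, "-")])
    assert library_complexity(overlapping)[1] == 50


# ------------------------------------- generator-calibrated QC recoveries

def test_exon_intron_median_orders_gro_above_pro(gro_sample, pro_sample, small_genome):
    """More mRNA contamination (GRO) => larger exon/intron median."""
    annos, _ = small_genome
    _, med_gro = exon_intron_ratio(gro_sample.reads, annos)
    _, med_pro = exon_intron_ratio(pro_sample.reads, annos)
    assert med_gro > med_pro


def test_prep_tail_rates_recovered(gro_sample, pro_sample):
    """CIRC poly(A) and TSRT terminal-C rates recovered within binomial CI."""
    pa, _ = prep_signature_scores(gro_sample.reads["sequence"].tolist())
    _, cf = prep_signature_scores(pro_sample.reads["sequence"].tolist())
    assert pa == pytest.approx(0.5, abs=0.02)
    assert cf > 0.45  # 0.5 injected + small random baseline


def test_short_fragment_rate_shows_in_tss_ratio(gro_sample, pro_sample, small_genome):
    annos, _ = small_genome
    assert short_read_tss_ratio(pro_sample.reads, annos) > short_read_tss_ratio(
        gro_sample.reads, annos
    )


def test_gene_intergenic_orders_gro_above_pro(gro_sample, pro_sample, small_genome):
    annos, _ = small_genome
    assert gene_intergenic_ratio(gro_sample.reads, annos) > gene_intergenic_ratio(
        pro_sample.reads, annos
    )
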