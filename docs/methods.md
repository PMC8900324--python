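# Methods

`roseq` quantifies the technical signatures that run-on sequencing
enrichment protocols (GRO-seq, PRO-seq) and library-preparation
chemistries (ligation, circularization, random priming, template-switch
RT) leave in a sequencing library, and classifies the enrichment
protocol of a library directly from its coverage signal.  This note
describes the models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## Coordinate and counting conventions

All coordinates are 0-based, half-open (BED native).  A gene's TSS is
its 5'-most base (`start` on `+`, `end - 1` on `-`); the cleavage
(polyA) site is the opposite end.  Where a read must be assigned to a
region (pause window, gene body, exon, intron, TSS proximity), its
**5' end** decides — `start` on `+`, `end - 1` on `-` — which prevents
a read from being counted in two adjacent regions.  The gene/intergenic
ratio is the exception: it follows read-distribution convention and
counts a read as genic if it overlaps the strand-agnostic union of
annotated gene spans by at least 1 bp.  Minus-strand bedGraphs may
carry negative values (IGV convention); magnitudes are stored.

## QC statistics

**Pausing index.** PI = (pause-region count / L1) / (body count / L2),
sense-strand reads only.  Default windows: pause −50..+250 from the TSS
(L1 = 300 bp), body +251 to the annotated cleavage site.  An alternate
scheme (−20..+80; +81 to polyA − 1000) is available via
`PauseWindows.alternate()`.  Genes shorter than 2000 bp are excluded;
an empty body yields NaN and the gene is dropped from summaries.  Only
a gene's longest isoform should be supplied (`keep_longest_isoform`).

**Exon/intron ratio** (mRNA-contamination proxy).  Per gene,
log2(RPKM_exonic / RPKM_intronic), first (5'-most) exon excluded to
avoid the initiation peak, genes with whole-gene RPKM < 1 excluded;
the library summary is the median over retained genes.  Log base 2 is
a package choice; any base only rescales the medians jointly.

**Short-read TSS ratio.** Reads longer than 30 bp are discarded;
the statistic is the fraction of remaining reads whose 5' end lies
within ±20 bp of a same-strand annotated TSS.

**Prep sequence signatures.** Circularization preps polyadenylate
before RT, so untrimmed reads end in poly(A): a read counts if it ends
in ≥ 8 consecutive A.  Template-switch RT appends C's: a read counts if
≥ 3 C occur in its final 5 nt.  The thresholds are package choices
(the phenomena are qualitative in origin); at these settings the
random-sequence false-positive rate is ≈ 0.002% (poly(A)) and ≈ 5%
(terminal C).

**Complexity.** Distinct (chrom, start, end, strand) tuples over total
reads, and the size of the strand-agnostic union of covered bases.

## Wavelet protocol signature

Coverage over a gene (sense strand, 5'→3') is min-max normalized,
`c_i = (x_i − min x)/(max x − min x)`; constant genes are rejected.  A
**single-level** symlet-5 DWT (symmetric padding) splits the signal
into approximation (consistent polymerase shape) and detail
(high-frequency) coefficients; systematic protocol artifacts live in
the detail band alongside shot noise.  One decomposition level is used
throughout — deeper stacks are out of scope.  Perfect reconstruction
holds to < 1e-8 relative error; energy conservation is exact in
periodized mode (symmetric padding redistributes boundary energy, so
the energy identity is asserted only for periodization).  Polynomial
annihilation (constant/ramp → zero detail) holds for all coefficients
away from the padded boundary; under linear-extension padding it holds
for every coefficient.

Genes enter this analysis only if ubiquitously and highly transcribed:
TPM coefficient of variation (population SD / mean, across samples)
< 0.55 and mean TPM > 150, both strict (a second, looser tier at
CV < 0.85 / TPM > 100 can be selected by passing those thresholds).
TPM counts the sense-strand 5' ends over the full annotated gene body —
the same region whose coverage feeds the transform.

Per gene, the samples × detail-coefficients matrix is reduced by PCA:
columns are mean-centered, no variance scaling (the coefficients share
units), scores are projections on the top-2 right singular vectors.
Each loading vector is oriented so its largest-magnitude entry is
positive; this makes scores, and therefore every downstream fold,
byte-reproducible.  Genes are categorised as `PC1_separable` (a
threshold on PC1 alone splits the protocols), `plane_separable` (a
strictly separating line exists in the PC1/PC2 plane — decided exactly
by linear-programming feasibility), or `not_separable`.

## Classifier

Per gene, a linear-kernel SVM (C = 1.0) on the (PC1, PC2) scores,
evaluated by leave-one-out cross-validation: n samples → n folds, each
sample held out once.  Features are z-scaled **within each training
fold** (mean/SD of the 17 training samples, applied to the held-out
sample).  Scaling is essential, not cosmetic: PC scores of normalized
coverage are O(0.05), and an unscaled soft margin at C = 1 collapses
to majority-of-training voting, which under leave-one-out predicts the
wrong class systematically.  Standard SVM front ends scale by default
for the same reason.  PCA is computed once on all samples and folds
are evaluated on the precomputed scores; passing
`refit_pca_per_fold=True` instead re-estimates the score basis inside
every training fold (the precomputed variant mildly leaks the held-out
sample into the score basis, not into the SVM; the refit variant is
stricter but its basis is noisier on small folds).

Per-sample calls use majority voting across genes; exact ties are
broken by the sign of the summed SVM decision values and flagged.

**Leave-one-out null behaviour.**  With balanced classes, the held-out
sample's class is always the minority of its training fold, so on
label-uninformative features LOOCV is pessimistically biased: the null
mean accuracy sits well *below* 0.5 (≈ 0.3 in our null cohorts), not
at it.  The meaningful null check is therefore one-sided — accuracy
must not exceed the upper binomial bound around 0.5, which would
indicate information leaking through the pipeline.  Signal cohorts are
unaffected (accuracy ≈ 1 when a margin exists).

## Run-on simulator

A 2000-nt template with equal A/C/G/T counts (shuffled, seeded).
Polymerase positions: 10,000 initiation ~ round(N(+50, 25)) clipped to
the template, 5,000 elongating ~ Uniform(300, 2000).  The normal's
parameters and the elongation interval are package defaults — the
pause region of a typical gene sits a few tens of bp downstream of the
TSS.  Each polymerase extends base by base; at every occurrence of the
labeled base (C, the biotin-marked nucleotide) extension halts with
probability `p_bio` (the biotin fraction of that base's pool:
`p_bio_from_ntp_pool(biotin, cold)`), otherwise it stops after
`max_runon` = 100 nt or at the template end — the cap stands in for
the brief run-on window when no terminator is incorporated (GRO mode,
p_bio = 0).  On an equal-composition template the per-base halt rate
is p_bio/4, so uncapped run-on lengths are geometric with mean
4/p_bio.  The bulk path uses this geometric formulation over the
template's labeled-base index; it is distributionally identical to the
base-by-base walk and exact at the p_bio ∈ {0, 1} endpoints.

Reads span [TSS, termination) — transcript length measured from the
TSS — with an optional polymerase-anchored emission for sensitivity
analysis.  Size selection mimics AMPure cleanup: each read draws a
cutoff ~ Exponential(mean 25 nt) and is retained iff at least that
long, so P(retain | L) = 1 − exp(−L/25), monotone in L.

**Short-read TSS fraction.**  The mappable short-fragment population
is modelled on the run-on *fragments* (5' end at the polymerase
position, length = extension): fragments below 16 nt (a typical
aligner floor) are unmappable, and 2,000 handling fragments (uniform
positions, exponential lengths of mean 20 nt) form the genome-wide
short-read background the statistic is normalized against.  The
fraction of mappable, retained, ≤ 30 nt fragments starting within
20 nt of the TSS then peaks at intermediate p_bio — high biotin makes
TSS-proximal fragments too short to map or survive selection, low
biotin makes them too long to be short — reproducing the non-monotone
dependence on the biotin/NTP ratio.  Anchoring this statistic at the
TSS-spanning transcript instead would pin every 5' end to the TSS and
degenerate the fraction to 1.  The simulated metagene is emitted both
as full-read coverage and as the 3'-end (termination) density; the 5'
peak shift with p_bio is read from the latter, since TSS-anchored
full-read coverage is by construction maximal at the TSS.

## Metagene

Sense and antisense coverage in [TSS − upstream, TSS + downstream],
oriented 5'→3', scaled to CPM (1e6 / library depth), averaged with
equal weight per gene and then per sample.  Gene filters: length
≥ 2000 bp; upstream contamination — more than 1% of the bases in the
upstream window (2 kb default, figure-specific elsewhere) covered on
the gene's strand removes the gene; TPM < 0.01 removes the gene.  Peak
position is the sense argmax, ties broken toward the TSS.  The
upstream filter presumes sparse intergenic coverage; on the densely
covered synthetic genome it removes everything, so generator-based
tests exercise it on constructed sparse tracks.

## Synthetic cohort generator

One chromosome; by default 100 non-overlapping genes of 2.5–3.5 kb
with 2–4 exons on random strands, 0.5–1.5 kb gaps; 9 GRO + 9 PRO
samples of 200,000 reads each (preps cycle GRO: LIG/CIRC/RPR,
PRO: LIG/TSRT, the combinations used in practice).  Reads are drawn
from a per-gene mixture: 20% 5'-peak component (Gaussian at
TSS + peak_offset, width 30 bp), gene-body component, exon-biased
contamination, TSS-proximal sub-30-nt fragments, and uniform
intergenic background.  Protocol signatures (defaults):

| knob | GRO | PRO | measured by |
|---|---|---|---|
| peak offset (bp) | +20 | +80 | metagene peak position |
| texture period (bp) | 6 | 3 | wavelet detail PCA / SVM |
| texture amplitude | 0.6 | 0.6 | — |
| exon contamination | 0.15 | 0.05 | exon/intron median |
| short-fragment rate | 0.02 | 0.10 | short-read TSS ratio |
| intergenic fraction | 0.08 | 0.12 | gene/intergenic ratio |

The texture is a multiplicative sinusoid on the read-start density,
phase-anchored to genomic coordinates so it is systematic across
samples of a protocol, with periods chosen to land in the detail band
of a single-level transform (wavelengths 2–8 bp).  Read lengths are
N(40, 8) clipped to [20, 80] nt; CIRC reads carry 8–12 nt poly(A)
tails at rate 0.5 and TSRT reads terminal C-runs at rate 0.5.  A
per-sample, per-gene lognormal expression wobble (σ = 0.1) sets the
cross-sample TPM CV.  Per-gene coverage equals the base-wise sum of
the emitted read intervals exactly.  All randomness descends from one
master seed via `SeedSequence.spawn`, one stream per sample.

What the generator does **not** emulate: real genome sequence
(read sequences are uniform random apart from prep tails), PCR
duplicates, mappability structure, sparse intergenic deserts (so the
upstream metagene filter is not applicable to generated cohorts), or
any biological perturbation response.  Passing tests therefore show
that each module recovers the signature it targets from data where
that signature is present by construction — not that real GRO/PRO
libraries are classified at any particular accuracy.

## Problem sizes and determinism

Default analyses run on the cohort sizes above (18 samples × 100
genes; ~3.6 M reads per cohort) and complete in seconds on one core.
Simulator checks use 10 seeds × an 8-point p_bio grid at the default
15,000 polymerases.  Every stochastic path takes an explicit seed or
generator; fitting the same cohort twice is byte-identical.

## Known limitations

* The upstream-contamination metagene filter is strand-aware by
  choice; the convention in the field's tooling is unstated.
* TPM for gene selection counts the full gene body, not exons only.
* The LOOCV null sits below chance (see above); compare observed
  accuracies against that empirical null, not against 0.5.
* Linear separability in PC space is decided exactly; with > 2
  protocols the categories would need redefinition.
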