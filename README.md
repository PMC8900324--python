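# roseq

Protocol signatures in run-on sequencing libraries.

Nascent-transcription assays capture RNA still engaged with RNA
polymerase.  The two main enrichment strategies — GRO-seq (Br-UTP +
anti-BrdU pulldown) and PRO-seq (biotin-NTP incorporation, which also
terminates extension) — combined with different library-preparation
chemistries (ligation, circularization, random priming, template-switch
RT) leave systematic technical marks in the resulting libraries: shifted
5' peaks at transcription start sites, different levels of mRNA
contamination, characteristic read-end sequences, and reproducible
high-frequency texture in the coverage signal.  `roseq` is for
computational biologists who work with such libraries and need to
(a) quantify these signatures as QC statistics, and (b) identify the
enrichment protocol of a library directly from its data.

## What it computes

* **QC metrics** — RNA Pol II pausing index
  `PI = (reads in pause window / L1) / (reads in gene body / L2)`
  (pause window −50..+250 bp around the TSS, L1 = 300 bp);
  per-gene log2 exon/intron RPKM ratios and their median; gene vs
  intergenic read ratio; short-read (≤ 30 nt) TSS ratio; positional
  nucleotide composition; poly(A)-tail and terminal-C prep signatures;
  library complexity.
* **Protocol classification** — per gene, coverage is min-max
  normalized (`c_i = (x_i − min x)/(max x − min x)`), decomposed by a
  single-level symlet-5 DWT, and the high-frequency detail
  coefficients are reduced by PCA across samples; a linear SVM over
  the per-gene (PC1, PC2) scores is evaluated by leave-one-out
  cross-validation, with a majority vote across genes calling each
  sample's protocol.
* **Run-on simulation** — polymerases placed around a TSS extend along
  a synthetic template and halt with probability `p_bio` at each
  labeled base (biotin chemistry), followed by exponential-cutoff size
  selection (mean 25 nt); outputs metagene traces, 3'-end densities
  and short-read statistics as functions of the biotin/NTP ratio.
* **TSS metagenes** — CPM-normalized average profiles with the
  standard gene filters (length ≥ 2 kb, clean 2 kb upstream, TPM ≥ 0.01).
* **Synthetic cohorts** — seeded libraries (coverage + reads +
  sequences + truth labels) with controllable protocol and prep
  signatures, so the whole pipeline is testable offline.

## Worked example

```python
from roseq.synth import CohortConfig, generate_cohort
from roseq.model import ProtocolSignatureModel

config = CohortConfig(n_genes=50, n_samples_per_protocol=6,
                      depth_per_sample=100_000, seed=42)
samples, labels, annotations, chrom_sizes = generate_cohort(config)
model = ProtocolSignatureModel(samples, annotations,
                               genes=[g.gene_id for g in annotations])
results = model.fit()
print(results.summary())
```

prints

```
Protocol signature classification (wavelet detail PCA + linear SVM, LOOCV)
==========================================================================
Samples:                12  (folds = 12)
Genes analysed:         50
Wavelet / padding:      sym5 / symmetric
SVM C:                  1
--------------------------------------------------------------------------
Mean per-gene accuracy: 0.887
Median accuracy:        0.958
Genes >= 70% accurate:  80.0%
Majority-vote accuracy: 100.0%  (12/12 samples)
--------------------------------------------------------------------------
Separability categories:
  PC1_separable      68.0%
  plane_separable    12.0%
  not_separable      20.0%
==========================================================================
```

Reading this: each of the 50 genes contributes one leave-one-out SVM
evaluated on its own wavelet-detail PC scores; the average single-gene
classifier identifies the protocol of a held-out library 88.7% of the
time, and letting the genes vote identifies it for every library.
68% of genes separate GRO from PRO on PC1 alone and another 12% on a
line in the PC1/PC2 plane.

The same pipeline is scriptable from the shell:

```sh
roseq synth --seed 42 --out cohort/          # write bedGraphs/BED/labels
roseq classify --cohort cohort/ --out acc.tsv
roseq simulate --p-bio 0.2 --seed 7 --out sim/
roseq qc --reads reads.bed --annotations genes.bed --out report.tsv
roseq metagene --bedgraph-pos s.pos.bedGraph --bedgraph-neg s.neg.bedGraph \
    --annotations genes.bed --out profile.tsv
```

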