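# clonetrace

Analysis toolkit for two single-cell lineage questions in experimental
hematology, built around lentiviral cellular barcoding and multiplex
qRT-PCR:

1. **Clonal lineage tracking.** Progenitors are tagged with heritable DNA
   barcodes from a finite viral library (725 legal 30-mers built on the
   degenerate template `GGNNNACNNNGTNNNTANNNCANNNTGNNN`), transplanted,
   and their progeny re-sorted into compartments — here a self-renewing
   progenitor population (NMP) and two blast compartments (myeloblasts MB,
   erythroblasts EB). A barcode recovered from several compartments means
   one clone fed them all. `clonetrace` recovers barcodes from amplicon
   FASTQ, applies a depth-scaled inclusion floor, and asks whether the
   observed sharing exceeds chance.
2. **Lineage co-expression.** Single cells or colonies are profiled on
   myeloid and erythroid gene panels by multiplex qRT-PCR. `clonetrace`
   QC-filters Ct tables on housekeeping assays, normalizes to
   2<sup>−ΔCt</sup>, counts co-expressed lineage genes per cell, and
   compares genotypes per gene.

A synthetic-data module generates both data types with known ground truth,
so the whole pipeline is testable without external data.

## Statistical core

**Set-overlap nulls.** Under the null, each compartment's barcode set is
an independent uniform fixed-size subset of a pool of N barcodes. For two
sets of sizes n_A, n_B the intersection size X is hypergeometric and the
reported p is the enrichment tail

P(X ≥ k) = Σ_{x≥k} C(n_A, x) · C(N−n_A, n_B−x) / C(N, n_B).

For m sets the package provides both a Monte-Carlo random-draw estimate
(default 10,000,000 iterations, add-one corrected) and an exact tail: the
running intersection of a fixed size-j set with a fresh uniform n-subset
is again hypergeometric, so the m-way intersection law follows by folding
hypergeometric kernels — exact at any pool size. Two-way tests default to
the library pool (N = 725); m-way tests to the union of detected barcodes.

**qRT-PCR scoring.** Assays flagged `Fail` become undetected (Ct = 999);
cells whose housekeeping Ct misses an explicit cutoff are dropped; the
relative expression of a detected gene is 2^−(Ct − h̄) with h̄ the mean
housekeeping Ct of that cell. Genotypes are compared per gene on level
(two-sided rank-sum on 2^−ΔCt, zeros included) and on detection frequency
(two-sided Fisher's exact test), combined by Fisher's method
(χ² = −2 Σ ln p against df = 2k). The erythroid-to-myeloid
expression-frequency ratio R is the mean per-gene detection frequency of
the erythroid panel over that of the myeloid panel.

## Worked example

`python examples/barcode_tracking.py` simulates a transplantation of 400
barcoded clones (30% tripotent) sequenced at 50k reads per compartment
with 0.5% substitution error, and prints:

```
barcodes per population: {'NMP': 400, 'MB': 174, 'EB': 184}
Venn regions: {'NMP': 157, 'MB': 0, 'NMP&MB': 59, 'EB': 0, 'NMP&EB': 69,
               'MB&EB': 0, 'NMP&MB&EB': 115}

2-way MB/EB overlap: k=115 of pool 725, p = 2.07e-41 (hypergeometric)
3-way overlap: k=115 of union pool 400, Monte-Carlo p = 1e-06 (M=1,000,000),
               exact p = 1e-12
```

All 115 tripotent-region barcodes sit in the triple intersection; both
overlap tests reject chance sharing decisively — the signature of
multipotent clones feeding every compartment. `examples/overlap_nulls.py`
shows the nulls on a hand-checkable instance (P(|A∩B| ≥ 3) = 66/252 for
4- and 5-subsets of a 10-pool), and `examples/qpcr_coexpression.py` runs
the qPCR arm, recovering frequency ratios R = 0.12 for a myeloid-committed
condition vs R = 0.85 for an erythroid-shifted one, with erythroid genes
topping the per-gene combined p-values.

There is also a thin CLI (`clonetrace simulate | extract | overlap | qpcr
| coexpress | run-all`) for shell use; see `clonetrace --help`.

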