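# pairomics

How much of a tumor's aberrant gene expression can DNA methylation and
somatic copy number aberration (SCNA) actually explain?  `pairomics`
implements an integrative paired tumor/normal analysis over three array
platforms — log2 expression per transcript, normalized methylation score
per probe, and SNP-array log R ratio (LRR) per copy-number probe — for
study designs where every tumor sample has a matched normal tissue from
the same patient.  It is aimed at cancer epigenomics analysts who want the
full chain, from per-probe paired tests to a cohort-level attribution
statement, as a tested, scriptable library.

## The method

For each platform, every feature is tested with a two-sided paired Student
t-test on the within-pair differences *d* = tumor − normal,

&nbsp;&nbsp;&nbsp;&nbsp;*t* = mean(*d*) / (sd(*d*)/√n),&nbsp;&nbsp;df = n − 1,

with family-wise error controlled per platform by Bonferroni: the
significance threshold is α/m where m is the number of features tested on
that platform (Benjamini–Hochberg FDR control is available as the
validation-style alternative).  Significant features are then collapsed to
gene level:

* **Methylation** — the significant probes of a gene are averaged per
  direction; a gene whose significant probes disagree in direction yields
  one aggregate per direction, both carried forward independently.
* **Copy number** — instead of a segmentation algorithm, a spanning rule:
  a gene is called only where ≥ 2 *adjacent* significant probes (in
  genomic order) share a direction; isolated significant probes never
  produce a call.  Same-direction runs merge into one call per direction
  with the mean LRR delta across the contributing probes.

Each differentially expressed (DE) gene is then classified starburst-style
per mechanism: **explained** requires a coordinate direction pair
(hypermethylated & down-regulated, hypomethylated & up-regulated, copy
gain & up, loss & down) **and** a significant sign-consistent Spearman
correlation between expression and the gene-level mechanism signal
(negative for methylation, positive for copy number) across the pooled
tumor + normal samples.  The cohort contribution report divides the
explained counts by the DE gene count; the union fraction subtracts genes
explained by both mechanisms.

A synthetic-data generator plants genes into five classes (null,
expression-only, methylation-driven with inverse coupling, CN-driven with
positive dosage coupling, dual) with within-pair correlation and
per-platform noise, so every stage is verifiable by parameter recovery
against the recorded truth table.

## Worked example

`examples/04_integration_and_contribution.py` simulates a 300-gene,
30-pair cohort and runs the full pipeline:

```
differentially expressed genes: 150
  with methylation overlap: 23 (explained: 23)
  with SCNA overlap:        33 (explained: 32)
  explained by both:        4
fraction explained -- methylation: 15.3%, copy number: 21.3%, union: 34.0%
planted truth      -- methylation: 15.4%, copy number: 24.4%, union: 37.2%
  G0002: expression down, methylation up, rho = -0.45 (p = 3.6e-04) -> explained_hyper_down
```

Of the 150 DE genes the pipeline attributes 15.3% to methylation and
21.3% to copy number, against planted truths of 15.4% and 24.4% — the
per-gene starburst line shows one hypermethylated, down-regulated gene
whose expression is significantly anti-correlated with its methylation
signal.  The other examples cover simulation (`01`), differential testing
and cluster separation (`02`), gene-level collapse and SCNA calling
(`03`), and reference-list overlap (`05`).

The same stages are available from a shell:

```
pairomics simulate --config sim.yaml --out data/
pairomics difftest --matrix data/expression.tsv --platform expression --out diff_expr.tsv
pairomics run-all --data data/ --out results/
pairomics compare --study genes.txt --reference ref.txt
```

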