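# Methods

## Data model and conventions

All stages operate on `PairedOmicsMatrix` objects: a feature × pair matrix
per platform, with the tumor and normal halves kept aligned by pair id.
Pair linkage is encoded in matrix column names (`<pair>_T` / `<pair>_N`);
coordinates in annotations are 0-based half-open (BED convention), so the
package interoperates with standard genome-arithmetic tooling.  Missing
values are written as `NA`; a feature missing either half of a pair drops
that pair for that feature's test (complete-pairs analysis).  Matrices are
written at full double precision so read/write round-trips are bit-exact;
report fractions are serialized with six decimal digits.

## Differential testing

Each feature is tested with a two-sided one-sample Student t on the
within-pair differences.  Degenerate inputs are handled explicitly:
identically zero differences give t = 0, p = 1; zero-variance nonzero-mean
differences are reported as the p → 0 limit but flagged `degenerate`
rather than trusted, avoiding spurious infinities downstream.  Features
with fewer than two complete pairs are flagged `untestable`, reported, and
excluded from the multiplicity count m, so the Bonferroni threshold α/m
always reflects the tests actually performed on that platform.  The
Benjamini–Hochberg step-up alternative (`correction: bh`) delegates to
statsmodels and always rejects a superset of the Bonferroni rejections at
equal α.

Tumor/normal separability on the significant features is summarized by
agglomerative clustering of the 2n sample profiles — average linkage on
1 − Pearson correlation, a standard expression-heatmap choice, exposed in
the config — cut at two clusters and scored by the adjusted Rand index
against the true labels.  Note the correlation distance is invariant to a
uniform shift of a sample's profile: separation is visible only when the
tumor/normal difference varies across features, which is the realistic
regime and the one the simulator produces.

## Gene-level summaries

Methylation probes collapse per gene and per direction: the aggregate is
the arithmetic mean of the contributing significant probes' mean
differences.  A gene with significant probes in both directions emits two
aggregates (split indices 0/1) that travel through integration
independently; the gene counts as explained if either split qualifies.
Expression transcripts collapse with the identical rule.

Copy-number calling deliberately avoids segmentation algorithms (their
outputs disagree across tools) in favor of a spanning rule: "adjacent"
means consecutive among that gene's annotated CN probes ordered by
genomic coordinate, runs never span a chromosome boundary, and a run must
contain at least `min_adjacent_probes` (default 2, the minimum the rule
permits) significant probes of one sign.  Probes with mean difference
exactly 0 cannot be significant (their p is 1), so no sign tie-break is
needed.  Same-direction runs of one gene merge into a single call whose
mean LRR delta is taken over all contributing probes of that direction;
opposite directions yield separate gain and loss calls.  Interpretation
choice: runs are evaluated within each gene's own probe set rather than
across intergenic probes, since the unit of every downstream statement is
the gene.

## Integration

Spearman correlation is the Pearson correlation of average ranks.  For
n ≤ 7 the two-sided p-value is the exact permutation tail mass over all
n! rank permutations; for larger n the Student-t approximation
t = ρ√((n−2)/(1−ρ²)) is used.  Zero rank variance leaves ρ undefined and
flagged; such genes can never be called explained.  The correlation level
`spearman_alpha` is 0.05, two-sided and uncorrected — the correlation step
is a confirmation applied to an already FWER-screened gene set, not an
additional discovery screen — and is exposed in the config.

"Explained" is the conjunction of coordinate direction and significant
sign-consistent correlation.  Because a looser reading (coordinate
direction alone) is also defensible, the contribution report carries both:
`n_*_explained` under the conjunction and `n_*_coordinate` without the
correlation gate, so either reading can be audited.  Correlations are
computed across all 2n pooled tumor + normal samples by default,
maximizing dynamic range; `correlation_samples: tumor` restricts to tumor
samples.  The union fraction is inclusion–exclusion:
(meth + cn − both) / DE.

## Synthetic cohorts

The generator emulates a 30-pair discovery design: per gene, one
expression transcript, 5–50 methylation probes and 5–40 CN probes laid
out consecutively on synthetic chromosomes (genes never interleave), so
probe adjacency is well defined.  Within-pair correlation comes from a
latent per-probe, per-pair baseline shared by both halves; with noise SD
σ and baseline SD τ = σ√(ρ/(1−ρ)), tumor and normal correlate at
ρ_pair = 0.5 under the null.  Methylation lives on an unbounded score
scale (normalized log-intensity methylation arrays are not bounded beta
values), so no truncation is applied.

Planted classes and defaults: methylation shift ±0.8 score units, LRR
shift ±0.5, expression couplings β = −1.0 (inverse) and γ = +1.5 log2
units per unit shift, expression-only shift ±1.0 log2, noise SDs
0.5/0.3/0.2 per platform.  No published effect-size estimates exist for
this design, so these are arbitrary choices sized for essentially full
per-feature power at n = 30.  Two consequences are worth knowing when
interpreting recovery rates.  First, at m = 300 expression tests the
noncentral-t power for a methylation-driven gene's expression call
(effect 0.8 log2, paired-difference SD 0.5·√2) is 0.95.  Second, because
the planted coupling is a deterministic group-mean shift, a driven gene's
expression co-varies with its methylation signal only through tumor/normal
group membership, which caps the pooled-sample Spearman correlation near
the point-biserial value ρ ≈ 0.5; at 60 samples the α = 0.05 gate then
misses a further ~2% of genes.  The full-pipeline recovery rate of
methylation-driven genes therefore plateaus around 93%, a property of
these study conditions rather than of the implementation.  Dual-class
genes draw one expression direction and set both mechanism signs
coherently with it (hypermethylated + deleted → down), the biologically
typical configuration, so the two drivers never cancel.  CN shifts are
applied to one contiguous probe run covering `frac_probes_affected`
(default all) of the gene's probes, giving the adjacency rule realistic
segmental structure; `n_artifact_genes` optionally plants single-probe
LRR shifts into null genes to exercise the rule's rejection of isolated
probes.  Seeding is hierarchical — the global seed spawns one substream
per gene — so enlarging a cohort never perturbs earlier genes' draws, and
identical configs are bit-reproducible.

What the simulator does *not* model: batch effects and their correction
artifacts, tumor purity / stromal contamination, bounded beta-value
compression, probe-specific affinity biases, and linkage between genes.
Passing recovery tests therefore demonstrates the statistical chain is
correct under clean planted effects, not that the pipeline is robust to
those real-data pathologies.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use scaled-down cohorts chosen
as the smallest sizes at which each property is statistically meaningful:
error control on 200 all-null replicates of 500 features × 30 pairs per
platform; parameter recovery on 20 replicates of 300 genes × 30 pairs
with class fractions null 0.50 / expression-only 0.30 /
methylation-driven 0.08 / CN-driven 0.10 / dual 0.02.  At those sizes the
full suite runs in well under five minutes on one core.

## Known limitations

* The adjacency rule is blind to SCNAs covered by a single probe and to
  runs split across annotation gaps; that is inherent to the spanning
  strategy, not a defect.
* The Spearman gate is uncorrected across genes; with hundreds of DE
  genes a few explained calls will be correlation false positives at
  α = 0.05.
* Split-direction (two-aggregate) genes are labeled by their
  best-qualifying split; the per-split detail is retained in the
  gene-level tables but not in the per-gene integration record.
* The paired t-test assumes approximately normal within-pair differences;
  no moderated/shrinkage variance estimation is provided.
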