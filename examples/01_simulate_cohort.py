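"""Generate a synthetic paired tumor/normal cohort with planted gene classes.

Every downstream stage can be checked against the truth table this script
prints: which genes were planted as methylation-driven, copy-number-driven,
both, expression-only, or null.
"""

from collections import Counter

from pairomics import SimulationConfig, generate_dataset

config = SimulationConfig(n_genes=200, n_pairs=30, seed=7)
ds = generate_dataset(config)

print(f"pairs: {config.n_pairs}, genes: {config.n_genes}")
print(f"expression matrix:  {ds.expression.tumor.shape[0]} transcripts")
print(f"methylation matrix: {ds.methylation.tumor.shape[0]} probes")
print(f"copy-number matrix: {ds.cnv.tumor.shape[0]} probes")

counts = Counter(t.gene_class for t in ds.truth)
print("planted classes:", dict(counts))
# e.g. a meth_driven gene is hypermethylated in tumors and its expression
# moves the opposite way; null genes have no tumor/normal difference at all
example = next(t for t in ds.truth if t.gene_class == "meth_driven")
print(
    f"example: {example.gene_symbol} is {example.gene_class} "
    f"(methylation {example.meth_direction}, expression {example.expr_direction})"
)
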