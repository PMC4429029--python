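"""Collapse significant probes to gene level.

Methylation probes are averaged per gene and direction; a gene whose
significant probes disagree in direction yields two aggregates, both
carried forward.  Copy-number calls require at least two adjacent
significant same-direction probes, so isolated probes never produce a
call.
"""

from pairomics import (
    AnalysisConfig,
    SimulationConfig,
    call_scna,
    collapse_methylation,
    generate_dataset,
    run_differential,
)

ds = generate_dataset(SimulationConfig(n_genes=200, n_pairs=30, seed=7))
config = AnalysisConfig()

diff_meth = run_differential(ds.methylation, config)
aggs = collapse_methylation(diff_meth, ds.annotations)
hyper = [a for a in aggs if a.direction == "up"]
print(
    f"methylation: {sum(a.n_significant_probes for a in aggs)} significant "
    f"probes collapse to {len(aggs)} gene-level aggregates "
    f"({len(hyper)} hypermethylated, {len(aggs) - len(hyper)} hypomethylated)"
)
a = aggs[0]
print(
    f"  e.g. {a.gene_symbol}: {a.n_significant_probes} probes, "
    f"mean tumor-normal methylation shift {a.mean_delta:+.2f}"
)

diff_cnv = run_differential(ds.cnv, config)
calls = call_scna(diff_cnv, ds.annotations, min_adjacent=2)
gains = [c for c in calls if c.direction == "gain"]
print(
    f"copy number: {len(calls)} gene-level SCNA calls "
    f"({len(gains)} gains, {len(calls) - len(gains)} losses)"
)
c = calls[0]
print(
    f"  e.g. {c.gene_symbol}: {len(c.run_probe_ids)} adjacent probes, "
    f"mean LRR shift {c.mean_lrr_delta:+.2f}"
)
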