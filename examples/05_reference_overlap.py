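"""Compare a study gene list with an external reference list.

Validation of a discovery cohort against public datasets reduces to list
overlap: how many of the study's differential genes reappear, and what
percentage of the study list that is.
"""

from pairomics import overlap_genes, overlap_with_reference

study = [f"GENE{i:03d}" for i in range(252)]
# a reference list that happens to contain 200 of the study genes
reference = study[:200] + [f"OTHER{i}" for i in range(500)]

n, pct = overlap_with_reference(study, reference)
print(f"{n} of {len(study)} study genes found in the reference ({pct}%)")

a_only, both, b_only = overlap_genes(study, reference)
print(f"Venn: {a_only} study-only, {both} shared, {b_only} reference-only")
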