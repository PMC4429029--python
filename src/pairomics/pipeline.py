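"""End-to-end orchestration: differential tests -> gene level -> integration."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import AnalysisConfig
from .datatypes import (
    ContributionReport,
    DifferentialRecord,
    GeneAggregate,
    IntegrationRecord,
    PairedOmicsMatrix,
    ProbeAnnotation,
    ScnaCall,
)
from .differential import run_differential
from .gene_level import call_scna, collapse_expression, collapse_methylation
from .integration import classify, contribution


@dataclass
class PipelineResult:
    """Everything the integrative analysis produces, stage by stage."""

    diff_expression: list[DifferentialRecord]
    diff_methylation: list[DifferentialRecord]
    diff_cnv: list[DifferentialRecord]
    expr_calls: list[GeneAggregate]
    meth_aggregates: list[GeneAggregate]
    scna_calls: list[ScnaCall]
    integration: list[IntegrationRecord]
    report: ContributionReport

    @property
    def de_genes(self) -> list[str]:
        """Differentially expressed gene symbols, deduplicated, sorted."""
        return sorted({c.gene_symbol for c in self.expr_calls})


def run_pipeline(
    expression: PairedOmicsMatrix,
    methylation: PairedOmicsMatrix,
    cnv: PairedOmicsMatrix,
    annotations: Sequence[ProbeAnnotation],
    config: Optional[AnalysisConfig] = None,
) -> PipelineResult:
    """Run the full integrative analysis on three paired matrices.

    Each platform is tested with paired t-tests under its own multiplicity
    correction (m = features tested on that platform); significant
    methylation probes and transcripts are collapsed per gene and
    direction, CN probes pass through the adjacent-probe spanning rule;
    DE genes are then classified against both mechanisms and the cohort
    contribution fractions computed.
    """
    config = config or AnalysisConfig()
    annotations = list(annotations)
    diff_expr = run_differential(expression, config)
    diff_meth = run_differential(methylation, config)
    diff_cnv = run_differential(cnv, config)
    expr_calls = collapse_expression(diff_expr, annotations)
    meth_aggs = collapse_methylation(diff_meth, annotations)
    scna = call_scna(diff_cnv, annotations, config.min_adjacent_probes)
    expr_genes = {a.gene_symbol for a in annotations if a.platform == "expression"}
    records = classify(
        expr_calls,
        meth_aggs,
        scna,
        expression,
        methylation,
        cnv,
        config,
        expression_genes=expr_genes,
    )
    report = contribution(records)
    return PipelineResult(
        diff_expression=diff_expr,
        diff_methylation=diff_meth,
        diff_cnv=diff_cnv,
        expr_calls=expr_calls,
        meth_aggregates=meth_aggs,
        scna_calls=scna,
        integration=records,
        report=report,
    )
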