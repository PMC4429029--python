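"""Core data model shared by every pipeline stage.

The pipeline operates on three feature-by-pair matrices (log2 expression per
transcript, normalized methylation score per probe, log R ratio per SNP/CN
probe), a probe/transcript annotation shared by all platforms, and the
records produced stage by stage: per-feature paired-test results, gene-level
methylation/copy-number summaries, per-gene starburst categories and the
cohort-level contribution report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: Valid platform tokens and the measurement unit each one carries.
PLATFORMS = ("expression", "methylation", "cnv")
PLATFORM_UNITS = {
    "expression": "log2_expression",
    "methylation": "methylation_score",
    "cnv": "log_r_ratio",
}
STRANDS = ("+", "-", ".")
REGION_CLASSES = ("promoter", "cpg_island", "exon", "intron", "intergenic")
GENE_CLASSES = ("null", "expr_only", "meth_driven", "cn_driven", "dual")


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe (or transcript) mapped to a gene and a genomic interval.

    Coordinates are 0-based half-open (BED convention).  A probe mapping to
    several genes appears as several records sharing ``probe_id``.
    """

    probe_id: str
    platform: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    gene_symbol: str = ""
    region_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise FormatError(f"unknown platform {self.platform!r}")
        if self.start < 0 or self.end <= self.start:
            from .errors import CoordinateError

            raise CoordinateError(
                f"probe {self.probe_id}: need end > start >= 0, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"probe {self.probe_id}: bad strand {self.strand!r}")
        if self.region_class is not None and self.region_class not in REGION_CLASSES:
            raise FormatError(
                f"probe {self.probe_id}: bad region class {self.region_class!r}"
            )


@dataclass
class PairedOmicsMatrix:
    """One platform's feature-by-pair values, tumor and normal halves aligned.

    ``tumor`` and ``normal`` are DataFrames with identical index (features)
    and columns (pair ids).  Missing values are NaN; infinities are invalid.
    """

    platform: str
    tumor: pd.DataFrame
    normal: pd.DataFrame
    unit: str = ""

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise FormatError(f"unknown platform {self.platform!r}")
        if not self.unit:
            self.unit = PLATFORM_UNITS[self.platform]
        if self.unit != PLATFORM_UNITS[self.platform]:
            raise FormatError(
                f"unit {self.unit!r} inconsistent with platform {self.platform!r}"
            )
        if self.tumor.shape != self.normal.shape:
            raise FormatError("tumor and normal halves differ in shape")
        if not self.tumor.index.equals(self.normal.index) or not self.tumor.columns.equals(
            self.normal.columns
        ):
            raise FormatError("tumor and normal halves differ in feature/pair ordering")
        for half in (self.tumor, self.normal):
            vals = half.to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise FormatError("non-finite (infinite) values present")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.tumor.index)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.tumor.columns)

    @property
    def n_pairs(self) -> int:
        return self.tumor.shape[1]

    def subset_features(self, feature_ids: Sequence[str]) -> "PairedOmicsMatrix":
        """Matrix restricted to the given features, in the given order."""
        return PairedOmicsMatrix(
            platform=self.platform,
            tumor=self.tumor.loc[list(feature_ids)],
            normal=self.normal.loc[list(feature_ids)],
            unit=self.unit,
        )

    def pooled_samples(self) -> pd.DataFrame:
        """Features x (2n samples): tumor columns then normal columns.

        Column names are suffixed ``_T`` / ``_N`` so both halves coexist.
        """
        t = self.tumor.copy()
        t.columns = [f"{c}_T" for c in t.columns]
        n = self.normal.copy()
        n.columns = [f"{c}_N" for c in n.columns]
        return pd.concat([t, n], axis=1)


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-feature paired t-test result with direction and significance call.

    ``direction`` is ``up`` iff significant with positive tumor-minus-normal
    mean difference, ``down`` iff significant and negative, ``none``
    otherwise.  ``degenerate`` marks zero-variance nonzero-mean differences
    (p reported as the 0 limit but flagged rather than trusted).
    ``untestable`` marks features with fewer than two complete pairs; these
    are excluded from the multiplicity count m.
    """

    feature_id: str
    n_complete_pairs: int
    mean_diff: float
    t_stat: float
    p_value: float
    direction: str = "none"
    significant: bool = False
    threshold_used: float = float("nan")
    degenerate: bool = False
    untestable: bool = False


@dataclass(frozen=True)
class GeneAggregate:
    """Gene-level summary of same-direction significant probes.

    ``mean_delta`` is the arithmetic mean, over the contributing significant
    probes, of their tumor-minus-normal mean differences.  A gene whose
    significant probes disagree in direction yields two records
    (``split_index`` 0 and 1) carried forward independently -- the handling
    the discovery cohort needed for FYN's two opposite-direction probes.
    """

    gene_symbol: str
    platform: str
    direction: str
    n_significant_probes: int
    mean_delta: float
    probe_ids: tuple[str, ...] = ()
    split_index: int = 0


@dataclass(frozen=True)
class ScnaCall:
    """Gene-level somatic copy number call from the adjacent-probe rule.

    ``run_probe_ids`` are the significant probes contributing to the call,
    consecutive in genomic order within each run; same-direction runs of one
    gene are merged, so the mean LRR delta is taken across all contributing
    probes of that direction.
    """

    gene_symbol: str
    direction: str  # gain | loss
    run_probe_ids: tuple[str, ...]
    mean_lrr_delta: float


# Starburst categories, per platform.
METH_CATEGORIES = (
    "explained_hyper_down",
    "explained_hypo_up",
    "overlap_unexplained",
    "no_overlap",
)
CN_CATEGORIES = (
    "explained_gain_up",
    "explained_loss_down",
    "overlap_unexplained",
    "no_overlap",
)


@dataclass(frozen=True)
class IntegrationRecord:
    """Per-gene starburst classification against methylation and SCNA.

    ``explained_*`` categories require coordinate directions AND a
    significant sign-consistent Spearman correlation (negative for
    methylation, positive for copy number) between expression and the
    gene-level signal across all pooled samples.
    """

    gene_symbol: str
    expr_direction: str
    meth_direction: Optional[str] = None
    cn_direction: Optional[str] = None
    rho_meth: Optional[float] = None
    p_meth: Optional[float] = None
    rho_cn: Optional[float] = None
    p_cn: Optional[float] = None
    category_meth: str = "no_overlap"
    category_cn: str = "no_overlap"


@dataclass(frozen=True)
class ContributionReport:
    """Cohort-level attribution of aberrant expression to the two mechanisms.

    ``frac_meth`` = methylation-explained DE genes / all DE genes, and so on;
    the union fraction subtracts the doubly explained genes.  The
    ``n_*_coordinate`` counts record direction-coordinate overlaps regardless
    of the correlation requirement, so both readings of "explained" can be
    audited side by side.
    """

    n_de_genes: int
    n_meth_overlap: int
    n_meth_explained: int
    n_cn_overlap: int
    n_cn_explained: int
    n_both_explained: int
    frac_meth: float
    frac_cn: float
    frac_union: float
    n_meth_coordinate: int = 0
    n_cn_coordinate: int = 0

    @classmethod
    def from_counts(
        cls,
        n_de_genes: int,
        n_meth_overlap: int = 0,
        n_meth_explained: int = 0,
        n_cn_overlap: int = 0,
        n_cn_explained: int = 0,
        n_both_explained: int = 0,
        n_meth_coordinate: int = 0,
        n_cn_coordinate: int = 0,
    ) -> "ContributionReport":
        """Build a report, computing fractions with a zero-denominator guard."""
        if n_de_genes > 0:
            frac_meth = n_meth_explained / n_de_genes
            frac_cn = n_cn_explained / n_de_genes
            frac_union = (n_meth_explained + n_cn_explained - n_both_explained) / n_de_genes
        else:
            frac_meth = frac_cn = frac_union = 0.0
        return cls(
            n_de_genes=n_de_genes,
            n_meth_overlap=n_meth_overlap,
            n_meth_explained=n_meth_explained,
            n_cn_overlap=n_cn_overlap,
            n_cn_explained=n_cn_explained,
            n_both_explained=n_both_explained,
            frac_meth=frac_meth,
            frac_cn=frac_cn,
            frac_union=frac_union,
            n_meth_coordinate=n_meth_coordinate,
            n_cn_coordinate=n_cn_coordinate,
        )


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one simulated gene."""

    gene_symbol: str
    gene_class: str
    expr_direction: str = "none"  # up | down | none
    meth_direction: str = "none"
    cn_direction: str = "none"

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise FormatError(f"unknown gene class {self.gene_class!r}")
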