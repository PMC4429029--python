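"""Analysis configuration shared by the differential and integration stages."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Union

import yaml

from .errors import FormatError

PathLike = Union[str, Path]


@dataclass
class AnalysisConfig:
    """Knobs of the statistical pipeline.

    alpha_fwer
        family-wise significance level for the per-feature paired tests;
        divided by the per-platform feature count under Bonferroni.
    correction
        ``bonferroni`` (discovery-style FWER control) or ``bh``
        (Benjamini-Hochberg FDR control, validation-style).
    spearman_alpha
        two-sided, uncorrected level for the expression-vs-mechanism
        Spearman correlation in the integration step.
    min_adjacent_probes
        minimum run length of consecutive significant same-direction CN
        probes for a gene-level SCNA call; at least 2.
    correlation_samples
        ``pooled`` correlates across tumor and normal samples of every pair
        (2n points); ``tumor`` restricts to tumor samples.
    """

    alpha_fwer: float = 0.05
    correction: str = "bonferroni"
    spearman_alpha: float = 0.05
    min_adjacent_probes: int = 2
    correlation_samples: str = "pooled"
    cluster_linkage: str = "average"
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_fwer < 1.0:
            raise FormatError("alpha_fwer must lie in (0, 1)")
        if not 0.0 < self.spearman_alpha < 1.0:
            raise FormatError("spearman_alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "bh"):
            raise FormatError(f"unknown correction {self.correction!r}")
        if self.min_adjacent_probes < 2:
            raise FormatError("min_adjacent_probes must be >= 2")
        if self.correlation_samples not in ("pooled", "tumor"):
            raise FormatError(f"unknown correlation_samples {self.correlation_samples!r}")

    @classmethod
    def from_file(cls, path: PathLike) -> "AnalysisConfig":
        """Load from YAML or JSON (YAML is a JSON superset)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)},
                fh,
                sort_keys=False,
            )
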