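"""Probe-to-gene collapse for methylation and the adjacent-probe SCNA rule.

Methylation: significant probes of a gene are averaged per direction; a gene
whose significant probes disagree in direction yields one aggregate per
direction, both carried forward independently.

Copy number: segmental aberrations are called with a spanning rule instead
of a segmentation algorithm -- a gene is called only where at least
``min_adjacent`` consecutive probes (in genomic order among that gene's
probes) are significant with the same sign.  Same-direction runs of one gene
merge into a single call averaged over all contributing probes;
opposite-direction runs yield separate gain and loss calls.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import NamedTuple, Sequence

import numpy as np

from .datatypes import DifferentialRecord, GeneAggregate, ProbeAnnotation, ScnaCall
from .errors import PairomicsError


class Run(NamedTuple):
    start_index: int
    length: int
    sign: int


def enumerate_runs(flags: Sequence[bool], signs: Sequence[int]) -> list[Run]:
    """Maximal runs of consecutive True flags with constant sign.

    Scans left to right; a sign change or a False flag terminates the
    current run.  Single-probe runs are returned; callers filter by length.
    """
    flags = list(flags)
    signs = list(signs)
    if len(flags) != len(signs):
        raise PairomicsError("flags and signs must have equal length")
    runs: list[Run] = []
    start = None
    cur_sign = 0
    for i, (f, s) in enumerate(zip(flags, signs)):
        if f and start is not None and s == cur_sign:
            continue
        if start is not None:
            runs.append(Run(start, i - start, cur_sign))
            start = None
        if f:
            start, cur_sign = i, s
    if start is not None:
        runs.append(Run(start, len(flags) - start, cur_sign))
    return runs


class UnmappedProbeWarning(UserWarning):
    """A significant probe had no annotation row and was excluded."""


def _gene_probe_order(
    annotations: Sequence[ProbeAnnotation], platform: str
) -> dict[str, list[ProbeAnnotation]]:
    """Per gene, that platform's probes sorted by (chromosome, start)."""
    by_gene: dict[str, list[ProbeAnnotation]] = defaultdict(list)
    for ann in annotations:
        if ann.platform == platform:
            by_gene[ann.gene_symbol].append(ann)
    for gene in by_gene:
        by_gene[gene].sort(key=lambda a: (a.chromosome, a.start, a.probe_id))
    return by_gene


def _warn_unmapped(diff: Sequence[DifferentialRecord], mapped: set[str]) -> list[str]:
    unmapped = [r.feature_id for r in diff if r.significant and r.feature_id not in mapped]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} significant probe(s) without annotation excluded: "
            f"{unmapped[:5]}{'...' if len(unmapped) > 5 else ''}",
            UnmappedProbeWarning,
            stacklevel=3,
        )
    return unmapped


def _collapse(
    diff: Sequence[DifferentialRecord],
    annotations: Sequence[ProbeAnnotation],
    platform: str,
) -> list[GeneAggregate]:
    by_gene = _gene_probe_order(annotations, platform)
    mapped = {a.probe_id for anns in by_gene.values() for a in anns}
    _warn_unmapped(diff, mapped)

    sig = {r.feature_id: r for r in diff if r.significant}
    aggregates: list[GeneAggregate] = []
    for gene in sorted(by_gene):
        groups: dict[str, list[DifferentialRecord]] = {"up": [], "down": []}
        seen: set[str] = set()
        for a in by_gene[gene]:
            if a.probe_id in sig and a.probe_id not in seen:
                seen.add(a.probe_id)
                rec = sig[a.probe_id]
                groups["up" if rec.mean_diff > 0 else "down"].append(rec)
        present = [d for d in ("up", "down") if groups[d]]
        for split_index, direction in enumerate(present):
            members = groups[direction]
            aggregates.append(
                GeneAggregate(
                    gene_symbol=gene,
                    platform=platform,
                    direction=direction,
                    n_significant_probes=len(members),
                    mean_delta=float(np.mean([r.mean_diff for r in members])),
                    probe_ids=tuple(r.feature_id for r in members),
                    split_index=split_index if len(present) > 1 else 0,
                )
            )
    return aggregates


def collapse_methylation(
    diff: Sequence[DifferentialRecord], annotations: Sequence[ProbeAnnotation]
) -> list[GeneAggregate]:
    """Collapse significant methylation probes to per-gene, per-direction means.

    Genes with no significant probe emit nothing.  When a gene has
    significant probes in both directions, two aggregates are produced
    (split_index 0 for up, 1 for down) and both travel through integration
    independently.
    """
    return _collapse(diff, annotations, "methylation")


def collapse_expression(
    diff: Sequence[DifferentialRecord], annotations: Sequence[ProbeAnnotation]
) -> list[GeneAggregate]:
    """Collapse significant transcripts to per-gene expression calls.

    Mirrors :func:`collapse_methylation` on the expression platform; genes
    whose significant transcripts disagree in direction yield one call per
    direction.
    """
    return _collapse(diff, annotations, "expression")


def call_scna(
    diff: Sequence[DifferentialRecord],
    annotations: Sequence[ProbeAnnotation],
    min_adjacent: int = 2,
) -> list[ScnaCall]:
    """Call gene-level SCNAs from runs of adjacent significant CN probes.

    Per gene, probes are ordered by genomic coordinate; maximal runs of
    consecutive significant same-sign probes are found (runs never span a
    chromosome boundary); runs shorter than ``min_adjacent`` are discarded
    -- isolated significant probes never produce a call.  Surviving
    same-direction runs merge into one call per direction, with the mean
    LRR delta taken over all contributing probes.
    """
    if min_adjacent < 2:
        raise PairomicsError("min_adjacent must be >= 2")
    by_gene = _gene_probe_order(annotations, "cnv")
    mapped = {a.probe_id for anns in by_gene.values() for a in anns}
    _warn_unmapped(diff, mapped)

    sig = {r.feature_id: r for r in diff if r.significant}
    calls: list[ScnaCall] = []
    for gene in sorted(by_gene):
        anns = by_gene[gene]
        flags = [a.probe_id in sig for a in anns]
        signs = [
            int(np.sign(sig[a.probe_id].mean_diff)) if a.probe_id in sig else 0
            for a in anns
        ]
        # adjacency never spans a chromosome boundary
        runs: list[Run] = []
        seg_start = 0
        for i in range(1, len(anns) + 1):
            if i == len(anns) or anns[i].chromosome != anns[seg_start].chromosome:
                seg_runs = enumerate_runs(flags[seg_start:i], signs[seg_start:i])
                runs.extend(Run(r.start_index + seg_start, r.length, r.sign) for r in seg_runs)
                seg_start = i
        by_dir: dict[int, list[ProbeAnnotation]] = defaultdict(list)
        for run in runs:
            if run.length >= min_adjacent:
                by_dir[run.sign].extend(anns[run.start_index : run.start_index + run.length])
        for sign in sorted(by_dir, reverse=True):
            probes = by_dir[sign]
            deltas = [sig[a.probe_id].mean_diff for a in probes]
            calls.append(
                ScnaCall(
                    gene_symbol=gene,
                    direction="gain" if sign > 0 else "loss",
                    run_probe_ids=tuple(a.probe_id for a in probes),
                    mean_lrr_delta=float(np.mean(deltas)),
                )
            )
    return calls
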