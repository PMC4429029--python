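"""Expression/methylation/copy-number integration and contribution fractions.

A differentially expressed (DE) gene is classified per mechanism:

* ``no_overlap`` -- no gene-level methylation aggregate / SCNA call;
* ``overlap_unexplained`` -- the mechanism changed but not coordinately, or
  the Spearman correlation with expression is absent or sign-inconsistent;
* ``explained_hyper_down`` / ``explained_hypo_up`` -- hypermethylated with
  down-regulation / hypomethylated with up-regulation AND a significant
  negative Spearman correlation between expression and the gene-level
  methylation signal;
* ``explained_gain_up`` / ``explained_loss_down`` -- analogous for copy
  number, requiring a significant positive correlation (dosage effect).

The cohort contribution report divides the explained counts by the number
of DE genes; the union subtracts genes explained by both mechanisms.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import defaultdict
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import scipy.stats as st

from .config import AnalysisConfig
from .datatypes import (
    ContributionReport,
    GeneAggregate,
    IntegrationRecord,
    PairedOmicsMatrix,
    ScnaCall,
)
from .errors import IntegrationError, PairomicsError

#: n at or below which the Spearman p-value is an exact permutation tail mass
EXACT_PERMUTATION_N = 7


class IntegrationWarning(UserWarning):
    """A gene with mechanism-level results could not be integrated."""


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    undefined: bool


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a small-sample exact p-value.

    rho is the Pearson correlation of average ranks.  For n <= 7 the
    two-sided p is the exact tail mass |rho_perm| >= |rho| over all n!
    permutations of one rank vector; for larger n the usual Student-t
    approximation t = rho sqrt((n-2)/(1-rho^2)) is used.  Zero rank
    variance in either vector leaves rho undefined (flagged, p = NaN).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise PairomicsError("x and y must be 1-D of equal length")
    n = xa.size
    if n < 3:
        raise PairomicsError(f"spearman needs n >= 3, got {n}")
    rx = st.rankdata(xa)
    ry = st.rankdata(ya)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return SpearmanResult(float("nan"), float("nan"), True)
    rho = _rank_rho(rx, ry)
    if n <= EXACT_PERMUTATION_N:
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= target:
                hits += 1
        p = hits / total
    else:
        r = min(max(rho, -1.0), 1.0)
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * st.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(p), False)


def overlap_genes(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[int, int, int]:
    """Venn counts (a only, both, b only) for two gene sets."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(a & b), len(b - a)


def overlap_with_reference(
    study_genes: Sequence[str], reference_genes: Iterable[str]
) -> tuple[int, float]:
    """Overlap count and percent of a study list found in a reference list.

    Percent is 100 * |study ∩ reference| / |study| rounded to one decimal;
    an empty study list yields (0, 0.0).
    """
    study = set(study_genes)
    if not study:
        return 0, 0.0
    n = len(study & set(reference_genes))
    return n, round(100.0 * n / len(study), 1)


def _signal_vector(
    matrix: PairedOmicsMatrix, feature_ids: Sequence[str], samples: str
) -> np.ndarray:
    """Mean over the given features of the per-sample values.

    ``samples='pooled'`` concatenates tumor then normal columns (2n points);
    ``'tumor'`` uses tumor columns only.
    """
    feats = [f for f in feature_ids if f in matrix.tumor.index]
    if not feats:
        raise IntegrationError(f"none of {list(feature_ids)[:3]}... in matrix")
    t = matrix.tumor.loc[feats].to_numpy(dtype=float).mean(axis=0)
    if samples == "tumor":
        return t
    n = matrix.normal.loc[feats].to_numpy(dtype=float).mean(axis=0)
    return np.concatenate([t, n])


def _classify_meth(
    expr_dir: str, agg: GeneAggregate, rho: float, p: float, alpha: float
) -> str:
    coordinate = (expr_dir == "down" and agg.direction == "up") or (
        expr_dir == "up" and agg.direction == "down"
    )
    if not coordinate:
        return "overlap_unexplained"
    if np.isfinite(rho) and rho < 0 and p < alpha:
        return "explained_hyper_down" if expr_dir == "down" else "explained_hypo_up"
    return "overlap_unexplained"


def _classify_cn(
    expr_dir: str, call: ScnaCall, rho: float, p: float, alpha: float
) -> str:
    coordinate = (expr_dir == "up" and call.direction == "gain") or (
        expr_dir == "down" and call.direction == "loss"
    )
    if not coordinate:
        return "overlap_unexplained"
    if np.isfinite(rho) and rho > 0 and p < alpha:
        return "explained_gain_up" if expr_dir == "up" else "explained_loss_down"
    return "overlap_unexplained"


_METH_RANK = {"explained_hyper_down": 0, "explained_hypo_up": 0, "overlap_unexplained": 1}
_CN_RANK = {"explained_gain_up": 0, "explained_loss_down": 0, "overlap_unexplained": 1}


def classify(
    expr_calls: Sequence[GeneAggregate],
    meth_aggregates: Sequence[GeneAggregate],
    scna_calls: Sequence[ScnaCall],
    expr_matrix: PairedOmicsMatrix,
    meth_matrix: PairedOmicsMatrix,
    cnv_matrix: PairedOmicsMatrix,
    config: AnalysisConfig,
    expression_genes: Optional[set[str]] = None,
) -> list[IntegrationRecord]:
    """Assign one starburst record per DE gene.

    Split-direction aggregates (and split expression calls) are evaluated
    once per split; the gene carries the best-qualifying combination, so a
    gene is labeled explained if any split qualifies.  Genes present in the
    methylation/SCNA results but absent from the expression matrix are
    skipped with a warning.
    """
    expr_by_gene: dict[str, list[GeneAggregate]] = defaultdict(list)
    for c in expr_calls:
        expr_by_gene[c.gene_symbol].append(c)
    meth_by_gene: dict[str, list[GeneAggregate]] = defaultdict(list)
    for a in meth_aggregates:
        meth_by_gene[a.gene_symbol].append(a)
    scna_by_gene: dict[str, list[ScnaCall]] = defaultdict(list)
    for s in scna_calls:
        scna_by_gene[s.gene_symbol].append(s)

    orphans = (set(meth_by_gene) | set(scna_by_gene)) - set(expr_by_gene)
    records: list[IntegrationRecord] = []
    samples = config.correlation_samples
    for gene in sorted(expr_by_gene):
        candidates: list[IntegrationRecord] = []
        for expr_call in expr_by_gene[gene]:
            try:
                expr_vec = _signal_vector(expr_matrix, expr_call.probe_ids or [gene], samples)
            except IntegrationError:
                warnings.warn(
                    f"gene {gene} missing from expression matrix; skipped",
                    stacklevel=2,
                )
                continue
            meth_best: tuple[int, str, Optional[str], float, float] = (
                2,
                "no_overlap",
                None,
                float("nan"),
                float("nan"),
            )
            for agg in meth_by_gene.get(gene, []):
                vec = _signal_vector(meth_matrix, agg.probe_ids, samples)
                res = spearman(expr_vec, vec)
                cat = _classify_meth(
                    expr_call.direction, agg, res.rho, res.p_value, config.spearman_alpha
                )
                key = (_METH_RANK[cat], cat, agg.direction, res.rho, res.p_value)
                if key[0] < meth_best[0]:
                    meth_best = key
            cn_best: tuple[int, str, Optional[str], float, float] = (
                2,
                "no_overlap",
                None,
                float("nan"),
                float("nan"),
            )
            for call in scna_by_gene.get(gene, []):
                vec = _signal_vector(cnv_matrix, call.run_probe_ids, samples)
                res = spearman(expr_vec, vec)
                cat = _classify_cn(
                    expr_call.direction, call, res.rho, res.p_value, config.spearman_alpha
                )
                key = (_CN_RANK[cat], cat, call.direction, res.rho, res.p_value)
                if key[0] < cn_best[0]:
                    cn_best = key
            candidates.append(
                IntegrationRecord(
                    gene_symbol=gene,
                    expr_direction=expr_call.direction,
                    meth_direction=meth_best[2],
                    cn_direction=cn_best[2],
                    rho_meth=None if math.isnan(meth_best[3]) else meth_best[3],
                    p_meth=None if math.isnan(meth_best[4]) else meth_best[4],
                    rho_cn=None if math.isnan(cn_best[3]) else cn_best[3],
                    p_cn=None if math.isnan(cn_best[4]) else cn_best[4],
                    category_meth=meth_best[1],
                    category_cn=cn_best[1],
                )
            )
        if not candidates:
            continue
        # prefer the split that explains most (explained < unexplained < none)
        def _score(r: IntegrationRecord) -> tuple[int, int]:
            return (
                _METH_RANK.get(r.category_meth, 2),
                _CN_RANK.get(r.category_cn, 2),
            )

        records.append(min(candidates, key=_score))
    # a mechanism-changed gene that is simply not DE is expected; warn only
    # when the gene is entirely unknown to the expression data
    if expression_genes is not None:
        for gene in sorted(orphans - expression_genes):
            warnings.warn(
                f"gene {gene} has mechanism-level results but is absent from "
                "the expression data; skipped",
                IntegrationWarning,
                stacklevel=2,
            )
    return records


def contribution(records: Sequence[IntegrationRecord]) -> ContributionReport:
    """Cohort-level contribution fractions from per-gene starburst records."""
    if not records:
        return ContributionReport.from_counts(0)
    n_de = len(records)
    meth_expl = {r.gene_symbol for r in records if r.category_meth.startswith("explained")}
    cn_expl = {r.gene_symbol for r in records if r.category_cn.startswith("explained")}
    meth_overlap = sum(1 for r in records if r.category_meth != "no_overlap")
    cn_overlap = sum(1 for r in records if r.category_cn != "no_overlap")
    meth_coord = sum(
        1
        for r in records
        if r.category_meth.startswith("explained")
        or (
            r.meth_direction is not None
            and (
                (r.expr_direction == "down" and r.meth_direction == "up")
                or (r.expr_direction == "up" and r.meth_direction == "down")
            )
        )
    )
    cn_coord = sum(
        1
        for r in records
        if r.category_cn.startswith("explained")
        or (
            r.cn_direction is not None
            and (
                (r.expr_direction == "up" and r.cn_direction == "gain")
                or (r.expr_direction == "down" and r.cn_direction == "loss")
            )
        )
    )
    return ContributionReport.from_counts(
        n_de_genes=n_de,
        n_meth_overlap=meth_overlap,
        n_meth_explained=len(meth_expl),
        n_cn_overlap=cn_overlap,
        n_cn_explained=len(cn_expl),
        n_both_explained=len(meth_expl & cn_expl),
        n_meth_coordinate=meth_coord,
        n_cn_coordinate=cn_coord,
    )
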