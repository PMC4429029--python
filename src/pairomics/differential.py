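"""Per-feature paired testing, multiplicity control and cluster separation.

The discovery design is paired: every tumor sample has a matched normal from
the same patient, so each feature is tested with a one-sample Student t on
the within-pair differences d = tumor - normal,

    t = mean(d) / (sd(d) / sqrt(n)),    df = n - 1,

two-sided.  Family-wise error is controlled per platform with Bonferroni
(threshold alpha / m, with m the number of features actually tested on that
platform); the validation-style alternative is Benjamini-Hochberg FDR.
Tumor/normal separability of the significant features is summarized by the
adjusted Rand index of a two-group average-linkage correlation clustering
against the true labels.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datatypes import DifferentialRecord, PairedOmicsMatrix
from .errors import InsufficientPairsError, PairomicsError


class PairedTResult(NamedTuple):
    mean_diff: float
    t_stat: float
    p_value: float
    n: int
    degenerate: bool


def paired_t_test(tumor: Sequence[float], normal: Sequence[float]) -> PairedTResult:
    """Two-sided paired Student t-test on tumor minus normal differences.

    Degenerate inputs: identically zero differences give ``t = 0, p = 1``;
    zero-variance nonzero-mean differences are reported as the ``p -> 0``
    limit with ``degenerate=True`` so callers can refuse to trust them.

    Raises
    ------
    InsufficientPairsError
        fewer than two pairs.
    PairomicsError
        length mismatch.
    """
    t_arr = np.asarray(tumor, dtype=float)
    n_arr = np.asarray(normal, dtype=float)
    if t_arr.shape != n_arr.shape or t_arr.ndim != 1:
        raise PairomicsError("tumor and normal vectors must be 1-D of equal length")
    n = t_arr.size
    if n < 2:
        raise InsufficientPairsError(f"paired t-test needs >= 2 pairs, got {n}")
    d = t_arr - n_arr
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, 0.0, 1.0, n, False)
        t = np.inf if mean > 0 else -np.inf
        return PairedTResult(mean, float(t), 0.0, n, True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * st.t.sf(abs(t), df=n - 1)
    return PairedTResult(mean, float(t), float(p), n, False)


def paired_t_matrix(
    tumor: np.ndarray, normal: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized paired t over the rows of two feature-x-pair arrays.

    NaN in either half drops that pair for that feature (complete-pairs
    analysis).  Returns ``(mean_diff, t_stat, p_value, n_complete,
    degenerate)`` arrays; rows with fewer than two complete pairs get NaN
    statistics and must be treated as untestable by the caller.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    d = tumor - normal
    ok = np.isfinite(d)
    n = ok.sum(axis=1)
    d0 = np.where(ok, d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = d0.sum(axis=1) / n
        resid = np.where(ok, d0 - mean[:, None], 0.0)
        var = (resid**2).sum(axis=1) / np.maximum(n - 1, 1)
        sd = np.sqrt(var)
        se = sd / np.sqrt(n)
        t = mean / se
    testable = n >= 2
    zero_sd = testable & (sd == 0.0)
    degenerate = zero_sd & (mean != 0.0)
    t = np.where(zero_sd & (mean == 0.0), 0.0, t)
    t = np.where(degenerate, np.sign(mean) * np.inf, t)
    p = np.full(t.shape, np.nan)
    finite = testable & np.isfinite(t)
    p[finite] = 2.0 * st.t.sf(np.abs(t[finite]), df=n[finite] - 1)
    p[zero_sd & (mean == 0.0)] = 1.0
    p[degenerate] = 0.0
    mean = np.where(testable, mean, np.nan)
    t = np.where(testable, t, np.nan)
    p = np.where(testable, p, np.nan)
    return mean, t, p, n, degenerate


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test p-value threshold alpha / m controlling FWER at alpha."""
    if not 0.0 < alpha < 1.0:
        raise PairomicsError("alpha must lie in (0, 1)")
    if m < 1:
        raise PairomicsError("m must be >= 1")
    return alpha / m


def bh_fdr(p_values: Sequence[float], alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level alpha.

    Rejects the k smallest p-values, where k is the largest i with
    p_(i) <= i * alpha / m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise PairomicsError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def run_differential(
    matrix: PairedOmicsMatrix, config: AnalysisConfig
) -> list[DifferentialRecord]:
    """Test every feature of one platform and call significance.

    Under Bonferroni, the threshold is ``alpha_fwer / m`` where m counts the
    features actually tested (features left with fewer than two complete
    pairs are flagged untestable and excluded from m).
    """
    features = matrix.feature_ids
    if not features:
        return []
    mean, t, p, n, degen = paired_t_matrix(
        matrix.tumor.to_numpy(), matrix.normal.to_numpy()
    )
    testable = n >= 2
    m = int(testable.sum())

    significant = np.zeros(len(features), dtype=bool)
    if m > 0:
        if config.correction == "bonferroni":
            threshold = bonferroni_threshold(config.alpha_fwer, m)
            thresholds = np.full(len(features), threshold)
            significant[testable] = p[testable] < threshold
        else:
            reject = bh_fdr(p[testable], config.alpha_fwer)
            significant[np.flatnonzero(testable)] = reject
            k = int(reject.sum())
            thresholds = np.full(len(features), k * config.alpha_fwer / m)
    else:
        thresholds = np.full(len(features), np.nan)

    records = []
    for i, fid in enumerate(features):
        sig = bool(significant[i])
        if not testable[i]:
            direction = "none"
        elif sig and mean[i] > 0:
            direction = "up"
        elif sig and mean[i] < 0:
            direction = "down"
        else:
            direction = "none"
        records.append(
            DifferentialRecord(
                feature_id=str(fid),
                n_complete_pairs=int(n[i]),
                mean_diff=float(mean[i]),
                t_stat=float(t[i]),
                p_value=float(p[i]),
                direction=direction,
                significant=sig,
                threshold_used=float(thresholds[i]),
                degenerate=bool(degen[i]),
                untestable=not bool(testable[i]),
            )
        )
    return records


def cluster_separation(
    matrix: PairedOmicsMatrix,
    significant_features: Sequence[str],
    linkage: str = "average",
) -> float:
    """Adjusted Rand index of a 2-cluster cut against tumor/normal labels.

    Stacks the tumor and normal samples as 2n observations over the
    significant features, clusters them by average linkage on
    1 - Pearson correlation of sample profiles, cuts at two clusters and
    scores agreement with the true labels (1 = perfect separation,
    about 0 = random).
    """
    feats = list(significant_features)
    if len(feats) < 2:
        raise PairomicsError("cluster separation needs >= 2 significant features")
    if matrix.n_pairs < 2:
        raise PairomicsError("cluster separation needs >= 2 samples per group")
    sub = matrix.subset_features(feats)
    X = np.vstack([sub.tumor.to_numpy().T, sub.normal.to_numpy().T])
    if not np.isfinite(X).all():
        raise PairomicsError("cluster separation requires complete data")
    sds = X.std(axis=1)
    if np.any(sds == 0):
        raise PairomicsError("a sample profile has zero variance; correlation undefined")
    dist = 1.0 - np.corrcoef(X)
    np.fill_diagonal(dist, 0.0)
    # tiny negative entries from float error
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = sch.linkage(squareform(dist, checks=False), method=linkage)
    assignments = sch.fcluster(Z, t=2, criterion="maxclust")
    labels = np.array([1] * sub.n_pairs + [0] * sub.n_pairs)
    return float(adjusted_rand_score(labels, assignments))
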