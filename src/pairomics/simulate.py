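"""Synthetic paired tumor/normal three-platform datasets with planted truth.

The generator emulates the structure of a discovery cohort of 30 tumor /
matched-normal pairs profiled on three array platforms: one expression
transcript per gene, 5-50 methylation probes and 5-40 SNP/CN probes per
gene, laid out consecutively on synthetic chromosomes so probe adjacency is
well defined.  Each gene is planted into one of five classes:

``null``
    no tumor/normal difference on any platform.
``expr_only``
    expression shifted by +-delta_expr_only; methylation and copy number
    null (a stand-in for regulation by mechanisms outside the assay, e.g.
    transcription factors or non-coding RNAs).
``meth_driven``
    tumor methylation probes shifted by +-delta_meth; expression responds
    with beta_meth * (signed shift), beta_meth <= 0 (inverse coupling).
``cn_driven``
    a contiguous run of the gene's CN probes shifted by +-delta_lrr;
    expression responds with gamma_cn * (signed shift), gamma_cn >= 0
    (dosage effect).
``dual``
    both mechanisms, with signs chosen coherently (hypermethylated and
    deleted genes go down; hypomethylated and amplified genes go up) so the
    two drivers reinforce rather than cancel.

Within-pair correlation is induced by a per-probe, per-pair latent baseline
shared between the tumor and normal halves; with noise SD sigma and
baseline SD tau = sigma * sqrt(rho / (1 - rho)) the tumor/normal values of
a pair correlate at rho_pair under the null.

Randomness is hierarchical: the global seed spawns one independent
substream per gene, so enlarging ``n_genes`` never perturbs the draws of
earlier genes.  The same config (including seed) is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    GENE_CLASSES,
    PairedOmicsMatrix,
    ProbeAnnotation,
    TruthRecord,
)
from .errors import FormatError

PathLike = Union[str, Path]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the discovery design: 30 pairs, ~1,000 genes, one
    transcript plus 5-50 methylation and 5-40 CN probes per gene.  Effect
    sizes (delta_meth 0.8 score units, delta_lrr 0.5, couplings -1.0 and
    +1.5 log2 units, delta_expr_only 1.0 log2) are arbitrary but sized for
    essentially full per-feature power at n = 30 under the platform noise
    SDs (0.5 / 0.3 / 0.2).
    """

    n_pairs: int = 30
    n_genes: int = 1000
    class_fractions: dict = field(
        default_factory=lambda: {
            "null": 0.50,
            "expr_only": 0.30,
            "meth_driven": 0.08,
            "cn_driven": 0.10,
            "dual": 0.02,
        }
    )
    probes_per_gene_meth: tuple[int, int] = (5, 50)
    probes_per_gene_cnv: tuple[int, int] = (5, 40)
    delta_meth: float = 0.8
    delta_lrr: float = 0.5
    beta_meth: float = -1.0
    gamma_cn: float = 1.5
    delta_expr_only: float = 1.0
    sigma_expr: float = 0.5
    sigma_meth: float = 0.3
    sigma_lrr: float = 0.2
    rho_pair: float = 0.5
    frac_probes_affected: float = 1.0
    n_artifact_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise FormatError("n_pairs must be >= 2")
        if self.n_genes < 1:
            raise FormatError("n_genes must be >= 1")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise FormatError(f"unknown gene classes {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise FormatError(f"class_fractions must sum to 1, got {total}")
        for name in ("sigma_expr", "sigma_meth", "sigma_lrr"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be > 0")
        for name in ("probes_per_gene_meth", "probes_per_gene_cnv"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise FormatError(f"{name} range empty or invalid")
        if not 0.0 <= self.rho_pair < 1.0:
            raise FormatError("rho_pair must lie in [0, 1)")
        if not 0.0 < self.frac_probes_affected <= 1.0:
            raise FormatError("frac_probes_affected must lie in (0, 1]")
        if self.beta_meth > 0:
            raise FormatError("beta_meth must be <= 0 (inverse coupling)")
        if self.gamma_cn < 0:
            raise FormatError("gamma_cn must be >= 0 (dosage effect)")

    @classmethod
    def from_file(cls, path: PathLike) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        for name in ("probes_per_gene_meth", "probes_per_gene_cnv"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`generate_dataset`."""

    expression: PairedOmicsMatrix
    methylation: PairedOmicsMatrix
    cnv: PairedOmicsMatrix
    annotations: list[ProbeAnnotation]
    truth: list[TruthRecord]


def _paired_block(
    rng: np.random.Generator,
    n_probes: int,
    n_pairs: int,
    baseline_mean: float,
    sigma: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated tumor/normal halves for one gene on one platform.

    Returns (tumor, normal), each n_probes x n_pairs, before any planted
    tumor shift.
    """
    tau = sigma * math.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    baseline = baseline_mean + tau * rng.standard_normal((n_probes, n_pairs))
    tumor = baseline + sigma * rng.standard_normal((n_probes, n_pairs))
    normal = baseline + sigma * rng.standard_normal((n_probes, n_pairs))
    return tumor, normal


def _contiguous_run(rng: np.random.Generator, n: int, frac: float) -> slice:
    """A random contiguous slice covering ceil(frac * n) probes."""
    length = max(1, math.ceil(frac * n))
    start = int(rng.integers(0, n - length + 1))
    return slice(start, start + length)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one synthetic cohort; pure function of the config."""
    n_classes = len(GENE_CLASSES)
    ss = np.random.SeedSequence(config.seed)
    gene_seeds = ss.spawn(config.n_genes)
    pair_ids = [f"p{i + 1:02d}" for i in range(config.n_pairs)]

    probs = np.array([config.class_fractions.get(c, 0.0) for c in GENE_CLASSES])
    probs = probs / probs.sum()

    expr_t, expr_n, expr_ids = [], [], []
    meth_t, meth_n, meth_ids = [], [], []
    cnv_t, cnv_n, cnv_ids = [], [], []
    annotations: list[ProbeAnnotation] = []
    truth: list[TruthRecord] = []

    # single-probe CN artifacts are planted into the first n_artifact_genes
    # genes that come out null
    artifacts_left = config.n_artifact_genes

    for g in range(config.n_genes):
        rng = np.random.default_rng(gene_seeds[g])
        gene = f"G{g + 1:04d}"
        chrom = f"chr{(g % 22) + 1}"
        offset = (g // 22) * 1_000_000  # genes on one chromosome never interleave

        gene_class = GENE_CLASSES[int(rng.choice(n_classes, p=probs))]
        n_mp = int(rng.integers(config.probes_per_gene_meth[0], config.probes_per_gene_meth[1] + 1))
        n_cp = int(rng.integers(config.probes_per_gene_cnv[0], config.probes_per_gene_cnv[1] + 1))

        expr_mu = float(rng.normal(8.0, 2.0))
        meth_mu = float(rng.normal(0.0, 1.0))

        et, en = _paired_block(rng, 1, config.n_pairs, expr_mu, config.sigma_expr, config.rho_pair)
        mt, mn = _paired_block(rng, n_mp, config.n_pairs, meth_mu, config.sigma_meth, config.rho_pair)
        ct, cn = _paired_block(rng, n_cp, config.n_pairs, 0.0, config.sigma_lrr, config.rho_pair)

        expr_shift = 0.0
        meth_sign = 0
        cn_sign = 0
        if gene_class == "expr_only":
            expr_shift = config.delta_expr_only * (1 if rng.random() < 0.5 else -1)
        elif gene_class == "meth_driven":
            meth_sign = 1 if rng.random() < 0.5 else -1
            expr_shift = config.beta_meth * meth_sign * config.delta_meth
        elif gene_class == "cn_driven":
            cn_sign = 1 if rng.random() < 0.5 else -1
            expr_shift = config.gamma_cn * cn_sign * config.delta_lrr
        elif gene_class == "dual":
            # coherent signs: both mechanisms push expression the same way
            expr_sign = 1 if rng.random() < 0.5 else -1
            meth_sign = -expr_sign if config.beta_meth < 0 else expr_sign
            cn_sign = expr_sign
            expr_shift = (
                config.beta_meth * meth_sign * config.delta_meth
                + config.gamma_cn * cn_sign * config.delta_lrr
            )

        if meth_sign != 0:
            run = _contiguous_run(rng, n_mp, config.frac_probes_affected)
            mt[run, :] += meth_sign * config.delta_meth
        if cn_sign != 0:
            run = _contiguous_run(rng, n_cp, config.frac_probes_affected)
            ct[run, :] += cn_sign * config.delta_lrr
        et += expr_shift

        if gene_class == "null" and artifacts_left > 0:
            # one isolated probe carries a full-size LRR shift; the
            # adjacent-probe rule must never call these
            idx = int(rng.integers(0, n_cp))
            ct[idx, :] += config.delta_lrr * (1 if rng.random() < 0.5 else -1)
            artifacts_left -= 1

        expr_id = f"{gene}_tx1"
        expr_ids.append(expr_id)
        expr_t.append(et[0])
        expr_n.append(en[0])
        annotations.append(
            ProbeAnnotation(
                probe_id=expr_id,
                platform="expression",
                chromosome=chrom,
                start=offset,
                end=offset + 10_000,
                strand="+",
                gene_symbol=gene,
            )
        )
        for j in range(n_mp):
            pid = f"{gene}_m{j + 1:03d}"
            meth_ids.append(pid)
            annotations.append(
                ProbeAnnotation(
                    probe_id=pid,
                    platform="methylation",
                    chromosome=chrom,
                    start=offset + j * 100,
                    end=offset + j * 100 + 50,
                    strand=".",
                    gene_symbol=gene,
                )
            )
        meth_t.append(mt)
        meth_n.append(mn)
        for j in range(n_cp):
            pid = f"{gene}_c{j + 1:03d}"
            cnv_ids.append(pid)
            annotations.append(
                ProbeAnnotation(
                    probe_id=pid,
                    platform="cnv",
                    chromosome=chrom,
                    start=offset + j * 200,
                    end=offset + j * 200 + 1,
                    strand=".",
                    gene_symbol=gene,
                )
            )
        cnv_t.append(ct)
        cnv_n.append(cn)

        def _dir(sign: int) -> str:
            return "up" if sign > 0 else ("down" if sign < 0 else "none")

        truth.append(
            TruthRecord(
                gene_symbol=gene,
                gene_class=gene_class,
                expr_direction="none"
                if expr_shift == 0.0
                else ("up" if expr_shift > 0 else "down"),
                meth_direction=_dir(meth_sign),
                cn_direction=_dir(cn_sign),
            )
        )

    def _matrix(platform: str, ids: list[str], t_blocks, n_blocks) -> PairedOmicsMatrix:
        t = np.vstack([np.atleast_2d(b) for b in t_blocks])
        n = np.vstack([np.atleast_2d(b) for b in n_blocks])
        return PairedOmicsMatrix(
            platform=platform,
            tumor=pd.DataFrame(t, index=ids, columns=pair_ids),
            normal=pd.DataFrame(n, index=ids, columns=pair_ids),
        )

    return SyntheticDataset(
        expression=_matrix("expression", expr_ids, expr_t, expr_n),
        methylation=_matrix("methylation", meth_ids, meth_t, meth_n),
        cnv=_matrix("cnv", cnv_ids, cnv_t, cnv_n),
        annotations=annotations,
        truth=truth,
    )


def generate_null_matrix(
    platform: str,
    n_features: int,
    n_pairs: int,
    sigma: float,
    rho_pair: float,
    seed: int,
) -> PairedOmicsMatrix:
    """All-null paired matrix for error-rate studies.

    Every feature's tumor and normal values share a latent per-pair
    baseline (within-pair correlation ``rho_pair``) and have no systematic
    tumor/normal difference, so any significant call downstream is a false
    positive.
    """
    rng = np.random.default_rng(seed)
    tumor, normal = _paired_block(rng, n_features, n_pairs, 0.0, sigma, rho_pair)
    ids = [f"f{i + 1:05d}" for i in range(n_features)]
    pairs = [f"p{i + 1:02d}" for i in range(n_pairs)]
    return PairedOmicsMatrix(
        platform=platform,
        tumor=pd.DataFrame(tumor, index=ids, columns=pairs),
        normal=pd.DataFrame(normal, index=ids, columns=pairs),
    )


def truth_explained_fractions(truth: list[TruthRecord]) -> dict:
    """Planted-truth attribution fractions, the oracle for the pipeline.

    Among genes with a planted expression change, the fraction driven by
    methylation (meth_driven or dual), by copy number (cn_driven or dual),
    and by either mechanism (union).  With no expressed genes the
    fractions are 0 and ``n_expressed`` is 0 so callers can detect the
    empty denominator.
    """
    if not truth:
        raise FormatError("truth table is empty")
    expressed = [t for t in truth if t.expr_direction != "none"]
    n = len(expressed)
    if n == 0:
        return {"meth": 0.0, "cn": 0.0, "union": 0.0, "n_expressed": 0}
    n_meth = sum(1 for t in expressed if t.gene_class in ("meth_driven", "dual"))
    n_cn = sum(1 for t in expressed if t.gene_class in ("cn_driven", "dual"))
    n_union = sum(
        1 for t in expressed if t.gene_class in ("meth_driven", "cn_driven", "dual")
    )
    return {
        "meth": n_meth / n,
        "cn": n_cn / n,
        "union": n_union / n,
        "n_expressed": n,
    }
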