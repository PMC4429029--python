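import itertools
import math

import numpy as np
import pytest
import scipy.stats as st

from pairomics import (
    AnalysisConfig,
    ContributionReport,
    GeneAggregate,
    ScnaCall,
    classify,
    contribution,
    overlap_genes,
    overlap_with_reference,
    spearman,
)
from pairomics.datatypes import IntegrationRecord
from pairomics.errors import PairomicsError

from conftest import make_matrix


def exact_perm_p(x, y):
    """Exhaustive two-sided permutation oracle for the Spearman p-value."""
    rx, ry = st.rankdata(x), st.rankdata(y)

    def r(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b) / math.sqrt(float(a @ a) * float(b @ b))

    obs = abs(r(rx, ry))
    hits = sum(
        1
        for p in itertools.permutations(ry)
        if abs(r(rx, np.array(p))) >= obs - 1e-12
    )
    return math.factorial(len(y)), hits


class TestSpearman:
    def test_monotone_increasing(self):
        res = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        res = spearman([1, 2, 3], [3, 2, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_two_adjacent_swaps(self):
        # sum of squared rank differences = 4 -> rho = 1 - 24/120 = 0.8;
        # exact two-sided permutation tail mass is 16/120
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.rho == pytest.approx(0.8)
        total, hits = exact_perm_p([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.p_value == pytest.approx(hits / total)
        assert res.p_value == pytest.approx(16 / 120)

    def test_exact_p_matches_oracle_small_n(self):
        rng = np.random.default_rng(13)
        for n in (3, 4, 5, 6):
            for _ in range(8):
                x = rng.standard_normal(n)
                y = rng.standard_normal(n)
                res = spearman(x, y)
                total, hits = exact_perm_p(x, y)
                assert res.p_value == pytest.approx(hits / total), (x, y)

    def test_rho_matches_scipy_with_ties(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            n = int(rng.integers(8, 30))
            x = rng.integers(0, 5, size=n).astype(float)
            y = x + rng.integers(0, 3, size=n)
            ref = st.spearmanr(x, y)
            if np.isnan(ref.statistic):
                continue
            res = spearman(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(PairomicsError):
            spearman([1, 2], [2, 1])

    def test_constant_vector_flagged_undefined(self):
        res = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert res.undefined and math.isnan(res.rho)


class TestOverlaps:
    def test_venn_counts(self):
        assert overlap_genes({"g1", "g2"}, {"g2", "g3"}) == (1, 1, 1)

    def test_identical_sets(self):
        genes = {"a", "b", "c"}
        assert overlap_genes(genes, genes) == (0, 3, 0)

    def test_matches_membership_scan(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(50)]
        for _ in range(20):
            a = {g for g in universe if rng.random() < 0.4}
            b = {g for g in universe if rng.random() < 0.4}
            n_a, n_ab, n_b = overlap_genes(a, b)
            assert n_ab == sum(1 for g in a if g in b)
            assert n_a == sum(1 for g in a if g not in b)
            assert n_b == sum(1 for g in b if g not in a)

    def test_reference_overlap_percent(self):
        study = [f"g{i}" for i in range(252)]
        reference = study[:200] + ["other1", "other2"]
        assert overlap_with_reference(study, reference) == (200, 79.4)

    def test_disjoint_and_superset(self):
        assert overlap_with_reference(["a"], ["b"]) == (0, 0.0)
        assert overlap_with_reference(["a", "b"], ["a", "b", "c"]) == (2, 100.0)

    def test_empty_study(self):
        assert overlap_with_reference([], ["a"]) == (0, 0.0)


def _paired_samples(n_pairs, shift, rng, sigma=0.3, rho=0.5):
    tau = sigma * math.sqrt(rho / (1 - rho))
    base = tau * rng.standard_normal(n_pairs)
    tumor = base + shift + sigma * rng.standard_normal(n_pairs)
    normal = base + sigma * rng.standard_normal(n_pairs)
    return tumor, normal


def _scenario(meth_shift, expr_shift, n_pairs=30, seed=0):
    """One gene with an expression transcript and one methylation probe."""
    rng = np.random.default_rng(seed)
    et, en = _paired_samples(n_pairs, 0.0, rng, sigma=0.4)
    mt, mn = _paired_samples(n_pairs, meth_shift, rng)
    # couple expression to the methylation signal so Spearman sees it
    et = et + expr_shift / max(abs(meth_shift), 1e-9) * (mt - mt.mean() + meth_shift)
    expr = make_matrix("expression", et, en, features=["GENE1_tx"])
    meth = make_matrix("methylation", mt, mn, features=["GENE1_m1"])
    cnv = make_matrix(
        "cnv", rng.standard_normal((2, n_pairs)) * 0.2,
        rng.standard_normal((2, n_pairs)) * 0.2,
        features=["GENE1_c1", "GENE1_c2"],
    )
    return expr, meth, cnv


def _expr_call(direction, mean=1.0):
    return GeneAggregate(
        gene_symbol="GENE1",
        platform="expression",
        direction=direction,
        n_significant_probes=1,
        mean_delta=mean if direction == "up" else -mean,
        probe_ids=("GENE1_tx",),
    )


def _meth_agg(direction, mean=0.8, split=0):
    return GeneAggregate(
        gene_symbol="GENE1",
        platform="methylation",
        direction=direction,
        n_significant_probes=1,
        mean_delta=mean if direction == "up" else -mean,
        probe_ids=("GENE1_m1",),
        split_index=split,
    )


class TestClassify:
    def test_hypermethylated_down_regulated_is_explained(self):
        expr, meth, cnv = _scenario(meth_shift=0.8, expr_shift=-1.0, seed=3)
        recs = classify(
            [_expr_call("down")], [_meth_agg("up")], [], expr, meth, cnv,
            AnalysisConfig(),
        )
        (rec,) = recs
        assert rec.category_meth == "explained_hyper_down"
        assert rec.rho_meth < 0 and rec.p_meth < 0.05
        assert rec.category_cn == "no_overlap"

    def test_concordant_directions_never_explained(self):
        expr, meth, cnv = _scenario(meth_shift=0.8, expr_shift=1.0, seed=4)
        (rec,) = classify(
            [_expr_call("up")], [_meth_agg("up")], [], expr, meth, cnv,
            AnalysisConfig(),
        )
        assert rec.category_meth == "overlap_unexplained"

    def test_coordinate_but_uncorrelated_is_unexplained(self):
        # methylation changed, directions coordinate, but expression is
        # independent noise: the Spearman gate must fail
        rng = np.random.default_rng(9)
        expr = make_matrix(
            "expression", rng.standard_normal(30), rng.standard_normal(30),
            features=["GENE1_tx"],
        )
        mt, mn = _paired_samples(30, 0.8, rng)
        meth = make_matrix("methylation", mt, mn, features=["GENE1_m1"])
        cnv = make_matrix(
            "cnv", rng.standard_normal((2, 30)), rng.standard_normal((2, 30)),
            features=["GENE1_c1", "GENE1_c2"],
        )
        (rec,) = classify(
            [_expr_call("down")], [_meth_agg("up")], [], expr, meth, cnv,
            AnalysisConfig(),
        )
        assert rec.category_meth == "overlap_unexplained"

    def test_gene_without_mechanism_results_is_no_overlap(self):
        expr, meth, cnv = _scenario(0.8, -1.0, seed=5)
        (rec,) = classify([_expr_call("down")], [], [], expr, meth, cnv, AnalysisConfig())
        assert rec.category_meth == "no_overlap" and rec.category_cn == "no_overlap"

    def test_fyn_style_split_gene_explained_if_any_split_qualifies(self):
        # two opposite-direction methylation aggregates; only the "up"
        # split is anti-correlated with the down-regulated expression
        expr, meth, cnv = _scenario(meth_shift=0.8, expr_shift=-1.0, seed=6)
        aggs = [_meth_agg("up", split=0), _meth_agg("down", split=1)]
        (rec,) = classify([_expr_call("down")], aggs, [], expr, meth, cnv, AnalysisConfig())
        assert rec.category_meth == "explained_hyper_down"

    def test_cn_gain_up_explained(self):
        rng = np.random.default_rng(12)
        ct, cn_ = _paired_samples(30, 0.5, rng, sigma=0.2)
        et, en = _paired_samples(30, 0.0, rng, sigma=0.3)
        et = et + 1.5 * (ct - ct.mean() + 0.5)
        expr = make_matrix("expression", et, en, features=["GENE1_tx"])
        meth = make_matrix(
            "methylation", rng.standard_normal(30), rng.standard_normal(30),
            features=["GENE1_m1"],
        )
        cnv = make_matrix("cnv", ct, cn_, features=["GENE1_c1"])
        call = ScnaCall("GENE1", "gain", ("GENE1_c1",), 0.5)
        (rec,) = classify([_expr_call("up")], [], [call], expr, meth, cnv, AnalysisConfig())
        assert rec.category_cn == "explained_gain_up"
        assert rec.rho_cn > 0 and rec.p_cn < 0.05


class TestContribution:
    def test_discovery_cohort_arithmetic(self):
        r = ContributionReport.from_counts(
            252, n_meth_explained=11, n_cn_explained=56, n_both_explained=5
        )
        assert r.frac_meth == pytest.approx(11 / 252)
        assert r.frac_union == pytest.approx(62 / 252)
        assert round(r.frac_union, 4) == 0.2460

    def test_no_explained_genes(self):
        recs = [
            IntegrationRecord(gene_symbol=f"g{i}", expr_direction="up")
            for i in range(5)
        ]
        r = contribution(recs)
        assert r.n_de_genes == 5
        assert r.frac_meth == r.frac_cn == r.frac_union == 0.0

    def test_all_meth_explained(self):
        recs = [
            IntegrationRecord(
                gene_symbol=f"g{i}",
                expr_direction="down",
                meth_direction="up",
                rho_meth=-0.9,
                p_meth=1e-4,
                category_meth="explained_hyper_down",
            )
            for i in range(4)
        ]
        r = contribution(recs)
        assert r.frac_meth == 1.0 and r.frac_union == 1.0 and r.frac_cn == 0.0

    def test_empty_records(self):
        r = contribution([])
        assert r.n_de_genes == 0 and r.frac_union == 0.0

    def test_union_bounds(self):
        rng = np.random.default_rng(31)
        cats_m = ["explained_hyper_down", "overlap_unexplained", "no_overlap"]
        cats_c = ["explained_gain_up", "overlap_unexplained", "no_overlap"]
        for _ in range(20):
            recs = [
                IntegrationRecord(
                    gene_symbol=f"g{i}",
                    expr_direction="up",
                    category_meth=str(rng.choice(cats_m)),
                    category_cn=str(rng.choice(cats_c)),
                )
                for i in range(30)
            ]
            r = contribution(recs)
            assert 0.0 <= r.frac_union <= min(1.0, r.frac_meth + r.frac_cn)
            assert r.frac_union >= max(r.frac_meth, r.frac_cn) - 1e-12
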