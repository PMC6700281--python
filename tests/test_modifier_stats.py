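"""HWE enrichment, association models and the tag-SNP rule engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from httrepeat import modifier_stats as ms


class TestHweExpectedCounts:
    def test_study_worked_example(self):
        exp = ms.hwe_expected_counts(1753, 0.257)
        assert exp == pytest.approx([967.8, 669.5, 115.8], abs=0.1)
        assert tuple(int(round(e)) for e in exp) == (968, 669, 116)

    def test_low_maf_limit(self):
        exp = ms.hwe_expected_counts(1000, 1e-9)
        assert exp[0] == pytest.approx(1000)
        assert exp[1] == pytest.approx(0, abs=1e-5)

    @given(st.integers(1, 10000), st.floats(0.01, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_counts_sum_to_n(self, n, maf):
        assert ms.hwe_expected_counts(n, maf).sum() == pytest.approx(n)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ms.hwe_expected_counts(100, 0.0)
        with pytest.raises(ValueError):
            ms.hwe_expected_counts(0, 0.2)


class TestHweChisq:
    def test_study_worked_example(self):
        obs = ms.GenotypeCounts(915, 684, 154)
        res = ms.hwe_chisq(obs, ms.hwe_expected_counts(1753, 0.257))
        assert res.statistic == pytest.approx(15.80, abs=0.01)
        assert res.df == 2
        assert res.p < 0.0004

    def test_observed_equals_expected_is_zero(self):
        res = ms.hwe_chisq(ms.GenotypeCounts(25, 50, 25),
                           np.array([25.0, 50.0, 25.0]))
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_summed_oracle(self):
        # (10, 20, 10) vs HWE at q = 0.5, n = 40 -> expected (10, 20, 10)
        # shift to q = 0.4: expected (14.4, 19.2, 6.4)
        exp = ms.hwe_expected_counts(40, 0.4)
        by_hand = ((10 - 14.4) ** 2 / 14.4 + (20 - 19.2) ** 2 / 19.2
                   + (10 - 6.4) ** 2 / 6.4)
        res = ms.hwe_chisq(ms.GenotypeCounts(10, 20, 10), exp)
        assert res.statistic == pytest.approx(by_hand)

    @given(
        st.tuples(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)),
        st.floats(0.05, 0.5),
    )
    @settings(max_examples=500, deadline=None)
    def test_matches_independent_oracle_on_random_tables(self, counts, maf):
        n = sum(counts)
        if n == 0:
            return
        exp = ms.hwe_expected_counts(n, maf)
        res = ms.hwe_chisq(ms.GenotypeCounts(*counts), exp)
        oracle = sum((o - e) ** 2 / e for o, e in zip(counts, exp))
        assert res.statistic == pytest.approx(oracle)
        assert res.p == pytest.approx(float(sps.chi2.sf(oracle, 2)))

    def test_zero_expected_class_rejected(self):
        with pytest.raises(ValueError):
            ms.hwe_chisq(ms.GenotypeCounts(1, 1, 1), [1.0, 1.0, 0.0])


class TestAssociation:
    def test_reduces_to_simple_regression_without_covariates(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, 200).astype(float)
        y = -1.5 * d + rng.normal(0, 2, 200)
        res = ms.marginal_association(d, y)
        lr = sps.linregress(d, y)
        assert res.beta == pytest.approx(lr.slope)
        assert res.p == pytest.approx(lr.pvalue)

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError):
            ms.marginal_association(np.ones(50), np.random.default_rng(0).normal(size=50))

    def test_covariate_adjustment_removes_confounding(self):
        rng = np.random.default_rng(4)
        sex = rng.integers(0, 2, 2000).astype(float)
        d = rng.binomial(1, 0.2 + 0.4 * sex).astype(float)
        y = 3.0 * sex + rng.normal(0, 1, 2000)  # no direct dosage effect
        raw = ms.marginal_association(d, y)
        adj = ms.marginal_association(d, y, covariates=sex.reshape(-1, 1))
        assert abs(adj.beta) < abs(raw.beta)
        assert adj.p > 0.01

    def test_conditioning_on_causal_snp_removes_ld_signal(self):
        rng = np.random.default_rng(5)
        removed = 0
        for _ in range(100):
            causal = rng.binomial(2, 0.3, 1500).astype(float)
            # tightly linked proxy: copy with 5% allele flips
            flips = rng.binomial(1, 0.05, 1500)
            proxy = np.clip(causal + flips * rng.choice([-1, 1], 1500), 0, 2)
            y = -2.0 * causal + rng.normal(0, 3, 1500)
            assert ms.marginal_association(proxy, y).p < 1e-4
            cond = ms.conditional_association(
                proxy, y, conditioning=causal.reshape(-1, 1)
            )
            if cond.p > 0.05:
                removed += 1
        # conditional p is null-distributed, so ~95 of 100 replicates clear 0.05
        assert removed >= 90

    def test_conditioning_on_independent_snp_leaves_beta(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.3, 2000).astype(float)
        other = rng.binomial(2, 0.4, 2000).astype(float)
        y = -1.0 * d + rng.normal(0, 3, 2000)
        marg = ms.marginal_association(d, y)
        cond = ms.conditional_association(d, y, conditioning=other.reshape(-1, 1))
        assert abs(cond.beta - marg.beta) < 2 * marg.se

    def test_empty_conditioning_equals_marginal(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.3, 300).astype(float)
        y = rng.normal(0, 1, 300)
        assert ms.conditional_association(d, y) == ms.marginal_association(d, y)

    def test_perfect_collinearity_diagnosed(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.3, 100).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            ms.conditional_association(
                d, rng.normal(size=100), conditioning=d.reshape(-1, 1)
            )


def snp(name, maf, effect, p_marg, cond):
    return ms.SnpStats(
        snp=name, maf=maf, effect=effect,
        direction="hastening" if effect < 0 else "delaying",
        p_marginal=p_marg, p_conditional=cond,
    )


class TestTagRules:
    def test_5am1_example(self):
        s = snp("x", 0.25, -0.8, 1e-6, {"rs701383": 0.01})
        assert ms.classify_tag_snps([s])["x"] == "5AM1"

    def test_5am2_example(self):
        s = snp("x", 0.02, 6.0, 5e-4, {"rs701383": 5e-4})
        assert ms.classify_tag_snps([s])["x"] == "5AM2"

    def test_5am3_window(self):
        s = snp("x", 0.33, 0.6, 1e-4, {"rs701383": 0.05})
        assert ms.classify_tag_snps([s])["x"] == "5AM3"

    def test_marginal_boundary_is_strict(self):
        s = snp("x", 0.25, -0.8, 1e-5, {"rs701383": 0.01})
        assert ms.classify_tag_snps([s])["x"] is None

    @pytest.mark.parametrize(
        "maf,effect,p_marg,cond,label",
        [
            (0.014, -5.2, 1e-28, {"rs150393409": 1.0, "rs35811129": 1e-16}, "15AM1"),
            (0.275, 1.3, 1e-25, {"rs150393409": 1e-25, "rs35811129": 0.9}, "15AM2"),
            (0.007, -3.8, 1e-8, {"rs150393409": 1e-8, "rs35811129": 1e-8}, "15AM3"),
            (0.382, 0.8, 1e-10, {"rs150393409": 1e-10}, "15AM4"),
            (0.167, 0.9, 1e-9, {"rs274883": 0.5}, "19AM1"),
            (0.371, -0.6, 1e-6, {"rs3730945": 0.5}, "19AM2"),
            (0.001, 7.7, 1e-6, {"rs145821638": 0.5}, "19AM3"),
        ],
    )
    def test_locus_rule_sets(self, maf, effect, p_marg, cond, label):
        s = snp("x", maf, effect, p_marg, cond)
        assert ms.classify_tag_snps([s])["x"] == label

    def test_missing_conditional_p_skips_with_warning(self):
        s = snp("x", 0.25, -0.8, 1e-6, {})
        with pytest.warns(UserWarning, match="missing conditional"):
            labels = ms.classify_tag_snps([s])
        assert labels["x"] is None

    def test_engine_is_total_and_order_stable(self):
        stats = [
            snp("a", 0.25, -0.8, 1e-6, {"rs701383": 0.01}),
            snp("b", 0.4, 0.1, 0.5, {"rs701383": 0.5, "rs274883": 0.5,
                                     "rs150393409": 0.5, "rs35811129": 0.5,
                                     "rs3730945": 0.5, "rs145821638": 0.5}),
        ]
        labels = ms.classify_tag_snps(stats)
        assert set(labels) == {"a", "b"}
        assert labels["a"] == "5AM1" and labels["b"] is None

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        ms.rules_to_yaml(ms.BUILTIN_TAG_RULES, path)
        loaded = ms.rules_from_yaml(path)
        assert loaded == ms.BUILTIN_TAG_RULES


class TestTopQuartileHwe:
    def make_scores(self, n, rng):
        return pd.DataFrame({
            "sample": [f"s{i:05d}" for i in range(n)],
            "main_cag": rng.integers(40, 56, n),
            "peak_proportional_sum": rng.random(n),
        })

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(200):
            scores = self.make_scores(400, rng)
            geno = pd.Series(rng.binomial(2, 0.3, 400),
                             index=scores["sample"])
            pvals.append(ms.top_quartile_hwe_report(scores, geno).p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_coupled_minor_allele_detected(self):
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(30):
            n = 600
            geno = rng.binomial(2, 0.3, n)
            pps = rng.random(n) + 0.4 * geno  # minor allele raises expansion
            scores = pd.DataFrame({
                "sample": [f"s{i:05d}" for i in range(n)],
                "main_cag": [42] * n,
                "peak_proportional_sum": pps,
            })
            res = ms.top_quartile_hwe_report(
                scores, pd.Series(geno, index=scores["sample"])
            )
            pvals.append(res.p)
        assert np.median(pvals) < 0.05

    def test_stratified_mode_runs_and_pools(self):
        rng = np.random.default_rng(11)
        scores = self.make_scores(800, rng)
        geno = pd.Series(rng.binomial(2, 0.3, 800), index=scores["sample"])
        res = ms.top_quartile_hwe_report(scores, geno, stratify_by_cag=True)
        assert res.df == 2 and 0 < res.p <= 1
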