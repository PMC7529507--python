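"""Inter-estimator concordance statistics, with independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from puriploid import concordance as conc


# ---------------------------------------------------------------- oracles
def bh_bruteforce(p):
    """Step-up BH: adj_i = min_{j>=i} p_(j) * m / j, by direct enumeration."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def binom_two_sided(k, n):
    """Two-sided exact binomial p at 1/2 by pmf enumeration."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    return min(1.0, sum(pi for pi in pmf if pi <= pmf[k] * (1 + 1e-12)))


def ranksum_permutation(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


# ------------------------------------------------------------------ tests
class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.04, 0.5], [0.015, 0.06, 0.5]),
            ([0.25], [0.25]),
        ],
    )
    def test_known_values(self, p, expected):
        assert conc.bh_adjust(p) == pytest.approx(expected)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_bruteforce_oracle(self, p):
        assert conc.bh_adjust(p) == pytest.approx(bh_bruteforce(p), abs=1e-12)

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = conc.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            conc.bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        adj = conc.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)


class TestBinomialDirection:
    def test_symmetric_counts_give_one(self):
        assert conc.binomial_direction_test(5, 5) == pytest.approx(1.0)

    def test_eight_two_tail_mass(self):
        assert conc.binomial_direction_test(8, 2) == pytest.approx(112 / 1024)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            conc.binomial_direction_test(0, 0)

    def test_matches_pmf_enumeration_small_n(self):
        for n in range(1, 16):
            for k in range(n + 1):
                assert conc.binomial_direction_test(k, n - k) == pytest.approx(
                    binom_two_sided(k, n), abs=1e-12
                )


class TestWilcoxon:
    def test_exact_matches_full_permutation(self):
        rng = np.random.default_rng(1)
        for n, m in [(3, 3), (4, 3), (5, 4), (4, 6)]:
            x = rng.normal(size=n)
            y = rng.normal(0.5, 1.0, size=m)
            assert conc._ranksum_p(x, y) == pytest.approx(
                ranksum_permutation(x, y), abs=1e-10
            )

    def test_spec_example_two_over_thirtyfive(self):
        x = np.array([0.9, 0.8, 0.85, 0.95])
        y = np.array([0.1, 0.2, 0.15])
        assert conc._ranksum_p(x, y) == pytest.approx(2 / 35, abs=1e-12)


class TestCorrelationMatrix:
    def test_identical_methods_unit_correlation(self):
        m = pd.DataFrame({"A": [0.1, 0.2, 0.3, 0.4], "B": [0.1, 0.2, 0.3, 0.4]})
        r = conc.correlation_matrix(m).r
        assert r.loc["A", "B"] == pytest.approx(1.0)

    def test_anti_correlated_methods(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        m = pd.DataFrame({"A": a, "B": 1 - a})
        assert conc.correlation_matrix(m).r.loc["A", "B"] == pytest.approx(-1.0)

    def test_pairwise_complete_uses_overlap_only(self):
        m = pd.DataFrame(
            {"A": [0.1, 0.2, 0.3, 0.4], "B": [0.1, 0.2, 0.3, np.nan]}
        )
        rep = conc.correlation_matrix(m)
        assert rep.r.loc["A", "B"] == pytest.approx(1.0)
        assert rep.n.loc["A", "B"] == 3

    def test_under_threshold_cell_missing(self):
        m = pd.DataFrame({"A": [0.1, 0.2, np.nan, np.nan], "B": [0.3, 0.1, 0.2, 0.4]})
        rep = conc.correlation_matrix(m, min_pairs=3)
        assert np.isnan(rep.r.loc["A", "B"])

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(size=(30, 4)), columns=list("ABCD"))
        r = conc.correlation_matrix(m).r
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)


class TestOrderMethods:
    def test_identical_methods_adjacent(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(size=40)
        m = pd.DataFrame(
            {"A": base, "B": base + rng.normal(0, 1e-6, 40), "C": rng.uniform(size=40)}
        )
        order = conc.order_methods(conc.correlation_matrix(m))
        ia, ib = order.index("A"), order.index("B")
        assert abs(ia - ib) == 1

    def test_strong_pair_merged_first(self):
        r = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        order = conc.order_methods(conc.ConcordanceReport(r=r, n=r * 0 + 10))
        assert abs(order.index("A") - order.index("B")) == 1

    def test_single_method(self):
        r = pd.DataFrame([[1.0]], index=["A"], columns=["A"])
        assert conc.order_methods(conc.ConcordanceReport(r=r, n=r)) == ["A"]


class TestAnova:
    def test_identical_values_no_signal(self):
        m = pd.DataFrame({"A": [0.5, 0.5, 0.5], "B": [0.5, 0.5, 0.5]})
        f, p = conc.intermethod_anova(m)
        assert f == 0.0 and p == 1.0

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        f, p = conc.intermethod_anova(pd.DataFrame({"A": pd.Series(a), "B": pd.Series(b)}))
        t, pt = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            conc.intermethod_anova(pd.DataFrame({"A": [0.5, 0.6, 0.7]}))


class TestAgreement:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.7, 0.7, 0.7), "concordant"),
            ((0.8, 0.5, 0.55), "underestimate"),
            ((0.4, 0.6, 0.65), "overestimate"),
            ((0.6, 0.8, 0.4), "discordant"),
        ],
    )
    def test_classification(self, triple, expected):
        assert conc.classify_agreement(*triple) == expected

    def test_missing_estimate_rejected(self):
        with pytest.raises(ValueError):
            conc.classify_agreement(0.5, np.nan, 0.5)

    def test_classes_partition_complete_triples(self):
        rng = np.random.default_rng(5)
        path = pd.Series(rng.uniform(size=60))
        dna = pd.Series(np.where(rng.random(60) < 0.2, np.nan, rng.uniform(size=60)))
        mrna = pd.Series(rng.uniform(size=60))
        out = conc.agreement_summary(path, dna, mrna)
        assert out["n_eligible"] == dna.notna().sum()
        assert len(out["classes"]) == out["n_eligible"]
        assert sum(out["fractions"].values()) == pytest.approx(1.0)

    def test_shift_invariance_of_classes(self):
        for trip in [(0.5, 0.3, 0.25), (0.5, 0.62, 0.7), (0.4, 0.45, 0.5)]:
            shifted = tuple(v + 0.1 for v in trip)
            assert conc.classify_agreement(*trip) == conc.classify_agreement(*shifted)


class TestMutationStratification:
    def test_spec_example_extreme_ranking(self):
        purity = pd.Series(
            {"a": 0.9, "b": 0.8, "c": 0.85, "d": 0.95, "e": 0.1, "f": 0.2, "g": 0.15}
        )
        muts = pd.DataFrame({"sample": list("abcd"), "gene": ["G"] * 4})
        out = conc.stratify_by_mutation(purity, muts)
        row = out.iloc[0]
        assert row["tested"]
        assert row["wilcoxon_p"] == pytest.approx(2 / 35)

    def test_three_mutants_flagged_untested(self):
        purity = pd.Series({s: 0.5 + 0.01 * i for i, s in enumerate("abcdefgh")})
        muts = pd.DataFrame({"sample": list("abc"), "gene": ["G"] * 3})
        out = conc.stratify_by_mutation(purity, muts)
        assert not out.iloc[0]["tested"]
        assert np.isnan(out.iloc[0]["wilcoxon_p"])

    def test_log2fc_of_doubled_mean(self):
        purity = pd.Series({"a": 0.8, "b": 0.8, "c": 0.8, "d": 0.8, "e": 0.4, "f": 0.4})
        muts = pd.DataFrame({"sample": list("abcd"), "gene": ["G"] * 4})
        out = conc.stratify_by_mutation(purity, muts)
        assert out.iloc[0]["log2fc"] == pytest.approx(1.0)

    def test_bh_across_tested_genes_only(self):
        rng = np.random.default_rng(6)
        purity = pd.Series(rng.uniform(0.2, 0.9, 40), index=[f"s{i}" for i in range(40)])
        rows = []
        for g in range(6):
            carriers = rng.choice(40, size=5 if g < 4 else 2, replace=False)
            rows += [{"sample": f"s{i}", "gene": f"g{g}"} for i in carriers]
        out = conc.stratify_by_mutation(purity, pd.DataFrame(rows))
        tested = out[out["tested"]]
        untested = out[~out["tested"]]
        assert untested["fdr_adjusted_p"].isna().all()
        assert tested["fdr_adjusted_p"].notna().all()
        assert np.allclose(
            tested["fdr_adjusted_p"], bh_bruteforce(tested["wilcoxon_p"].to_numpy())
        )


class TestVafCorrelation:
    def test_linear_vaf_gives_unit_correlation(self):
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(12)]
        purity = pd.Series(rng.uniform(0.3, 0.9, 12), index=samples)
        muts = pd.DataFrame(
            {"sample": samples, "gene": "G", "vaf": purity.to_numpy() / 2}
        )
        out = conc.vaf_purity_correlation(purity, muts)
        assert out.iloc[0]["vaf_pearson_r"] == pytest.approx(1.0)

    def test_ten_carriers_excluded(self):
        samples = [f"s{i}" for i in range(10)]
        purity = pd.Series(np.linspace(0.2, 0.9, 10), index=samples)
        muts = pd.DataFrame({"sample": samples, "gene": "G", "vaf": np.linspace(0.1, 0.5, 10)})
        assert len(conc.vaf_purity_correlation(purity, muts)) == 0

    def test_constant_vaf_missing_correlation(self):
        samples = [f"s{i}" for i in range(12)]
        purity = pd.Series(np.linspace(0.2, 0.9, 12), index=samples)
        muts = pd.DataFrame({"sample": samples, "gene": "G", "vaf": 0.3})
        out = conc.vaf_purity_correlation(purity, muts)
        assert np.isnan(out.iloc[0]["vaf_pearson_r"])

    def test_vaf_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            conc.vaf_purity_correlation(
                pd.Series({"a": 0.5}),
                pd.DataFrame({"sample": ["a"], "gene": ["G"], "vaf": [1.4]}),
            )


class TestFeatureScreen:
    def test_feature_tracking_one_estimator(self):
        rng = np.random.default_rng(8)
        n = 100
        samples = [f"s{i}" for i in range(n)]
        est = pd.DataFrame(
            {k: rng.uniform(size=n) for k in ("pathology", "DNA", "mRNA", "miRNA")},
            index=samples,
        )
        features = pd.DataFrame(
            [est["DNA"].to_numpy() + rng.normal(0, 0.01, n)],
            index=["f1"],
            columns=samples,
        )
        pairs, hist = conc.feature_purity_screen(features, est)
        sig = pairs[pairs["significant"]]
        assert set(sig["estimator"]) == {"DNA"}
        assert hist.loc[1] == 1

    def test_constant_feature_excluded(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(30)]
        est = pd.DataFrame({"DNA": rng.uniform(size=30)}, index=samples)
        features = pd.DataFrame([[0.5] * 30], index=["flat"], columns=samples)
        pairs, hist = conc.feature_purity_screen(features, est)
        assert pairs["rho"].isna().all()
        assert hist.sum() == 0

    def test_degenerate_identical_estimators_count_all(self):
        rng = np.random.default_rng(10)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        sig = rng.uniform(size=n)
        est = pd.DataFrame({k: sig for k in ("a", "b", "c", "d")}, index=samples)
        features = pd.DataFrame([sig], index=["f"], columns=samples)
        pairs, hist = conc.feature_purity_screen(features, est)
        assert hist.loc[4] == 1

    def test_null_false_positive_rate_bounded(self):
        # independent features and estimators: significant fraction must be
        # conservative (the |rho| filter dominates the FDR level)
        rng = np.random.default_rng(11)
        n, n_feat = 100, 400
        samples = [f"s{i}" for i in range(n)]
        est = pd.DataFrame(
            {k: rng.uniform(size=n) for k in ("pathology", "DNA", "mRNA", "miRNA")},
            index=samples,
        )
        features = pd.DataFrame(
            rng.uniform(size=(n_feat, n)), index=[f"f{i}" for i in range(n_feat)],
            columns=samples,
        )
        pairs, hist = conc.feature_purity_screen(features, est)
        frac_sig = pairs["significant"].mean()
        assert frac_sig <= 2 * conc.DEFAULT_FDR_MAX


class TestCovariateWrapper:
    def test_known_linear_covariate(self):
        rng = np.random.default_rng(12)
        samples = [f"s{i}" for i in range(40)]
        m = pd.DataFrame({"ASCAT": rng.uniform(size=40)}, index=samples)
        cov = pd.DataFrame({"pga": 2 * m["ASCAT"] + 1}, index=samples)
        out = conc.correlate_covariates(m, cov)
        assert out.loc["ASCAT", "pga"] == pytest.approx(1.0)
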