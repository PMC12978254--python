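"""Cohort interaction models and survival machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cinmn import cohort as co
from cinmn.simulate import make_cohort


class TestResponseInteraction:
    def test_equal_slopes_null(self):
        tab, _ = make_cohort(n_tumors=120, effect_mn_on_sting=(0.2, 0.2), seed=1)
        r = co.response_interaction(tab, "sting_malignant")
        assert abs(r.slope_diff) < 0.1
        assert r.p_interaction > 0.05 or abs(r.slope_diff) < 2 * 0.05

    def test_recovers_constructed_slope_difference(self):
        tab, truth = make_cohort(n_tumors=100, effect_mn_on_sting=(0.0, 0.5), seed=2)
        r = co.response_interaction(tab, "sting_malignant")
        assert r.slope_diff == pytest.approx(truth["sting_slope_diff"], abs=0.15)
        assert r.p_interaction < 0.01

    def test_trg3_like_class_excluded(self):
        tab, _ = make_cohort(n_tumors=100, frac_other_response=0.3, seed=3)
        r = co.response_interaction(tab, "sting_malignant")
        assert r.n_r + r.n_nr == (tab["response"] != "other").sum()

    def test_constant_mn_class_degenerate(self):
        tab, _ = make_cohort(n_tumors=60, seed=4)
        tab.loc[tab["response"] == "R", "mn_score"] = 2.0
        with pytest.warns(UserWarning, match="degenerate"):
            r = co.response_interaction(tab, "sting_malignant")
        assert r.degenerate and np.isnan(r.slope_diff)

    def test_needs_three_per_class(self):
        tab, _ = make_cohort(n_tumors=60, seed=5)
        sub = pd.concat([tab[tab.response == "R"].iloc[:2], tab[tab.response == "NR"]])
        with pytest.raises(ValueError, match=">= 3"):
            co.response_interaction(sub, "sting_malignant")


class TestCinCgasStingInteraction:
    @pytest.fixture
    def design(self, rng):
        n = 150
        idx = [f"t{i}" for i in range(n)]
        return {
            "cin": pd.Series(rng.normal(size=n), index=idx),
            "sting": pd.Series(rng.normal(size=n), index=idx),
            "purity": pd.Series(rng.beta(5, 2, n), index=idx),
            "leuk": pd.Series(rng.beta(2, 5, n), index=idx),
            "rng": rng,
        }

    def test_multiplicative_gene_classed_enriched_dependent(self, design):
        n = len(design["cin"])
        expr = pd.DataFrame(
            {"mult": 0.6 * design["cin"] + 0.5 * design["cin"] * design["sting"]
             + design["rng"].normal(0, 0.3, n)}
        ).T
        out = co.cin_cgassting_interaction(expr, design["cin"], design["sting"],
                                           design["purity"], design["leuk"])
        assert out.loc["mult", "class"] == "cin_enriched_dependent"

    def test_cin_only_gene_not_dependent(self, design):
        n = len(design["cin"])
        expr = pd.DataFrame({"lin": 0.8 * design["cin"] + design["rng"].normal(0, 0.3, n)}).T
        out = co.cin_cgassting_interaction(expr, design["cin"], design["sting"],
                                           design["purity"], design["leuk"])
        assert out.loc["lin", "class"] == "none"

    def test_noise_genes_rarely_classed(self, design):
        n = len(design["cin"])
        expr = pd.DataFrame(design["rng"].normal(size=(2000, n)), columns=design["cin"].index)
        out = co.cin_cgassting_interaction(expr, design["cin"], design["sting"],
                                           design["purity"], design["leuk"])
        rate = (out["class"] != "none").mean()
        assert rate <= 0.01  # two independent 0.05 gates plus sign agreement


class TestAgreement:
    def test_exact_linear_target(self):
        tab, _ = make_cohort(n_tumors=80, seed=6)
        tab["target"] = 2.0 * tab["cin_mn"]
        coef, p = co.cin_score_agreement(tab, "target")
        assert coef == pytest.approx(2.0, abs=1e-8)
        assert p < 1e-20

    def test_independent_scores_p_uniformish(self):
        ps = []
        for seed in range(30):
            tab, _ = make_cohort(n_tumors=60, seed=seed)
            # offset seed: the cohort's lognormal MN shares the generator's
            # normal stream, so an identical seed would reproduce log(MN)
            rng = np.random.default_rng(10_000 + seed)
            tab["target"] = rng.normal(size=len(tab))
            ps.append(co.cin_score_agreement(tab, "target")[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_confounded_marginal_differs_from_adjusted(self, rng):
        """A purity-driven target correlates with CIN marginally but the
        adjusted CIN coefficient stays near zero."""
        n = 300
        purity = rng.beta(5, 2, n)
        cin = 2.0 * purity + rng.normal(0, 0.3, n)
        target = 3.0 * purity + rng.normal(0, 0.3, n)
        tab = pd.DataFrame({"cin_mn": cin, "purity": purity,
                            "leukocyte_fraction": rng.beta(2, 5, n), "target": target})
        marginal = np.corrcoef(cin, target)[0, 1]
        coef, _ = co.cin_score_agreement(tab, "target")
        assert marginal > 0.5
        assert abs(coef) < 0.25


class TestKmLogrank:
    def test_km_equals_empirical_survival_without_censoring(self):
        t = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        curves, _, _ = co.km_logrank(t, np.ones(5, int), np.array(["x"] * 5))
        km = curves["x"]
        for time in [1, 2, 3, 4, 5]:
            assert km.loc[float(time)] == pytest.approx((t > time).mean())

    def test_identical_groups_statistic_zero(self):
        t = np.tile([1.0, 2, 3, 4], 2)
        e = np.ones(8, int)
        g = np.repeat(["a", "b"], 4)
        # groups share every event time -> observed = expected exactly
        _, stat, p = co.km_logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_textbook_hand_computation(self):
        """Two groups of three with all events: the log-rank chi-square
        equals the hand-tallied (O-E)^2/V."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, int)
        g = np.array(["A", "A", "A", "B", "B", "B"])
        # hand computation over the six event times
        o_minus_e, var = 0.0, 0.0
        at_risk = [("A", 1.0), ("A", 2.0), ("A", 3.0), ("B", 4.0), ("B", 5.0), ("B", 6.0)]
        for tt in t:
            n = sum(1 for _, x in at_risk if x >= tt)
            n_a = sum(1 for grp, x in at_risk if x >= tt and grp == "A")
            d = 1
            o = 1 if tt <= 3 else 0
            ex = d * n_a / n
            o_minus_e += o - ex
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        _, stat, p = co.km_logrank(t, e, g)
        assert stat == pytest.approx(expected_chi2)
        assert p == pytest.approx(stats.chi2.sf(expected_chi2, 1))

    def test_logrank_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        g = np.repeat(["a", "b"], 20)
        _, s1, p1 = co.km_logrank(t, e, g)
        _, s2, p2 = co.km_logrank(np.log1p(t), e, g)
        assert s1 == pytest.approx(s2)

    def test_power_against_proportional_hazards(self):
        """HR = 2 at n = 500: rejection rate close to the analytic power
        (Schoenfeld: ~events/4 * ln(2)^2 noncentrality)."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_sim = 40
        for _ in range(n_sim):
            g = rng.integers(0, 2, 500)
            lam = 0.05 * np.exp(np.log(2.0) * g)
            t = rng.exponential(1 / lam)
            _, _, p = co.km_logrank(t, np.ones(500, int), g)
            rejections += p < 0.05
        # Schoenfeld power at 500 events, HR 2, equal allocation is ~1
        assert rejections / n_sim > 0.95

    def test_pairwise_variant(self):
        tab, _ = make_cohort(n_tumors=160, seed=8)
        strata = co.nested_median_stratify(tab["cin_mn"], tab["skew"])
        out = co.pairwise_logrank(tab["time_months"], tab["event"], strata,
                                  reference="CIN_high/My_dom")
        assert len(out) == 3
        assert (out["p"].between(0, 1)).all()


class TestMaxStat:
    def test_step_hazard_cutpoint_recovered(self, rng):
        n = 150
        score = rng.normal(size=n)
        lam = np.where(score > 0.3, 0.10, 0.03)
        t = rng.exponential(1 / lam)
        res = co.maxstat_cutpoint(score, t, np.ones(n, int), n_perm=200, seed=0)
        assert abs(res.cutpoint - 0.3) < 0.35
        assert res.p < 0.05

    def test_duplicate_scores_give_single_candidate_per_value(self):
        score = np.repeat([1.0, 2.0, 3.0], 10)
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 30)
        res = co.maxstat_cutpoint(score, t, np.ones(30, int),
                                  quantile_range=(0.0, 1.0), n_perm=50, seed=0)
        assert len(res.candidates) == len(np.unique(res.candidates["cutpoint"]))
        assert res.candidates["cutpoint"].tolist() == [1.0, 2.0]

    def test_null_permutation_p_uniform(self, rng):
        """Scores independent of survival: the naive best-split p would be
        anti-conservative, the permutation p is ~uniform."""
        ps, naive = [], []
        for k in range(60):
            n = 60
            score = rng.normal(size=n)
            t = rng.exponential(10, n)
            res = co.maxstat_cutpoint(score, t, np.ones(n, int), n_perm=99, seed=k)
            ps.append(res.p)
            naive.append(2 * stats.norm.sf(res.statistic))
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        # the unadjusted best-split p piles up near zero
        assert np.mean(np.array(naive) < 0.05) > 0.3


class TestStratification:
    def test_four_distinct_subjects_one_per_stratum(self):
        s = co.nested_median_stratify(pd.Series([1.0, 2, 3, 4]), pd.Series([1.0, 0, 1, 0]))
        assert sorted(s) == sorted(
            ["CIN_low/My_dom", "CIN_low/Ly_dom", "CIN_high/My_dom", "CIN_high/Ly_dom"]
        )

    def test_values_at_median_go_low(self):
        s = co.nested_median_stratify(pd.Series([1.0, 2.0, 3.0]), pd.Series([0.0, 0.0, 0.0]))
        # cin median 2 -> only 3.0 is high; skew ties at median -> Ly_dom
        assert s.tolist() == ["CIN_low/Ly_dom", "CIN_low/Ly_dom", "CIN_high/Ly_dom"]

    def test_strata_sizes_near_quarters(self):
        tab, _ = make_cohort(n_tumors=201, seed=9)
        s = co.nested_median_stratify(tab["cin_mn"], tab["skew"])
        sizes = s.value_counts()
        assert len(sizes) == 4
        assert (np.abs(sizes - len(tab) / 4) <= 1.5).all()


class TestCox:
    def test_null_group_hr_near_one(self):
        rng = np.random.default_rng(7)
        n = 400
        g = rng.integers(0, 2, n)
        t = rng.exponential(10, n)
        r = co.cox_univariate(g, t, np.ones(n, int))
        assert r.ci_low < 1.0 < r.ci_high

    def test_hr_two_recovered_at_n_1000(self, rng):
        n = 1000
        g = rng.integers(0, 2, n)
        lam = 0.05 * np.exp(np.log(2.0) * g)
        t = rng.exponential(1 / lam)
        r = co.cox_univariate(g, t, np.ones(n, int))
        assert r.hazard_ratio == pytest.approx(2.0, rel=0.1)
        assert r.converged

    def test_group_without_events_flagged(self):
        g = np.array([0, 0, 0, 1, 1, 1])
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 1, 0, 0, 0])
        with pytest.warns(UserWarning, match="no events"):
            r = co.cox_univariate(g, t, e)
        assert not r.converged and np.isnan(r.hazard_ratio)


class TestCohortPipeline:
    def test_positive_coefficients_worst_stratum_is_cin_high_my_dom(self):
        """With positive CIN and skew hazard coefficients the CIN-high,
        myeloid-dominated stratum has the worst survival."""
        tab, _ = make_cohort(
            n_tumors=1200, hazard_coefficients={"cin": 0.8, "skew": 0.8},
            censoring_rate=0.2, seed=10,
        )
        strata = co.nested_median_stratify(tab["cin_mn"], tab["skew"])
        curves, stat, p = co.km_logrank(tab["time_months"], tab["event"], strata)
        assert p < 1e-4
        medians = {}
        for g, km in curves.items():
            below = km[km <= 0.5]
            medians[g] = below.index[0] if len(below) else np.inf
        assert min(medians, key=medians.get) == "CIN_high/My_dom"
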