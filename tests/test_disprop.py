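"""Unit and property tests for the four disproportionality statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from pvsignal.disprop import (
    BcpnnPriors,
    ContingencyTable,
    PriorHyperparams,
    bcpnn_ic,
    bcpnn_ic_mc,
    bonferroni,
    build_tables,
    ebgm,
    ebgm_counts,
    fit_mgps_prior,
    fit_mgps_prior_counts,
    ml_ic,
    prr_chi2,
    ror,
    relative_reporting_ratio,
    score_tables,
)

cells = st.integers(min_value=1, max_value=500)


def oracle_ror(a, b, c, d):
    est = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    return est, est * math.exp(-z * se), est * math.exp(z * se)


def oracle_prr_chi2(a, b, c, d):
    n = a + b + c + d
    est = (a / (a + b)) / (c / (c + d))
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return est, chi2


class TestClosedForms:
    def test_ror_hand_example(self):
        est, lo, hi = ror(ContingencyTable(10, 90, 100, 9800))
        assert est == pytest.approx(10.888888888, abs=1e-6)
        assert (round(lo, 2), round(hi, 2)) == (5.50, 21.54)

    def test_ror_independence(self):
        est, lo, hi = ror(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_ror_haldane_on_zero_cell(self):
        est, lo, hi = ror(ContingencyTable(0, 90, 100, 9800))
        exp, exp_lo, exp_hi = oracle_ror(0.5, 90.5, 100.5, 9800.5)
        assert est == pytest.approx(exp, rel=1e-12)
        assert lo == pytest.approx(exp_lo, rel=1e-12)

    def test_ror_zero_cell_without_correction_is_undefined(self):
        est, lo, hi = ror(ContingencyTable(0, 90, 100, 9800), correction=False)
        assert math.isnan(est) and math.isnan(lo) and math.isnan(hi)

    def test_prr_chi2_hand_example(self):
        est, lo, hi, chi2, p = prr_chi2(ContingencyTable(10, 90, 100, 9800))
        assert est == pytest.approx(9.9, abs=1e-9)
        assert chi2 == pytest.approx(73.5455, abs=1e-3)
        assert p < 1e-10

    def test_chi2_matches_scipy(self):
        # independent route: scipy's Pearson statistic on the same table
        t = ContingencyTable(3266, 2130, 2449, 1329)
        _, _, _, chi2, p = prr_chi2(t)
        s_chi2, s_p, _, _ = stats.chi2_contingency(
            [[3266, 2130], [2449, 1329]], correction=False
        )
        assert chi2 == pytest.approx(s_chi2, rel=1e-12)
        assert p == pytest.approx(s_p, rel=1e-9)
        assert chi2 == pytest.approx(17.46, abs=0.01)

    def test_proportional_table_is_null(self):
        t = ContingencyTable(10, 90, 100, 900)  # a/(a+b) == c/(c+d)
        est, _, _, chi2, p = prr_chi2(t)
        assert est == pytest.approx(1.0, abs=1e-12)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        r, _, _ = ror(t)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert ml_ic(t) == pytest.approx(0.0, abs=1e-12)

    def test_grid_against_hand_formulas(self):
        for a in range(1, 6):
            for b in range(1, 6):
                for c in range(1, 6):
                    for d in range(1, 6):
                        t = ContingencyTable(a, b, c, d)
                        est, lo, hi = ror(t)
                        o_est, o_lo, o_hi = oracle_ror(a, b, c, d)
                        assert abs(est - o_est) < 1e-10
                        assert abs(lo - o_lo) < 1e-10
                        p_est, _, _, chi2, _ = prr_chi2(t)
                        o_p, o_chi2 = oracle_prr_chi2(a, b, c, d)
                        assert abs(p_est - o_p) < 1e-10
                        assert abs(chi2 - o_chi2) < 1e-10
                        o_ic = math.log2(a * t.n / ((a + b) * (a + c)))
                        assert abs(ml_ic(t) - o_ic) < 1e-10

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_interval_ordering_and_ror_prr_relation(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        est, lo, hi = ror(t)
        assert lo <= est <= hi
        p_est, p_lo, p_hi, _, _ = prr_chi2(t)
        assert p_lo <= p_est <= p_hi
        # ror/prr = d(a+b)/(b(c+d)); ror >= prr iff ror >= 1
        if est > 1:
            assert est >= p_est - 1e-12
        elif est < 1:
            assert est <= p_est + 1e-12

    def test_monotone_in_a(self):
        prior = PriorHyperparams(2.0, 4.0, 1.0, 1.0, 0.5)
        prev = None
        for a in (5, 10, 20, 40, 80):
            t = ContingencyTable(a, 100, 50, 5000)
            vals = (ror(t)[0], prr_chi2(t)[0], ml_ic(t), ebgm(t, prior)[0])
            if prev is not None:
                assert all(v > p for v, p in zip(vals, prev))
            prev = vals


class TestBcpnn:
    def test_ml_limit_zero_when_observed_equals_expected(self):
        # a=10, margins 100 and 1000, N=10000 -> E = 10
        assert ml_ic(ContingencyTable(10, 90, 990, 8910)) == pytest.approx(0.0, abs=1e-12)

    def test_ic025_positive_for_strong_signal(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(683, 9431, 20000, 13_000_000))
        assert ic > 5 and ic025 > 0

    def test_variance_nonnegative_on_grid(self):
        for a in range(0, 10):
            for b in range(0, 10):
                for c in range(0, 10):
                    t = ContingencyTable(a, b, c, 20)
                    ic, ic025 = bcpnn_ic(t)
                    assert math.isfinite(ic) and math.isfinite(ic025)
                    assert ic025 <= ic

    def test_mc_agrees_with_closed_form(self):
        t = ContingencyTable(50, 450, 500, 49000)
        ic, ic025 = bcpnn_ic(t)
        mc_ic, mc_ic025 = bcpnn_ic_mc(t, n_samples=200_000, rng=np.random.default_rng(5))
        assert mc_ic == pytest.approx(ic, abs=0.05)
        assert mc_ic025 == pytest.approx(ic025, abs=0.1)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            BcpnnPriors(alpha=-1)


def _posterior_cdf_quad(a, e, prior, x):
    """Quadrature oracle: integrate the posterior mixture density to x."""
    from scipy.stats import nbinom

    l1 = nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    l2 = nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    q = 1 / (1 + math.exp(math.log(1 - prior.w) - math.log(prior.w) + l2 - l1))

    def pdf(lam):
        return q * stats.gamma.pdf(lam, prior.alpha1 + a, scale=1 / (prior.beta1 + e)) + (
            1 - q
        ) * stats.gamma.pdf(lam, prior.alpha2 + a, scale=1 / (prior.beta2 + e))

    val, _ = integrate.quad(pdf, 0, x, limit=200)
    return val


class TestMgps:
    def test_ebgm_data_swamps_prior(self):
        prior = PriorHyperparams(2.0, 4.0, 1.0, 1.0, 0.5)
        gm, _ = ebgm_counts(1000, 100.0, prior)
        assert gm == pytest.approx(10.0, rel=0.02)

    def test_ebgm05_matches_quadrature(self):
        rng = np.random.default_rng(42)
        prior = PriorHyperparams(1.5, 2.0, 3.0, 1.0, 0.35)
        for _ in range(20):
            a = int(rng.integers(1, 400))
            e = float(rng.uniform(0.5, 200))
            _, eb05 = ebgm_counts(a, e, prior)
            mass = _posterior_cdf_quad(a, e, prior, eb05)
            assert mass == pytest.approx(0.05, abs=1e-6)

    def test_shrinkage_toward_one_when_observed_equals_expected(self):
        prior = PriorHyperparams(1.0, 1.0, 2.0, 2.0, 0.5)  # prior mean 1
        for e in (2.0, 10.0, 50.0):
            gm, _ = ebgm_counts(int(e), e, prior)
            assert 0.5 < gm < 2.0

    def test_consistency_ebgm_and_ic_approach_true_ratio(self):
        prior = PriorHyperparams(2.0, 4.0, 1.0, 1.0, 0.5)
        r = 3.0
        for scale in (10, 100, 1000):
            a = int(r * scale)
            gm, _ = ebgm_counts(a, float(scale), prior)
            assert gm == pytest.approx(r, rel=30 / scale + 0.01)

    def test_prior_recovery_from_single_gamma(self):
        rng = np.random.default_rng(2024)
        lam = rng.gamma(shape=2.0, scale=1 / 4.0, size=500)
        e = rng.lognormal(mean=3.5, sigma=1.0, size=500)
        a = rng.poisson(lam * e)
        fitted = fit_mgps_prior_counts(a, e)
        assert fitted.prior_mean == pytest.approx(0.5, rel=0.15)

    def test_fit_is_fixed_point_of_itself(self):
        rng = np.random.default_rng(7)
        lam = rng.gamma(2.0, 1 / 4.0, size=200)
        e = rng.lognormal(3.0, 1.0, size=200)
        a = rng.poisson(lam * e)
        fit1 = fit_mgps_prior_counts(a, e)
        fit2 = fit_mgps_prior_counts(
            a, e, start=(fit1.alpha1, fit1.beta1, fit1.alpha2, fit1.beta2, fit1.w)
        )
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)
        assert fit2.prior_mean == pytest.approx(fit1.prior_mean, rel=1e-3)

    def test_loglik_additive_for_duplicated_tables(self):
        from pvsignal.disprop import _mixture_loglik

        t = ContingencyTable(12, 88, 100, 9800)
        a = np.array([t.a], dtype=float)
        e = np.array([t.expected])
        params = np.array([np.log(0.2), np.log(0.1), np.log(2.0), np.log(4.0), 0.0])
        single = _mixture_loglik(params, a, e)
        double = _mixture_loglik(params, np.repeat(a, 2), np.repeat(e, 2))
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_needs_two_tables(self):
        with pytest.raises(ValueError):
            fit_mgps_prior([ContingencyTable(5, 5, 5, 5)])


class TestBonferroniAndTables:
    def test_bonferroni(self):
        adj = bonferroni([0.001] * 260)
        assert adj[0] == pytest.approx(0.26)
        assert bonferroni([0.01] * 260)[0] == 1.0
        assert bonferroni([0.0, 0.5])[0] == 0.0

    def test_bonferroni_order_preserving(self):
        p = [0.04, 0.001, 0.02]
        adj = bonferroni(p)
        assert list(np.argsort(adj)) == list(np.argsort(p))

    def test_build_tables_report_level_counting(self, small_sim, pt_soc_map):
        import pandas as pd

        reports = pd.DataFrame(
            {"primaryid": ["1", "2", "3"], "target": [True, True, False]}
        )
        reactions = pd.DataFrame(
            {"primaryid": ["1", "1", "2", "3"], "pt": ["Pain", "Pain", "Pain", "Pain"]}
        )
        tables = build_tables(reports, reactions, level="PT", min_count=1)
        term, t = tables[0]
        assert term == "Pain" and t.a == 2 and t.b == 0 and t.c == 1 and t.d == 0

    def test_build_tables_min_count_and_constant_margin(self, small_sim, pt_soc_map):
        from pvsignal import pipeline

        _, tables, _ = small_sim
        ing = pipeline.ingest_database(
            tables, pipeline.PipelineConfig(pt_soc_map=pt_soc_map)
        )
        tabs = build_tables(ing.reports, ing.reactions, level="PT", min_count=5)
        assert all(t.a >= 5 for _, t in tabs)
        margins = {t.a + t.b for _, t in tabs}
        assert len(margins) == 1  # a+b = total target reports for every term

    def test_min_count_below_one_rejected(self, small_sim):
        import pandas as pd

        with pytest.raises(ValueError):
            build_tables(
                pd.DataFrame({"primaryid": ["1"], "target": [True]}),
                pd.DataFrame({"primaryid": ["1"], "pt": ["X"]}),
                min_count=0,
            )

    def test_score_tables_columns_and_adjustment(self, small_sim, pt_soc_map):
        from pvsignal import pipeline

        _, tables, _ = small_sim
        ing = pipeline.ingest_database(
            tables, pipeline.PipelineConfig(pt_soc_map=pt_soc_map)
        )
        tabs = build_tables(ing.reports, ing.reactions, level="PT", min_count=5)
        scores = score_tables(tabs)
        assert {"ror", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05", "adjusted_p"} <= set(
            scores.columns
        )
        ok = scores["p"].notna()
        assert (scores.loc[ok, "adjusted_p"] >= scores.loc[ok, "p"] - 1e-15).all()
        assert (scores.loc[ok, "adjusted_p"] <= 1.0).all()
        # unshrunk observed/expected exposed alongside the shrunk EBGM
        assert (scores["rrr"] > 0).all()
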