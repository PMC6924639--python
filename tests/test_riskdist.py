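"""The log-normal polygenic relative-risk calculus, checked against
independent quadrature and Monte-Carlo oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from polyscreen.riskdist import (RiskModel, eligible_fraction,
                                 fraction_cases_above_percentile,
                                 fraction_cases_above_threshold,
                                 percentile_rr, stratum_relative_risks)


def population_density(model):
    s = model.sigma

    def pdf(r):
        return np.exp(-(np.log(r) - model.mu) ** 2 / (2 * model.variance)) \
            / (r * s * np.sqrt(2 * np.pi))

    return pdf


class TestRiskModel:
    def test_mean_relative_risk_is_one(self):
        assert RiskModel().mean_rr() == pytest.approx(1.0, abs=1e-12)

    def test_mean_rr_by_quadrature(self, risk_model):
        pdf = population_density(risk_model)
        mean, _ = quad(lambda r: r * pdf(r), 0, np.inf)
        assert abs(mean - 1.0) < 1e-9

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError):
            RiskModel(variance=0.0)
        with pytest.raises(ValueError):
            RiskModel(variance=-0.1)


class TestPercentileRR:
    @pytest.mark.parametrize("p, expected", [
        (0.5, 0.7118),    # exp(-0.34)
        (0.99, 4.847),    # exp(-0.34 + 2.3263 * 0.82462)
    ])
    def test_closed_form_values(self, risk_model, p, expected):
        assert percentile_rr(risk_model, p) == pytest.approx(expected, abs=5e-4)

    def test_degenerate_variance_limit(self):
        tiny = RiskModel(variance=1e-12)
        for p in (0.1, 0.5, 0.9):
            assert percentile_rr(tiny, p) == pytest.approx(1.0, abs=1e-5)

    def test_strictly_increasing(self, risk_model):
        grid = np.linspace(0.01, 0.99, 50)
        vals = percentile_rr(risk_model, grid)
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.7])
    def test_domain_error(self, risk_model, p):
        with pytest.raises(ValueError):
            percentile_rr(risk_model, p)

    @given(p=st.floats(0.001, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_log_symmetry(self, p):
        model = RiskModel()
        prod = percentile_rr(model, p) * percentile_rr(model, 1.0 - p)
        assert prod == pytest.approx(np.exp(2 * model.mu), rel=1e-9)


class TestCaseEnrichment:
    def test_top_quintile_holds_half_the_cases(self, risk_model):
        # the published headline: almost 49% of cases in the top 20%
        assert fraction_cases_above_percentile(risk_model, 0.80) == \
            pytest.approx(0.4932, abs=1e-4)

    def test_matches_quadrature_oracle(self, risk_model):
        # integral of r dF(r) above the 80th percentile, E[r] = 1
        pdf = population_density(risk_model)
        thr = percentile_rr(risk_model, 0.80)
        oracle, _ = quad(lambda r: r * pdf(r), thr, np.inf, epsabs=1e-10)
        assert fraction_cases_above_percentile(risk_model, 0.80) == \
            pytest.approx(oracle, abs=1e-9)

    def test_matches_monte_carlo(self, risk_model):
        # size-biased tail mass as a ratio estimator over 1e7 draws
        rng = np.random.default_rng(20160901)
        n = 10_000_000
        r = rng.lognormal(risk_model.mu, risk_model.sigma, size=n)
        thr = percentile_rr(risk_model, 0.80)
        x = r * (r > thr)
        est = x.mean() / r.mean()
        resid = x - est * r
        se = resid.std() / (r.mean() * np.sqrt(n))
        assert abs(fraction_cases_above_percentile(risk_model, 0.80) - est) < 3 * se

    def test_low_percentile_limit(self, risk_model):
        assert fraction_cases_above_percentile(risk_model, 1e-12) == \
            pytest.approx(1.0, abs=1e-9)

    def test_always_exceeds_population_share(self, risk_model):
        q = np.linspace(0.05, 0.95, 19)
        vals = fraction_cases_above_percentile(risk_model, q)
        assert np.all(vals >= (1 - q))
        assert np.all(np.diff(vals) < 0)

    def test_domain_error(self, risk_model):
        with pytest.raises(ValueError):
            fraction_cases_above_percentile(risk_model, 0.0)


class TestEligibleFraction:
    @pytest.mark.parametrize("baseline, expected", [
        (0.026, 0.114),   # age 55, 5% threshold: 1 in 10 men
        (0.071, 0.505),   # age 69, 5% threshold: just over half
    ])
    def test_published_eligibility_fractions(self, risk_model, baseline, expected):
        assert eligible_fraction(risk_model, baseline, 0.05) == \
            pytest.approx(expected, abs=5e-4)

    def test_median_individual_threshold_splits_population(self, risk_model):
        b = 0.03
        t = b * np.exp(risk_model.mu)
        assert eligible_fraction(risk_model, b, t) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_threshold_and_baseline(self, risk_model):
        ts = np.linspace(0.01, 0.2, 40)
        vals = eligible_fraction(risk_model, 0.05, ts)
        assert np.all(np.diff(vals) < 0)
        bs = np.linspace(0.01, 0.2, 40)
        vals = eligible_fraction(risk_model, bs, 0.05)
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("b, t", [(0.0, 0.05), (-0.1, 0.05), (0.05, 0.0), (0.05, 1.5)])
    def test_domain_errors(self, risk_model, b, t):
        with pytest.raises(ValueError):
            eligible_fraction(risk_model, b, t)


class TestStratumRelativeRisks:
    def test_derived_example(self, risk_model):
        rr_s, rr_u, f = stratum_relative_risks(risk_model, 0.026, 0.05)
        assert rr_s == pytest.approx(3.083, abs=2e-3)
        assert rr_u == pytest.approx(0.732, abs=1e-3)
        assert f == pytest.approx(0.114, abs=5e-4)

    def test_quadrature_oracle_for_screened_stratum(self, risk_model):
        # mean RR above the cut = truncated size-biased mass / population mass
        pdf = population_density(risk_model)
        b, t = 0.026, 0.05
        cut = t / b
        case_mass, _ = quad(lambda r: r * pdf(r), cut, np.inf, epsabs=1e-10)
        pop_mass, _ = quad(pdf, cut, np.inf, epsabs=1e-10)
        rr_s, rr_u, f = stratum_relative_risks(risk_model, b, t)
        assert rr_s == pytest.approx(case_mass / pop_mass, rel=1e-8)
        assert f == pytest.approx(pop_mass, abs=1e-9)

    @given(b=st.floats(0.005, 0.2), t=st.floats(0.005, 0.2))
    @settings(max_examples=100, deadline=None)
    def test_conservation_identity(self, b, t):
        model = RiskModel()
        try:
            rr_s, rr_u, f = stratum_relative_risks(model, b, t)
        except ValueError:
            return  # degenerate stratum is a legitimate rejection
        assert f * rr_s + (1 - f) * rr_u == pytest.approx(1.0, abs=1e-9)

    def test_whole_population_screened_limit(self, risk_model):
        b = 0.05
        prev = None
        for z in (2.0, 3.0, 4.0):
            t = b * np.exp(risk_model.mu - z * risk_model.sigma)
            rr_s, _, f = stratum_relative_risks(risk_model, b, t)
            if prev is not None:
                assert abs(rr_s - 1.0) < prev
            prev = abs(rr_s - 1.0)
            assert f > 0.97
        assert rr_s == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_stratum_error(self, risk_model):
        # thresholds so extreme that one stratum is numerically empty
        with pytest.raises(ValueError, match="degenerate"):
            stratum_relative_risks(risk_model, 1e-16, 0.9)
        with pytest.raises(ValueError, match="degenerate"):
            stratum_relative_risks(risk_model, 0.9, 1e-16)

    def test_case_split_consistency(self, risk_model):
        a = fraction_cases_above_threshold(risk_model, 0.026, 0.05)
        rr_s, rr_u, f = stratum_relative_risks(risk_model, 0.026, 0.05)
        assert rr_s * f == pytest.approx(a, rel=1e-12)
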