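"""Imputation routes for (mu, sigma) and prevalence fallbacks.

Expected values are either direct evaluations of the closed-form equations
or round-trips through an independently constructed forward model (CI bounds
built from known (mu, sigma); chi-square/ratio computed from a known integer
table).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from riskmeta import (
    PrevalenceTable,
    Study,
    StudyEstimate,
    impute_estimate,
    impute_prevalence,
    or_from_coefficient,
    sigma_from_ci,
    sigma_from_pvalue,
    solve_contingency,
    var_logor_from_table,
)
from riskmeta.imputation import PrevalenceUnavailable
from riskmeta.study_data import ContingencyTable, PrevalenceRecord


class TestOrFromCoefficient:
    @pytest.mark.parametrize(
        "mu, sigma, expected",
        [
            (0.0, 0.0, 1.0),
            (math.log(2), 0.0, 2.0),
            (0.5, 0.3, math.exp(0.545)),  # 0.5 + 0.09/2
        ],
    )
    def test_unbiased_mean(self, mu, sigma, expected):
        assert or_from_coefficient(mu, sigma) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            or_from_coefficient(math.inf, 0.1)


class TestSigmaFromCI:
    def test_degenerate_ci_gives_zero_sigma(self):
        assert sigma_from_ci(1.0, 1.0, 1.0) == (0.0, 0.0)

    def test_closed_form_example(self):
        mu, sigma = sigma_from_ci(2.0, 1.0, 4.0)
        assert sigma == pytest.approx(math.log(4) / 3.92, rel=1e-12)
        assert mu == pytest.approx(math.log(2) - sigma**2 / 2, rel=1e-12)

    @given(
        mu=st.floats(-2, 2),
        sigma=st.floats(0.01, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_roundtrip_from_constructed_bounds(self, mu, sigma):
        # forward model: the printed bound formulas
        center = mu + sigma**2 / 2
        lo, hi = math.exp(center - 1.96 * sigma), math.exp(center + 1.96 * sigma)
        mu2, sigma2 = sigma_from_ci(math.exp(mu), lo, hi)
        assert mu2 == pytest.approx(mu, abs=1e-10)
        assert sigma2 == pytest.approx(sigma, abs=1e-10)

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ValueError):
            sigma_from_ci(2.0, 0.0, 4.0)


class TestSigmaFromPvalue:
    @pytest.mark.parametrize(
        "p, mu, z_expected, sigma_expected",
        [
            (0.05, math.log(2), 1.9566, 0.3543),
            (0.01, 1.0, 2.5751, 0.3883),
        ],
    )
    def test_formula_values(self, p, mu, z_expected, sigma_expected):
        sigma, z = sigma_from_pvalue(p, mu)
        assert z == pytest.approx(z_expected, abs=1e-4)
        assert sigma == pytest.approx(sigma_expected, abs=1e-4)

    def test_z_tracks_exact_normal_quantile(self):
        # within 0.02 of the exact quantile over the moderate-p range; the
        # approximation drifts in the far tail (about 0.07 by p = 1e-6)
        for p in np.logspace(-3, math.log10(0.5), 30):
            _, z = sigma_from_pvalue(p, 1.0)
            assert abs(z - norm.isf(p / 2)) < 0.02
        for p in np.logspace(-6, -3, 15):
            _, z = sigma_from_pvalue(p, 1.0)
            assert abs(z - norm.isf(p / 2)) < 0.08

    def test_monotone_in_p(self):
        s1, _ = sigma_from_pvalue(0.01, math.log(2))
        s2, _ = sigma_from_pvalue(0.20, math.log(2))
        assert s1 < s2

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sigma_from_pvalue(0.0, 1.0)
        with pytest.raises(ValueError):
            sigma_from_pvalue(0.05, 0.0)


class TestSolveContingency:
    def test_documented_example(self):
        t = solve_contingency(30, 170, 2.0, 200.0 * 1000**2 / (100 * 100 * 170 * 30), ">1")
        assert t.a == pytest.approx(20, abs=1e-6)
        assert t.b == pytest.approx(80, abs=1e-5)
        assert t.c == pytest.approx(10, abs=1e-6)
        assert t.d == pytest.approx(90, abs=1e-5)

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            solve_contingency(30, 170, 1.0, 0.0)

    def test_totals_held_exactly(self):
        t = solve_contingency(30, 170, 2.0, 3.9216, ">1")
        assert t.a + t.c == pytest.approx(30, abs=1e-9)
        assert t.b + t.d == pytest.approx(170, abs=1e-9)

    @given(
        a=st.integers(1, 500),
        b=st.integers(1, 500),
        c=st.integers(1, 500),
        d=st.integers(1, 500),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_roundtrip_random_integer_tables(self, a, b, c, d):
        src = ContingencyTable(a, b, c, d)
        if abs(src.odds_ratio - 1.0) < 1e-6 or src.chi2 <= 1e-12:
            return
        out = solve_contingency(
            a + c, b + d, src.risk_ratio, src.chi2,
            ">1" if src.odds_ratio > 1 else "<1",
        )
        # all four defining equations reproduced
        assert out.a + out.c == pytest.approx(a + c, rel=1e-8)
        assert out.b + out.d == pytest.approx(b + d, rel=1e-8)
        assert out.risk_ratio == pytest.approx(src.risk_ratio, rel=1e-8)
        assert out.chi2 == pytest.approx(src.chi2, rel=1e-8)

    def test_inconsistent_statistics_error(self):
        # chi2 far above anything attainable for this ratio
        with pytest.raises(ValueError, match="inconsistent"):
            solve_contingency(30, 170, 1.2, 150.0, ">1")


class TestVarLogOR:
    def test_reciprocal_sum(self):
        assert var_logor_from_table(ContingencyTable(20, 80, 10, 90)) == pytest.approx(
            1 / 20 + 1 / 80 + 1 / 10 + 1 / 90, rel=1e-14
        )

    def test_symmetric_table(self):
        assert var_logor_from_table(ContingencyTable(10, 10, 10, 10)) == pytest.approx(0.4)

    def test_doubling_halves_variance(self):
        t1 = ContingencyTable(7, 13, 21, 9)
        t2 = ContingencyTable(14, 26, 42, 18)
        assert var_logor_from_table(t2) == pytest.approx(var_logor_from_table(t1) / 2)

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            var_logor_from_table(ContingencyTable(0, 1, 1, 1))


class TestDispatch:
    def test_exactly_one_route_fires_per_estimate(self, imputed_studies):
        for study in imputed_studies:
            for est in study.estimates:
                assert est.imputed
                assert est.trace is not None
                assert est.sigma >= 0 and math.isfinite(est.mu)
                assert (est.trace.z is not None) == (est.trace.method == "from_pvalue")
                assert (est.trace.table is not None) == (est.trace.method == "from_chi2")

    def test_precedence_reported_se_over_ci(self):
        est = StudyEstimate(
            "s", "f", "l", "or", 2.0, ci_low=1.0, ci_high=4.0, se=0.25
        )
        out = impute_estimate(est)
        assert out.trace.method == "reported"
        assert out.sigma == 0.25

    def test_ci_over_pvalue(self):
        est = StudyEstimate(
            "s", "f", "l", "or", 2.0, ci_low=1.0, ci_high=4.0, p_value=0.05
        )
        assert impute_estimate(est).trace.method == "from_ci"

    def test_bare_coefficient_rejected(self):
        est = StudyEstimate("s", "f", "l", "coefficient", 0.7)
        with pytest.raises(ValueError, match="no variability"):
            impute_estimate(est)


class TestImputePrevalence:
    def _studies(self):
        return [
            Study("s1", [
                StudyEstimate("s1", "f", "x", "or", 2.0, ci_low=1.1, ci_high=3.9,
                              control_prevalence=0.2),
                StudyEstimate("s1", "g", "y", "or", 1.5, ci_low=1.0, ci_high=2.2),
            ]),
            Study("s2", [
                StudyEstimate("s2", "f", "x", "or", 2.4, ci_low=1.3, ci_high=4.4,
                              control_prevalence=0.4),
                StudyEstimate("s2", "g", "y", "or", 1.4, ci_low=1.0, ci_high=2.0),
            ]),
        ]

    def test_mean_of_other_studies_is_tier4(self):
        rec = impute_prevalence("f", "x", self._studies())
        assert rec.prevalence == pytest.approx(0.3)
        assert rec.tier == 4

    def test_fallback_table_used_when_studies_silent(self):
        fallback = PrevalenceTable(
            [PrevalenceRecord("g", "y", 0.25, tier=1), PrevalenceRecord("g", "ref", 0.75, tier=1)]
        )
        rec = impute_prevalence("g", "y", self._studies(), fallback)
        assert rec.prevalence == pytest.approx(0.25)
        assert rec.tier == 1

    def test_exclusion_signal_when_no_source(self):
        with pytest.raises(PrevalenceUnavailable, match="excluded"):
            impute_prevalence("g", "y", self._studies(), None)
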