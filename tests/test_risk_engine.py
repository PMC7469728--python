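"""Calibration, patient risk, Monte Carlo propagation and DL pooling.

The DerSimonian-Laird oracle is coded from scratch here (plain loops) and
cross-checked against statsmodels' meta-analysis routine, independently of
the package implementation.
"""

import math
from dataclasses import replace

import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from riskmeta import (
    ModelConfig,
    PrevalenceTable,
    Study,
    StudyEstimate,
    baseline_risk,
    mc_log_se,
    patient_study_risk,
    pool_random_effects,
    predict,
    predict_many,
)
from riskmeta.risk_engine import StudyRisk
from riskmeta.study_data import NOT_APPLICABLE, PatientProfile, PrevalenceRecord

R0 = 0.000094


def _binary_study(or_value=2.0, sigma=0.3, sid="s1", factor="f", level="x"):
    est = StudyEstimate(
        sid, factor, level, "or", or_value, mu=math.log(or_value), sigma=sigma
    )
    return Study(sid, [est])


def _prev(p=0.5, factor="f", level="x", ref="ref"):
    return PrevalenceTable(
        [
            PrevalenceRecord(factor, level, p),
            PrevalenceRecord(factor, ref, 1 - p),
        ]
    )


class TestBaseline:
    def test_all_unit_ors_give_r0(self):
        study = _binary_study(or_value=1.0, sigma=0.1)
        cfg = ModelConfig()
        assert baseline_risk(study, _prev(), cfg) == pytest.approx(R0, rel=1e-14)

    def test_binary_factor_geometric_weighting(self):
        study = _binary_study(or_value=2.0)
        cfg = ModelConfig()
        assert baseline_risk(study, _prev(0.5), cfg) == pytest.approx(
            R0 / 2**0.5, rel=1e-12
        )

    def test_factors_multiply_in_denominator(self):
        ests = [
            StudyEstimate("s", "f", "x", "or", 2.0, mu=math.log(2), sigma=0.1),
            StudyEstimate("s", "g", "y", "or", 3.0, mu=math.log(3), sigma=0.1),
        ]
        prev = PrevalenceTable(
            [
                PrevalenceRecord("f", "x", 0.5),
                PrevalenceRecord("f", "ref", 0.5),
                PrevalenceRecord("g", "y", 0.2),
                PrevalenceRecord("g", "ref", 0.8),
            ]
        )
        cfg = ModelConfig()
        expected = R0 / (2**0.5 * 3**0.2)
        assert baseline_risk(Study("s", ests), prev, cfg) == pytest.approx(
            expected, rel=1e-12
        )

    def test_missing_prevalence_names_level(self):
        study = _binary_study()
        empty = PrevalenceTable(
            [PrevalenceRecord("g", "y", 0.4), PrevalenceRecord("g", "ref", 0.6)]
        )
        with pytest.raises(ValueError, match="f/x"):
            baseline_risk(study, empty, ModelConfig())

    def test_calibration_identity_on_synthetic_studies(
        self, imputed_studies, prevalences
    ):
        cfg = ModelConfig()
        for study in imputed_studies:
            r0k = baseline_risk(study, prevalences, cfg)
            log_avg = sum(
                prevalences.get(e.factor_id, e.level) * e.log_or_point
                for e in study.estimates
            )
            assert r0k * math.exp(log_avg) == pytest.approx(cfg.r0, rel=1e-12)


class TestPatientStudyRisk:
    def test_reference_profile_gets_baseline(self):
        study = _binary_study()
        profile = PatientProfile("p", {"f": "ref"})
        risk = patient_study_risk(profile, study, 1e-4, reference={"f": {"ref"}})
        assert risk == pytest.approx(1e-4)

    def test_level_multiplies_through(self):
        study = _binary_study(or_value=2.0)
        baseline = R0 / 2**0.5
        profile = PatientProfile("p", {"f": "x"})
        assert patient_study_risk(profile, study, baseline) == pytest.approx(
            2 * baseline, rel=1e-12
        )

    def test_not_applicable_counts_as_reference(self):
        study = _binary_study()
        profile = PatientProfile("p", {"f": NOT_APPLICABLE})
        assert patient_study_risk(profile, study, 1e-4) == pytest.approx(1e-4)

    def test_unmapped_level_raises(self):
        study = _binary_study()
        profile = PatientProfile("p", {"f": "elsewhere"})
        with pytest.raises(ValueError, match="unmapped level"):
            patient_study_risk(
                profile, study, 1e-4,
                reference={"f": {"ref"}},
            )

    def test_calibration_identity_patient(self):
        # a patient whose multiplier equals the population-average RR lands on R0
        study = _binary_study(or_value=2.0)
        cfg = ModelConfig()
        r0k = baseline_risk(study, _prev(0.5), cfg)
        assert r0k * 2**0.5 == pytest.approx(R0, rel=1e-12)


class TestMonteCarlo:
    def test_degenerate_sampling_gives_zero_se(self):
        study = _binary_study(sigma=0.0)
        cfg = ModelConfig(n_reps=500, prevalence_cv=0.0, seed=1)
        profile = PatientProfile("p", {"f": "x"})
        assert mc_log_se(profile, study, _prev(), cfg) == 0.0

    def test_analytic_propagation_single_binary_factor(self):
        # ln Rik = ln R0 + (1 - p) * sampled log-OR, so sd = (1-p) * sigma
        study = _binary_study(or_value=2.0, sigma=0.3)
        cfg = ModelConfig(n_reps=10_000, prevalence_cv=0.0, seed=11)
        profile = PatientProfile("p", {"f": "x"})
        se = mc_log_se(profile, study, _prev(0.5), cfg)
        assert se == pytest.approx(0.5 * 0.3, rel=0.02)

    def test_seed_reproducibility_bit_exact(self):
        study = _binary_study()
        cfg = ModelConfig(n_reps=2000, seed=42)
        profile = PatientProfile("p", {"f": "x"})
        a = mc_log_se(profile, study, _prev(), cfg)
        b = mc_log_se(profile, study, _prev(), cfg)
        assert a == b

    def test_se_scales_linearly_with_sigma_when_cv_zero(self):
        cfg = ModelConfig(n_reps=4000, prevalence_cv=0.0, seed=3)
        profile = PatientProfile("p", {"f": "x"})
        se1 = mc_log_se(profile, _binary_study(sigma=0.2), _prev(), cfg)
        se2 = mc_log_se(profile, _binary_study(sigma=0.4), _prev(), cfg)
        assert se2 == pytest.approx(2 * se1, rel=1e-9)

    def test_doubling_reps_stays_within_mc_error(self):
        study = _binary_study(or_value=2.0, sigma=0.3)
        profile = PatientProfile("p", {"f": "x"})
        cfg1 = ModelConfig(n_reps=5000, prevalence_cv=0.0, seed=5)
        cfg2 = ModelConfig(n_reps=10_000, prevalence_cv=0.0, seed=5)
        se1 = mc_log_se(profile, study, _prev(), cfg1)
        se2 = mc_log_se(profile, study, _prev(), cfg2)
        mc_err = math.hypot(se1 / math.sqrt(2 * 5000), se2 / math.sqrt(2 * 10_000))
        assert abs(se1 - se2) < 3 * mc_err

    def test_infeasible_beta_cv_advises_smaller(self):
        study = _binary_study()
        cfg = ModelConfig(n_reps=500, prevalence_cv=3.0, seed=1)
        profile = PatientProfile("p", {"f": "x"})
        with pytest.raises(ValueError, match="smaller prevalence CV"):
            mc_log_se(profile, study, _prev(0.5), cfg)


def dl_brute_force(points, log_ses, ci_level=0.95):
    """Independent DerSimonian-Laird implementation: plain loops, no numpy."""
    from scipy.stats import norm as _norm

    ells = [math.log(p) for p in points]
    vs = [s * s for s in log_ses]
    ws = [1.0 / v for v in vs]
    mean_fixed = sum(w * e for w, e in zip(ws, ells)) / sum(ws)
    q = sum(w * (e - mean_fixed) ** 2 for w, e in zip(ws, ells))
    c = sum(ws) - sum(w * w for w in ws) / sum(ws)
    tau2 = max(0.0, (q - (len(ells) - 1)) / c) if c > 0 else 0.0
    wstar = [1.0 / (v + tau2) for v in vs]
    pooled = sum(w * e for w, e in zip(wstar, ells)) / sum(wstar)
    se = math.sqrt(1.0 / sum(wstar))
    z = _norm.ppf(0.5 + ci_level / 2)
    return math.exp(pooled), math.exp(pooled - z * se), math.exp(pooled + z * se), tau2


class TestRandomEffects:
    def _risks(self, points, ses):
        return [
            StudyRisk(f"s{i}", baseline=1e-4, point=p, log_se=s, n_factors_used=2)
            for i, (p, s) in enumerate(zip(points, ses))
        ]

    def test_single_study_passthrough(self):
        pooled = pool_random_effects(self._risks([1e-4], [0.2]), ModelConfig())
        assert pooled.point == pytest.approx(1e-4)
        assert pooled.ci_low == pytest.approx(1e-4 * math.exp(-1.959963985 * 0.2), rel=1e-6)
        assert pooled.tau2 == 0.0
        assert any("single study" in n for n in pooled.notes)

    def test_two_studies_q_below_df_gives_zero_tau2(self):
        # equal SEs and nearly equal log-risks: Q <= 1 = df, so tau2 = 0
        p1, p2 = 1e-4, 1.1e-4
        pooled = pool_random_effects(self._risks([p1, p2], [0.3, 0.3]), ModelConfig())
        assert pooled.tau2 == 0.0
        assert pooled.point == pytest.approx(
            math.exp((math.log(p1) + math.log(p2)) / 2), rel=1e-12
        )

    @pytest.mark.parametrize("k", [1, 2, 5, 11])
    def test_matches_brute_force_oracle(self, k):
        rng = np.random.default_rng(k)
        points = np.exp(rng.normal(math.log(1e-4), 0.8, size=k))
        ses = rng.uniform(0.1, 0.6, size=k)
        pooled = pool_random_effects(
            self._risks(list(points), list(ses)), ModelConfig()
        )
        bp, blo, bhi, btau2 = dl_brute_force(list(points), list(ses))
        assert pooled.point == pytest.approx(bp, rel=1e-12)
        assert pooled.tau2 == pytest.approx(btau2, rel=1e-12, abs=1e-15)
        if k > 1:
            assert pooled.ci_low == pytest.approx(blo, rel=1e-9)
            assert pooled.ci_high == pytest.approx(bhi, rel=1e-9)

    def test_matches_statsmodels_dl(self):
        rng = np.random.default_rng(7)
        k = 6
        ells = rng.normal(math.log(1e-4), 0.7, size=k)
        ses = rng.uniform(0.15, 0.5, size=k)
        pooled = pool_random_effects(
            self._risks(list(np.exp(ells)), list(ses)), ModelConfig()
        )
        res = combine_effects(ells, ses**2, method_re="dl")
        assert pooled.tau2 == pytest.approx(res.tau2, rel=1e-10)
        assert math.log(pooled.point) == pytest.approx(res.mean_effect_re, rel=1e-10)

    def test_reml_flag_runs_and_brackets_dl(self):
        rng = np.random.default_rng(9)
        points = list(np.exp(rng.normal(math.log(1e-4), 0.9, size=5)))
        ses = list(rng.uniform(0.1, 0.4, size=5))
        reml = pool_random_effects(
            self._risks(points, ses), ModelConfig(re_method="reml")
        )
        assert reml.tau2 >= 0
        assert reml.ci_low < reml.point < reml.ci_high


class TestPredict:
    def _inputs(self):
        ests1 = [
            StudyEstimate("s1", "f", "x", "or", 2.0, mu=math.log(2), sigma=0.2),
            StudyEstimate("s1", "g", "y", "or", 3.0, mu=math.log(3), sigma=0.3),
        ]
        ests2 = [
            StudyEstimate("s2", "f", "x", "or", 2.5, mu=math.log(2.5), sigma=0.25),
            StudyEstimate("s2", "g", "y", "or", 2.8, mu=math.log(2.8), sigma=0.2),
        ]
        prev = PrevalenceTable(
            [
                PrevalenceRecord("f", "x", 0.3),
                PrevalenceRecord("f", "ref", 0.7),
                PrevalenceRecord("g", "y", 0.2),
                PrevalenceRecord("g", "ref", 0.8),
            ]
        )
        return [Study("s1", ests1), Study("s2", ests2)], prev

    def test_reference_profile_with_unit_ors_returns_r0(self):
        studies = [
            Study("s1", [
                StudyEstimate("s1", "f", "x", "or", 1.0, mu=0.0, sigma=0.1),
                StudyEstimate("s1", "g", "y", "or", 1.0, mu=0.0, sigma=0.1),
            ])
        ]
        prev = PrevalenceTable(
            [
                PrevalenceRecord("f", "x", 0.3),
                PrevalenceRecord("f", "ref", 0.7),
                PrevalenceRecord("g", "y", 0.2),
                PrevalenceRecord("g", "ref", 0.8),
            ]
        )
        profile = PatientProfile("p", {"f": "ref", "g": "ref"})
        with pytest.warns(UserWarning, match="no eligible study covers"):
            pooled = predict(profile, studies, prev, ModelConfig(n_reps=500, seed=2))
        assert pooled.point == pytest.approx(R0, rel=1e-12)

    def test_monotone_in_additional_risk_level(self):
        studies, prev = self._inputs()
        cfg = ModelConfig(n_reps=500, seed=2)
        base = predict(PatientProfile("p", {"f": "x", "g": "ref"}), studies, prev, cfg)
        more = predict(PatientProfile("p", {"f": "x", "g": "y"}), studies, prev, cfg)
        assert more.point > base.point

    def test_pooled_point_within_study_hull(self):
        studies, prev = self._inputs()
        cfg = ModelConfig(n_reps=500, seed=2)
        pooled = predict(PatientProfile("p", {"f": "x", "g": "y"}), studies, prev, cfg)
        pts = [s.point for s in pooled.per_study]
        assert min(pts) <= pooled.point <= max(pts)

    def test_predict_many_matches_predict(self):
        studies, prev = self._inputs()
        cfg = ModelConfig(n_reps=500, seed=2)
        profiles = [
            PatientProfile("a", {"f": "x", "g": "ref"}),
            PatientProfile("b", {"f": "ref", "g": "y"}),
        ]
        batch = predict_many(profiles, studies, prev, cfg)
        solo = [predict(p, studies, prev, cfg) for p in profiles]
        for x, y in zip(batch, solo):
            assert x.point == y.point
            assert x.ci_low == y.ci_low
            assert x.tau2 == y.tau2

    def test_report_shape(self):
        studies, prev = self._inputs()
        cfg = ModelConfig(n_reps=500, seed=2)
        pooled = predict(PatientProfile("p", {"f": "x", "g": "y"}), studies, prev, cfg)
        rep = pooled.to_report(cfg.r0)
        assert set(rep) >= {"point", "ci", "ratio_to_r0", "tau2", "per_study"}
        assert rep["ratio_to_r0"] == round(pooled.point / cfg.r0, 2)
        assert len(rep["per_study"]) == 2
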