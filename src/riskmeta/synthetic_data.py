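"""Synthetic study tables, prevalence tables and patient profiles.

The generators stand in for the model's real inputs: a set of case-control
studies with partially overlapping risk-factor coverage, lognormally
distributed odds ratios whose variability information is censored into the
reporting patterns found in the literature (full CI, p-value only,
chi-square + totals only, regression coefficient), a population prevalence
table, and patient profiles drawn from those prevalences under high-level
dependency constraints (e.g. a first delivery at least 9 months after sexual
debut).

The default specification mirrors the scale of the cervical-cancer evidence
base the model was built for: 11 studies, 17 risk factors, ~140 estimate
rows, with HPV infection a dominant binary factor (large true OR) so that
qualitative sensitivity findings are reproducible as properties.

Profile generation keeps categorical marginals exact while honouring
constraints by *comonotonic coupling*: factors in a linked group share one
uniform variate, and the default level layouts are arranged so the coupled
quantile functions can never violate the declared minimum gaps. Rejection
resampling remains as a guard for user-specified layouts without that
property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .study_data import (
    NOT_APPLICABLE,
    ContingencyTable,
    PatientProfile,
    PrevalenceRecord,
    PrevalenceTable,
    RiskFactor,
    Study,
    StudyEstimate,
)

__all__ = [
    "GeneratorSpec",
    "default_spec",
    "generate_studies",
    "generate_profiles",
    "table1_fixture",
    "true_risk",
]

REPORTING_PATTERNS = ("ci", "pvalue", "chi2", "coefficient")


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything the synthetic generators need, with validated invariants.

    ``true_log_or`` and ``prevalence`` are keyed by (factor_id, level);
    prevalences include the reference level and form a simplex per factor.
    ``linked_groups`` lists factors that share one uniform variate when
    sampling profiles; ``constraints`` are ``(earlier, later, min_gap)``
    triples on the continuous attributes declared in ``continuous_bins``.
    """

    factors: tuple[RiskFactor, ...]
    true_log_or: Mapping[tuple[str, str], float]
    prevalence: Mapping[tuple[str, str], float]
    tiers: Mapping[str, int] = field(default_factory=dict)
    n_studies: int = 11
    between_study_sd: float = 0.15
    reporting_probs: Mapping[str, float] = field(
        default_factory=lambda: {"ci": 0.55, "pvalue": 0.20, "chi2": 0.15, "coefficient": 0.10}
    )
    factors_per_study: tuple[int, int] = (5, 9)
    coverage_probs: Mapping[str, float] | None = None
    cases_range: tuple[int, int] = (100, 400)
    controls_range: tuple[int, int] = (200, 800)
    continuous_bins: Mapping[str, tuple[tuple[str, float, float], ...]] = field(
        default_factory=dict
    )
    linked_groups: tuple[tuple[str, ...], ...] = ()
    constraints: tuple[tuple[str, str, float], ...] = ()
    na_block: tuple[float, tuple[str, ...]] = (0.0, ())
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [f.factor_id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate factor ids")
        total_p = sum(self.reporting_probs.get(p, 0.0) for p in REPORTING_PATTERNS)
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError("reporting-pattern probabilities must sum to 1")
        for f in self.factors:
            s = sum(self.prevalence[(f.factor_id, lvl)] for lvl in f.levels)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{f.factor_id}: level prevalences must sum to 1")
            for lvl in f.nonreference_levels:
                if (f.factor_id, lvl) not in self.true_log_or:
                    raise ValueError(f"missing true log-OR for {f.factor_id}/{lvl}")
        if not 2 <= self.factors_per_study[0] <= self.factors_per_study[1] <= len(ids):
            raise ValueError("factors_per_study range invalid (min 2 per study)")
        if self.coverage_probs is not None:
            for fid, p in self.coverage_probs.items():
                if fid not in ids or not (0.0 <= p <= 1.0):
                    raise ValueError(f"invalid coverage probability for {fid!r}")
        # the constraint graph must be acyclic
        edges: dict[str, list[str]] = {}
        for a, b, gap in self.constraints:
            if gap < 0:
                raise ValueError("constraint gaps must be nonnegative")
            edges.setdefault(a, []).append(b)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for nxt in edges.get(node, ()):
                if state.get(nxt) == 1:
                    raise ValueError("constraint graph has a cycle")
                if state.get(nxt) is None:
                    visit(nxt)
            state[node] = 2

        for node in list(edges):
            if state.get(node) is None:
                visit(node)

    def factor(self, factor_id: str) -> RiskFactor:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise KeyError(factor_id)


def _f(factor_id: str, name: str, levels: Sequence[str], ref: str) -> RiskFactor:
    return RiskFactor(factor_id, name, tuple(levels), ref)


def default_spec(seed: int = 0) -> GeneratorSpec:
    """The default 11-study / 17-factor specification (30 non-reference levels).

    Factor list and realistic level layouts follow the cervical-cancer risk
    factors the meta-model covers (sexual behaviour, HPV, screening,
    gestational history, contraception, smoking, education, occupation);
    HPV infection carries a dominant true OR of 15.
    """
    factors = (
        _f("sexual_debut_age", "Age at sexual debut", ("<17", "17_19", ">=20"), ">=20"),
        _f("sex_partners", "Lifetime number of sexual partners", ("1", "2_3", ">=4"), "1"),
        _f("hpv_infection", "HPV infection", ("no", "yes"), "no"),
        _f("screening_history", "Negative cervical smears", ("0", "1_2", ">=3"), "0"),
        _f(
            "screening_interval",
            "Time since last negative smear",
            ("not_screened", "<=2y", ">2y"),
            "not_screened",
        ),
        _f("age_first_pregnancy", "Age at first pregnancy", ("<20", "20_24", ">=25"), ">=25"),
        _f("age_first_delivery", "Age at first delivery", ("<20", "20_24", ">=25"), ">=25"),
        _f("num_pregnancies", "Number of pregnancies", ("<=1", "2", ">=3"), "<=1"),
        _f("num_deliveries", "Number of deliveries", ("<=1", ">=2"), "<=1"),
        _f("contraception", "Contraception method", ("iud", "condom", "none"), "none"),
        _f("years_iud", "Years of IUD use", ("<10", ">=10", "none"), "none"),
        _f("menopause", "Menopause", ("no", "yes"), "no"),
        _f("poor_sexual_hygiene", "Poor sexual hygiene", ("no", "yes"), "no"),
        _f("smoking_index", "Cigarette index", ("0", "1_100", ">100"), "0"),
        _f("secondhand_smoke", "Second-hand smoking", ("no", "yes"), "no"),
        _f(
            "education",
            "Educational level",
            ("below_primary", "primary", "middle", "high", "college"),
            "college",
        ),
        _f("intellectual_job", "Intellectual occupation", ("no", "yes"), "no"),
    )
    true_or = {
        ("sexual_debut_age", "<17"): 2.8,
        ("sexual_debut_age", "17_19"): 1.6,
        ("sex_partners", "2_3"): 1.8,
        ("sex_partners", ">=4"): 3.0,
        ("hpv_infection", "yes"): 15.0,
        ("screening_history", "1_2"): 0.55,
        ("screening_history", ">=3"): 0.35,
        ("screening_interval", "<=2y"): 0.5,
        ("screening_interval", ">2y"): 0.8,
        ("age_first_pregnancy", "<20"): 2.2,
        ("age_first_pregnancy", "20_24"): 1.5,
        ("age_first_delivery", "<20"): 2.0,
        ("age_first_delivery", "20_24"): 1.4,
        ("num_pregnancies", "2"): 1.4,
        ("num_pregnancies", ">=3"): 2.0,
        ("num_deliveries", ">=2"): 1.7,
        ("contraception", "iud"): 1.3,
        ("contraception", "condom"): 0.7,
        ("years_iud", "<10"): 1.2,
        ("years_iud", ">=10"): 1.5,
        ("menopause", "yes"): 1.8,
        ("poor_sexual_hygiene", "yes"): 2.4,
        ("smoking_index", "1_100"): 1.8,
        ("smoking_index", ">100"): 2.6,
        ("secondhand_smoke", "yes"): 2.2,
        ("education", "below_primary"): 2.5,
        ("education", "primary"): 1.9,
        ("education", "middle"): 1.5,
        ("education", "high"): 1.2,
        ("intellectual_job", "yes"): 0.6,
    }
    prevalence = {
        ("sexual_debut_age", "<17"): 0.12,
        ("sexual_debut_age", "17_19"): 0.38,
        ("sexual_debut_age", ">=20"): 0.50,
        ("sex_partners", "1"): 0.70,
        ("sex_partners", "2_3"): 0.25,
        ("sex_partners", ">=4"): 0.05,
        ("hpv_infection", "no"): 0.88,
        ("hpv_infection", "yes"): 0.12,
        ("screening_history", "0"): 0.55,
        ("screening_history", "1_2"): 0.25,
        ("screening_history", ">=3"): 0.20,
        ("screening_interval", "not_screened"): 0.55,
        ("screening_interval", "<=2y"): 0.27,
        ("screening_interval", ">2y"): 0.18,
        ("age_first_pregnancy", "<20"): 0.20,
        ("age_first_pregnancy", "20_24"): 0.55,
        ("age_first_pregnancy", ">=25"): 0.25,
        ("age_first_delivery", "<20"): 0.15,
        ("age_first_delivery", "20_24"): 0.55,
        ("age_first_delivery", ">=25"): 0.30,
        ("num_pregnancies", "<=1"): 0.30,
        ("num_pregnancies", "2"): 0.35,
        ("num_pregnancies", ">=3"): 0.35,
        ("num_deliveries", "<=1"): 0.55,
        ("num_deliveries", ">=2"): 0.45,
        ("contraception", "iud"): 0.35,
        ("contraception", "condom"): 0.15,
        ("contraception", "none"): 0.50,
        ("years_iud", "<10"): 0.20,
        ("years_iud", ">=10"): 0.15,
        ("years_iud", "none"): 0.65,
        ("menopause", "no"): 0.62,
        ("menopause", "yes"): 0.38,
        ("poor_sexual_hygiene", "no"): 0.60,
        ("poor_sexual_hygiene", "yes"): 0.40,
        ("smoking_index", "0"): 0.95,
        ("smoking_index", "1_100"): 0.03,
        ("smoking_index", ">100"): 0.02,
        ("secondhand_smoke", "no"): 0.45,
        ("secondhand_smoke", "yes"): 0.55,
        ("education", "below_primary"): 0.10,
        ("education", "primary"): 0.20,
        ("education", "middle"): 0.35,
        ("education", "high"): 0.20,
        ("education", "college"): 0.15,
        ("intellectual_job", "no"): 0.75,
        ("intellectual_job", "yes"): 0.25,
    }
    tiers = {
        "sexual_debut_age": 1,
        "sex_partners": 2,
        "hpv_infection": 2,
        "screening_history": 4,
        "screening_interval": 2,
        "age_first_pregnancy": 1,
        "age_first_delivery": 1,
        "num_pregnancies": 1,
        "num_deliveries": 1,
        "contraception": 1,
        "years_iud": 2,
        "menopause": 1,
        "poor_sexual_hygiene": 2,
        "smoking_index": 1,
        "secondhand_smoke": 2,
        "education": 1,
        "intellectual_job": 1,
    }
    # reporting frequency differs by factor: smoking, sexual debut, number of
    # deliveries and HPV are covered by most studies, the rest sporadically
    coverage = {
        "sexual_debut_age": 0.82,
        "sex_partners": 0.40,
        "hpv_infection": 0.73,
        "screening_history": 0.40,
        "screening_interval": 0.35,
        "age_first_pregnancy": 0.40,
        "age_first_delivery": 0.40,
        "num_pregnancies": 0.60,
        "num_deliveries": 0.82,
        "contraception": 0.40,
        "years_iud": 0.35,
        "menopause": 0.45,
        "poor_sexual_hygiene": 0.40,
        "smoking_index": 0.82,
        "secondhand_smoke": 0.25,
        "education": 0.20,
        "intellectual_job": 0.35,
    }
    continuous_bins = {
        "sexual_debut_age": (("<17", 14.0, 17.0), ("17_19", 17.0, 20.0), (">=20", 20.0, 26.0)),
        "age_first_pregnancy": (
            ("<20", 16.0, 19.25),
            ("20_24", 19.75, 24.25),
            (">=25", 24.75, 33.0),
        ),
        "age_first_delivery": (
            ("<20", 17.0, 20.0),
            ("20_24", 20.5, 25.0),
            (">=25", 25.5, 34.0),
        ),
    }
    return GeneratorSpec(
        factors=factors,
        true_log_or={k: math.log(v) for k, v in true_or.items()},
        prevalence=prevalence,
        tiers=tiers,
        coverage_probs=coverage,
        continuous_bins=continuous_bins,
        linked_groups=(
            ("sexual_debut_age", "age_first_pregnancy", "age_first_delivery"),
            ("screening_history", "screening_interval"),
            ("contraception", "years_iud"),
            ("num_pregnancies", "num_deliveries"),
        ),
        constraints=(
            ("sexual_debut_age", "age_first_delivery", 0.75),
            ("age_first_pregnancy", "age_first_delivery", 0.75),
        ),
        na_block=(
            0.17,
            (
                "age_first_pregnancy",
                "age_first_delivery",
                "num_pregnancies",
                "num_deliveries",
            ),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Study generation


def _level_table(
    n_cases: int, n_controls: int, p_level: float, p_ref: float, odds_ratio: float
) -> ContingencyTable:
    """Level-vs-reference 2x2 table with the requested odds ratio.

    Controls follow the population split between the level and the
    reference; cases are tilted by the odds ratio. Cells are rounded to
    integers (minimum 1) so the reported summary statistics are coherent.
    """
    b = n_controls * p_level
    d = n_controls * p_ref
    m = n_cases * (p_level + p_ref)
    a = m * odds_ratio * b / (odds_ratio * b + d)
    c = m - a
    cells = [max(1, round(x)) for x in (a, b, c, d)]
    return ContingencyTable(*[float(x) for x in cells])


def generate_studies(
    spec: GeneratorSpec, seed: int | None = None
) -> tuple[list[Study], PrevalenceTable, dict]:
    """Generate synthetic studies, a prevalence table and the truth record.

    Each study reports a random subset (>= 2) of factors; per-study log-ORs
    are the truth plus between-study noise; the variability information of
    each estimate is censored down to one reporting pattern so that every
    imputation route is exercised. The truth record retains all generative
    values.
    """
    base = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base & 0x7FFFFFFF, 101]))
    patterns = list(REPORTING_PATTERNS)
    probs = [spec.reporting_probs.get(p, 0.0) for p in patterns]

    studies: list[Study] = []
    truth_study: dict[tuple[str, str, str], float] = {}
    for k in range(spec.n_studies):
        sid = f"S{k + 1:02d}"
        n_cases = int(rng.integers(spec.cases_range[0], spec.cases_range[1] + 1))
        n_controls = int(rng.integers(spec.controls_range[0], spec.controls_range[1] + 1))
        if spec.coverage_probs is not None:
            while True:
                mask = [
                    rng.uniform() < spec.coverage_probs.get(f.factor_id, 0.5)
                    for f in spec.factors
                ]
                if sum(mask) >= 2:
                    break
            chosen = [i for i, m in enumerate(mask) if m]
        else:
            n_f = int(
                rng.integers(spec.factors_per_study[0], spec.factors_per_study[1] + 1)
            )
            chosen = sorted(rng.choice(len(spec.factors), size=n_f, replace=False))
        estimates: list[StudyEstimate] = []
        for fi in chosen:
            factor = spec.factors[fi]
            ref = factor.reference_level
            p_ref = spec.prevalence[(factor.factor_id, ref)]
            for lvl in factor.nonreference_levels:
                mu = spec.true_log_or[(factor.factor_id, lvl)]
                if spec.between_study_sd > 0:
                    mu = mu + rng.normal(0.0, spec.between_study_sd)
                truth_study[(sid, factor.factor_id, lvl)] = mu
                p_lvl = spec.prevalence[(factor.factor_id, lvl)]
                table = _level_table(n_cases, n_controls, p_lvl, p_ref, math.exp(mu))
                sigma = math.sqrt(
                    1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d
                )
                pattern = patterns[int(rng.choice(len(patterns), p=probs))]
                if pattern == "pvalue" and mu == 0.0:
                    pattern = "ci"
                if pattern == "chi2" and (
                    abs(table.risk_ratio - 1.0) < 1e-9 or table.chi2 <= 0
                ):
                    pattern = "ci"
                common = dict(
                    study_id=sid,
                    factor_id=factor.factor_id,
                    level=lvl,
                    adjusted=True,
                    control_prevalence=p_lvl,
                )
                if pattern == "ci":
                    half = 1.96 * sigma
                    center = mu + sigma**2 / 2.0
                    est = StudyEstimate(
                        estimate_type="or",
                        value=math.exp(mu),
                        ci_low=math.exp(center - half),
                        ci_high=math.exp(center + half),
                        **common,
                    )
                elif pattern == "pvalue":
                    p = 2.0 * float(norm.sf(abs(mu) / sigma))
                    p = min(max(p, 1e-12), 0.999)
                    est = StudyEstimate(
                        estimate_type="or", value=math.exp(mu), p_value=p, **common
                    )
                elif pattern == "chi2":
                    # the subtable's cohort-style ratio, treated as an OR the
                    # way a reader relabels a published RR
                    est = StudyEstimate(
                        estimate_type="or",
                        value=table.risk_ratio,
                        chi2=table.chi2,
                        n_cases=int(table.a + table.c),
                        n_controls=int(table.b + table.d),
                        rr_relabelled=True,
                        **common,
                    )
                else:  # coefficient
                    est = StudyEstimate(
                        estimate_type="coefficient", value=mu, se=sigma, **common
                    )
                estimates.append(est)
        studies.append(Study(sid, estimates))

    records = []
    for f in spec.factors:
        for lvl in f.levels:
            records.append(
                PrevalenceRecord(
                    factor_id=f.factor_id,
                    level=lvl,
                    prevalence=spec.prevalence[(f.factor_id, lvl)],
                    tier=spec.tiers.get(f.factor_id, 1),
                    source_note="synthetic",
                )
            )
    truth = {
        "log_or": dict(spec.true_log_or),
        "study_log_or": truth_study,
        "between_study_sd": spec.between_study_sd,
        "seed": base,
    }
    return studies, PrevalenceTable(records), truth


# ---------------------------------------------------------------------------
# Profile generation


def _group_index(spec: GeneratorSpec) -> dict[str, int]:
    groups: dict[str, int] = {}
    for gi, group in enumerate(spec.linked_groups):
        for fid in group:
            groups[fid] = gi
    nxt = len(spec.linked_groups)
    for f in spec.factors:
        if f.factor_id not in groups:
            groups[f.factor_id] = nxt
            nxt += 1
    return groups


def generate_profiles(
    spec: GeneratorSpec, n: int, seed: int | None = None, max_attempts: int = 200
) -> list[PatientProfile]:
    """Draw ``n`` patient profiles from the population prevalences.

    Categorical levels follow the prevalence simplex of each factor; linked
    factors share one uniform variate (comonotonic coupling) so constrained
    chains stay consistent; continuous attributes are drawn uniformly within
    the chosen bin and checked against every declared minimum-gap
    constraint, resampling the whole profile on violation. Profiles depend
    only on (seed, index), so any generation order yields the same multiset.
    """
    base = spec.seed if seed is None else seed
    groups = _group_index(spec)
    na_prob, na_factors = spec.na_block
    out: list[PatientProfile] = []
    for i in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence([base & 0x7FFFFFFF, 202, i])
        )
        for _ in range(max_attempts):
            us = {gi: rng.uniform() for gi in sorted(set(groups.values()))}
            na_active = na_prob > 0 and rng.uniform() < na_prob
            assignments: dict[str, str] = {}
            attributes: dict[str, float] = {}
            for f in spec.factors:
                if na_active and f.factor_id in na_factors:
                    assignments[f.factor_id] = NOT_APPLICABLE
                    continue
                u = us[groups[f.factor_id]]
                cum = 0.0
                level = f.levels[-1]
                frac = 0.0
                for lvl in f.levels:
                    p = spec.prevalence[(f.factor_id, lvl)]
                    if u < cum + p or lvl == f.levels[-1]:
                        level = lvl
                        frac = min(max((u - cum) / p, 0.0), 1.0)
                        break
                    cum += p
                assignments[f.factor_id] = level
                bins = spec.continuous_bins.get(f.factor_id)
                if bins:
                    for blvl, lo, hi in bins:
                        if blvl == level:
                            attributes[f.factor_id] = lo + frac * (hi - lo)
                            break
            ok = True
            for fa, fb, gap in spec.constraints:
                if fa in attributes and fb in attributes:
                    if attributes[fb] < attributes[fa] + gap - 1e-12:
                        ok = False
                        break
            if ok:
                out.append(PatientProfile(f"P{i:04d}", assignments, attributes))
                break
        else:
            raise RuntimeError(
                f"profile {i}: constraints unsatisfiable after {max_attempts} attempts"
            )
    return out


def true_risk(
    profile: PatientProfile, spec: GeneratorSpec, r0: float = 0.000094
) -> float:
    """Generative risk of a profile under the spec's true log-ORs.

    Baseline-calibrated exactly like the model: r0 divided by the
    prevalence-weighted geometric OR product, times the profile's OR product.
    """
    log_avg = sum(
        spec.prevalence[(fid, lvl)] * b for (fid, lvl), b in spec.true_log_or.items()
    )
    mult = 0.0
    for f in spec.factors:
        lvl = profile.level(f.factor_id)
        if lvl == NOT_APPLICABLE or lvl == f.reference_level:
            continue
        mult += spec.true_log_or[(f.factor_id, lvl)]
    return r0 / math.exp(log_avg) * math.exp(mult)


# ---------------------------------------------------------------------------
# The eight hypothetical validation profiles


def table1_fixture() -> list[PatientProfile]:
    """Eight hypothetical women spanning low- to high-risk profiles.

    Level identifiers follow :func:`default_spec`; continuous source values
    (ages, cigarette index, IUD years) are retained in ``attributes``.
    ``not_applicable`` marks factors that cannot apply (e.g. gestational
    factors for never-pregnant women, IUD years for non-IUD users).
    """
    NA = NOT_APPLICABLE
    rows: list[tuple[dict[str, str], dict[str, float]]] = [
        (
            {
                "sexual_debut_age": "17_19",
                "sex_partners": "2_3",
                "hpv_infection": "yes",
                "screening_history": ">=3",
                "screening_interval": "<=2y",
                "age_first_pregnancy": "20_24",
                "age_first_delivery": "20_24",
                "num_pregnancies": "<=1",
                "num_deliveries": "<=1",
                "contraception": "condom",
                "years_iud": NA,
                "menopause": "no",
                "poor_sexual_hygiene": "yes",
                "smoking_index": "1_100",
                "secondhand_smoke": "yes",
                "education": "below_primary",
                "intellectual_job": "no",
            },
            {
                "sexual_debut_age": 19,
                "age_first_pregnancy": 21,
                "age_first_delivery": 22,
                "smoking_index": 50,
            },
        ),
        (
            {
                "sexual_debut_age": ">=20",
                "sex_partners": "2_3",
                "hpv_infection": "no",
                "screening_history": NA,
                "screening_interval": NA,
                "age_first_pregnancy": "20_24",
                "age_first_delivery": "20_24",
                "num_pregnancies": "2",
                "num_deliveries": "<=1",
                "contraception": "none",
                "years_iud": NA,
                "menopause": "no",
                "poor_sexual_hygiene": "yes",
                "smoking_index": ">100",
                "secondhand_smoke": "no",
                "education": "college",
                "intellectual_job": "no",
            },
            {
                "sexual_debut_age": 20,
                "age_first_pregnancy": 21.5,
                "age_first_delivery": 22.5,
                "smoking_index": 250,
            },
        ),
        (
            {
                "sexual_debut_age": "<17",
                "sex_partners": "1",
                "hpv_infection": "yes",
                "screening_history": NA,
                "screening_interval": NA,
                "age_first_pregnancy": NA,
                "age_first_delivery": NA,
                "num_pregnancies": NA,
                "num_deliveries": NA,
                "contraception": "condom",
                "years_iud": NA,
                "menopause": "no",
                "poor_sexual_hygiene": "no",
                "smoking_index": "0",
                "secondhand_smoke": "yes",
                "education": "middle",
                "intellectual_job": "yes",
            },
            {"sexual_debut_age": 16},
        ),
        (
            {
                "sexual_debut_age": "17_19",
                "sex_partners": "2_3",
                "hpv_infection": "no",
                "screening_history": "1_2",
                "screening_interval": NA,
                "age_first_pregnancy": ">=25",
                "age_first_delivery": ">=25",
                "num_pregnancies": "<=1",
                "num_deliveries": "<=1",
                "contraception": "none",
                "years_iud": NA,
                "menopause": "no",
                "poor_sexual_hygiene": "no",
                "smoking_index": "0",
                "secondhand_smoke": "no",
                "education": "high",
                "intellectual_job": "no",
            },
            {
                "sexual_debut_age": 19,
                "age_first_pregnancy": 27,
                "age_first_delivery": 28,
            },
        ),
        (
            {
                "sexual_debut_age": "17_19",
                "sex_partners": "1",
                "hpv_infection": "no",
                "screening_history": NA,
                "screening_interval": NA,
                "age_first_pregnancy": "<20",
                "age_first_delivery": "<20",
                "num_pregnancies": ">=3",
                "num_deliveries": ">=2",
                "contraception": "iud",
                "years_iud": ">=10",
                "menopause": "yes",
                "poor_sexual_hygiene": "no",
                "smoking_index": "0",
                "secondhand_smoke": "yes",
                "education": "below_primary",
                "intellectual_job": "no",
            },
            {
                "sexual_debut_age": 18,
                "age_first_pregnancy": 18,
                "age_first_delivery": 19,
                "years_iud": 15,
            },
        ),
        (
            {
                "sexual_debut_age": ">=20",
                "sex_partners": "1",
                "hpv_infection": "no",
                "screening_history": "1_2",
                "screening_interval": "<=2y",
                "age_first_pregnancy": ">=25",
                "age_first_delivery": ">=25",
                "num_pregnancies": "<=1",
                "num_deliveries": "<=1",
                "contraception": "iud",
                "years_iud": "<10",
                "menopause": "no",
                "poor_sexual_hygiene": "yes",
                "smoking_index": "1_100",
                "secondhand_smoke": "yes",
                "education": "high",
                "intellectual_job": "yes",
            },
            {
                "sexual_debut_age": 21,
                "age_first_pregnancy": 25,
                "age_first_delivery": 26,
                "years_iud": 9,
                "smoking_index": 50,
            },
        ),
        (
            {
                "sexual_debut_age": ">=20",
                "sex_partners": "2_3",
                "hpv_infection": "yes",
                "screening_history": NA,
                "screening_interval": NA,
                "age_first_pregnancy": "20_24",
                "age_first_delivery": "20_24",
                "num_pregnancies": "2",
                "num_deliveries": ">=2",
                "contraception": "none",
                "years_iud": NA,
                "menopause": "yes",
                "poor_sexual_hygiene": "no",
                "smoking_index": "0",
                "secondhand_smoke": "yes",
                "education": "middle",
                "intellectual_job": "no",
            },
            {
                "sexual_debut_age": 20,
                "age_first_pregnancy": 20,
                "age_first_delivery": 21,
            },
        ),
        (
            {
                "sexual_debut_age": "17_19",
                "sex_partners": "1",
                "hpv_infection": "no",
                "screening_history": NA,
                "screening_interval": NA,
                "age_first_pregnancy": NA,
                "age_first_delivery": NA,
                "num_pregnancies": NA,
                "num_deliveries": NA,
                "contraception": "none",
                "years_iud": NA,
                "menopause": "no",
                "poor_sexual_hygiene": "no",
                "smoking_index": "0",
                "secondhand_smoke": "no",
                "education": "below_primary",
                "intellectual_job": "yes",
            },
            {"sexual_debut_age": 19},
        ),
    ]
    return [
        PatientProfile(f"profile_{i}", assignments, attributes)
        for i, (assignments, attributes) in enumerate(rows, start=1)
    ]
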