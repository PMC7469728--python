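"""The meta-model core: calibration, patient risk, Monte Carlo SE, pooling.

For each study *k* the model calibrates a baseline risk for the *reference
patient* (every factor at its reference level)::

    R0k = R0 / exp( sum over the study's non-reference levels of
                    prevalence * ln OR )

where ``R0`` is the population probability of disease (default 0.000094, the
probability of cervical cancer for a Chinese woman aged 18-85). The divisor
is the relative risk of the population-average woman versus the reference
patient — the prevalence-weighted geometric product of the study's odds
ratios — so the population-average woman's risk equals ``R0`` exactly in
every study (the calibration identity).

A patient's study-specific risk multiplies the baseline by the odds ratios
matching her levels::

    Rik = ( prod_j OR_jk ) * R0k

The within-study uncertainty of ``ln Rik`` is propagated by Monte Carlo:
log-ORs are drawn normally ``N(mu_jk, sigma_jk)``, prevalences from Beta
distributions with coefficient of variation ``prevalence_cv`` (renormalised
within each factor), the baseline and patient risks are recomputed per
replicate, and ``sigma_ik`` is the sample SD of the simulated log risks.
Study risks are finally pooled on the log scale by a random-effects
meta-analysis (DerSimonian-Laird by default) and back-transformed.

Randomness is reproducible and removal-stable: every (study, factor) pair
draws from its own substream derived from the seed, so leave-one-study-out or
leave-one-factor-out scenarios reuse identical draws for what remains.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .study_data import (
    NOT_APPLICABLE,
    PatientProfile,
    PrevalenceTable,
    RiskFactor,
    Study,
)

__all__ = [
    "ModelConfig",
    "StudyRisk",
    "PooledRisk",
    "baseline_risk",
    "patient_study_risk",
    "mc_log_se",
    "pool_random_effects",
    "predict",
    "predict_many",
    "load_config",
]


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration of the meta-model.

    r0
        population probability of disease over the modelled age range;
        default 0.000094 (cervical cancer, Chinese women aged 18-85).
    n_reps
        Monte Carlo replications for the within-study SE; default 10,000.
    prevalence_cv
        coefficient of variation of each sampled prevalence; default 0.1.
    seed
        base RNG seed; substreams are derived per (study, factor).
    ci_level
        coverage of the pooled interval; default 0.95.
    re_method
        heterogeneity estimator, ``"dl"`` (DerSimonian-Laird) or ``"reml"``.
    """

    r0: float = 0.000094
    n_reps: int = 10_000
    prevalence_cv: float = 0.1
    seed: int = 0
    ci_level: float = 0.95
    re_method: str = "dl"

    def __post_init__(self) -> None:
        if not (0.0 < self.r0 < 1.0):
            raise ValueError("r0 must lie in (0, 1)")
        if self.n_reps < 100:
            raise ValueError("n_reps must be at least 100")
        if self.prevalence_cv < 0:
            raise ValueError("prevalence_cv must be nonnegative")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.re_method not in ("dl", "reml"):
            raise ValueError('re_method must be "dl" or "reml"')


def load_config(path: str | Path) -> ModelConfig:
    """Load a :class:`ModelConfig` from a YAML or JSON mapping."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    return ModelConfig(**(data or {}))


@dataclass(frozen=True)
class StudyRisk:
    """Per-study prediction: baseline, point risk and Monte Carlo log-SE."""

    study_id: str
    baseline: float
    point: float
    log_se: float
    n_factors_used: int

    def __post_init__(self) -> None:
        if not self.point > 0:
            raise ValueError("study risk must be positive")
        if self.log_se < 0:
            raise ValueError("log_se must be nonnegative")


@dataclass(frozen=True)
class PooledRisk:
    """Random-effects pooled risk with its interval and heterogeneity."""

    point: float
    ci_low: float
    ci_high: float
    tau2: float
    per_study: tuple[StudyRisk, ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")

    @property
    def relative_ci_width(self) -> float:
        return (self.ci_high - self.ci_low) / self.point

    def ratio_to(self, r0: float) -> float:
        return self.point / r0

    def to_report(self, r0: float) -> dict:
        return {
            "point": self.point,
            "ci": [self.ci_low, self.ci_high],
            "ratio_to_r0": round(self.point / r0, 2),
            "tau2": self.tau2,
            "per_study": [
                {"study_id": s.study_id, "point": s.point, "log_se": s.log_se}
                for s in self.per_study
            ],
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# Reference-level inference


def reference_levels(
    studies: Sequence[Study],
    prevalences: PrevalenceTable,
    factors: Sequence[RiskFactor] | None = None,
) -> dict[str, set[str]]:
    """Reference (multiplier-1) levels per factor.

    With explicit factor definitions the declared reference is used;
    otherwise any level present in the prevalence table but estimated by no
    study is treated as reference — a level no study models cannot
    contribute an odds ratio.
    """
    if factors is not None:
        return {f.factor_id: {f.reference_level} for f in factors}
    estimated: dict[str, set[str]] = {}
    for study in studies:
        for est in study.estimates:
            estimated.setdefault(est.factor_id, set()).add(est.level)
    out: dict[str, set[str]] = {}
    for fid in prevalences.factors():
        out[fid] = set(prevalences.levels(fid)) - estimated.get(fid, set())
    for fid, levels in estimated.items():
        out.setdefault(fid, set())
    return out


# ---------------------------------------------------------------------------
# Deterministic risk equations


def baseline_risk(
    study: Study, prevalences: PrevalenceTable, config: ModelConfig
) -> float:
    """Calibrated reference-patient risk ``R0k`` for one study."""
    log_rr_avg = 0.0
    for est in study.estimates:
        try:
            prev = prevalences.get(est.factor_id, est.level)
        except KeyError:
            raise ValueError(
                f"{study.study_id}: missing prevalence for "
                f"{est.factor_id}/{est.level}"
            ) from None
        log_rr_avg += prev * est.log_or_point
    return config.r0 / math.exp(log_rr_avg)


def patient_study_risk(
    profile: PatientProfile,
    study: Study,
    baseline: float,
    reference: Mapping[str, set[str]] | None = None,
    known_levels: Mapping[str, set[str]] | None = None,
) -> float:
    """Patient- and study-specific risk ``Rik``.

    For every factor the study models, the odds ratio matching the patient's
    level multiplies the baseline; reference or not-applicable levels (and
    factors the study does not model) contribute a factor of 1. A level the
    study does not estimate but that is a genuine non-reference level
    elsewhere raises ``unmapped level``.
    """
    multiplier = 0.0
    for fid in study.factor_ids:
        lvl = profile.level(fid)
        if lvl == NOT_APPLICABLE:
            continue
        est = study.get(fid, lvl)
        if est is not None:
            multiplier += est.log_or_point
            continue
        if reference is not None and lvl in reference.get(fid, set()):
            continue
        if reference is None and (
            known_levels is None or lvl not in known_levels.get(fid, set())
        ):
            continue
        raise ValueError(
            f"unmapped level: {study.study_id} has no estimate for "
            f"{fid}/{lvl} and it is not a reference level"
        )
    return baseline * math.exp(multiplier)


# ---------------------------------------------------------------------------
# Monte Carlo propagation


def _substream(seed: int, study_id: str, factor_id: str) -> np.random.Generator:
    s = zlib.crc32(study_id.encode()) & 0x7FFFFFFF
    f = zlib.crc32(factor_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, s, f]))


def _beta_params(mean: float, cv: float) -> tuple[float, float]:
    var = (cv * mean) ** 2
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"Beta parameters invalid for mean {mean:.4f} with CV {cv}: "
            "variance exceeds mean*(1-mean); use a smaller prevalence CV"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


class _FactorDraws:
    """Replicated draws for one (study, factor): log-ORs and prevalences."""

    __slots__ = ("levels", "log_or", "prev", "baseline_term")

    def __init__(self, study: Study, factor_id: str, prevalences: PrevalenceTable,
                 config: ModelConfig):
        rng = _substream(config.seed, study.study_id, factor_id)
        ests = study.estimates_for(factor_id)
        n = config.n_reps
        self.levels = [e.level for e in ests]
        self.log_or = {}
        for e in ests:
            if e.sigma is None or e.mu is None:
                raise ValueError(
                    f"{study.study_id}/{factor_id}/{e.level}: sigma not imputed"
                )
            self.log_or[e.level] = (
                rng.normal(e.mu, e.sigma, size=n) if e.sigma > 0
                else np.full(n, e.mu)
            )
        # prevalence simplex over every level the table knows for the factor
        all_levels = prevalences.levels(factor_id)
        prev = np.empty((n, len(all_levels)))
        for j, (lvl, p) in enumerate(all_levels.items()):
            if config.prevalence_cv == 0.0:
                prev[:, j] = p
            else:
                a, b = _beta_params(p, config.prevalence_cv)
                prev[:, j] = rng.beta(a, b, size=n)
        prev /= prev.sum(axis=1, keepdims=True)
        self.prev = {lvl: prev[:, j] for j, lvl in enumerate(all_levels)}
        # contribution of this factor to ln R0k per replicate (negated later)
        term = np.zeros(n)
        for lvl in self.levels:
            term += self.prev[lvl] * self.log_or[lvl]
        self.baseline_term = term


class _StudySampler:
    """Caches per-factor draws for one study; shared across profiles."""

    def __init__(self, study: Study, prevalences: PrevalenceTable, config: ModelConfig):
        self.study = study
        self.config = config
        self.factors = {
            fid: _FactorDraws(study, fid, prevalences, config)
            for fid in study.factor_ids
        }
        self.log_baseline = math.log(config.r0) - sum(
            fd.baseline_term for fd in self.factors.values()
        )

    def log_risks(
        self,
        profile: PatientProfile,
        reference: Mapping[str, set[str]] | None,
    ) -> np.ndarray:
        out = self.log_baseline.copy() if isinstance(self.log_baseline, np.ndarray) \
            else np.full(self.config.n_reps, self.log_baseline)
        for fid, fd in self.factors.items():
            lvl = profile.level(fid)
            if lvl == NOT_APPLICABLE:
                continue
            if lvl in fd.log_or:
                out += fd.log_or[lvl]
            elif reference is not None and lvl not in reference.get(fid, set()):
                raise ValueError(
                    f"unmapped level: {self.study.study_id} has no estimate for "
                    f"{fid}/{lvl} and it is not a reference level"
                )
        return out


def _sample_sd(values: np.ndarray) -> float:
    if np.ptp(values) == 0.0:  # degenerate sampling: exactly constant
        return 0.0
    return float(np.std(values, ddof=1))


def mc_log_se(
    profile: PatientProfile,
    study: Study,
    prevalences: PrevalenceTable,
    config: ModelConfig,
    reference: Mapping[str, set[str]] | None = None,
) -> float:
    """Sample SD of the simulated log study risks (within-study SE)."""
    sampler = _StudySampler(study, prevalences, config)
    return _sample_sd(sampler.log_risks(profile, reference))


# ---------------------------------------------------------------------------
# Random-effects pooling


def _dl_tau2(ell: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mean_fixed = np.sum(w * ell) / np.sum(w)
    q = float(np.sum(w * (ell - mean_fixed) ** 2))
    df = len(ell) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - df) / c)


def _reml_tau2(ell: np.ndarray, v: np.ndarray) -> float:
    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * ell) / np.sum(w)
        return 0.5 * (
            float(np.sum(np.log(v + tau2)))
            + math.log(float(np.sum(w)))
            + float(np.sum(w * (ell - mu) ** 2))
        )

    hi = max(1e-8, 10.0 * float(np.var(ell)))
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded")
    return float(max(0.0, res.x))


def pool_random_effects(
    study_risks: Sequence[StudyRisk], config: ModelConfig
) -> PooledRisk:
    """Pool per-study risks on the log scale with a random-effects model.

    DerSimonian-Laird: tau^2 from the fixed-effect Q statistic; weights
    ``1/(sigma_ik^2 + tau^2)``; Wald interval on the log scale,
    back-transformed.
    """
    if not study_risks:
        raise ValueError("no study risks to pool")
    notes: list[str] = []
    z = norm.ppf(0.5 + config.ci_level / 2.0)
    ell = np.array([math.log(s.point) for s in study_risks])
    v = np.array([s.log_se**2 for s in study_risks])
    if len(study_risks) == 1:
        s = study_risks[0]
        se = s.log_se
        notes.append("no heterogeneity estimable from a single study")
        return PooledRisk(
            point=s.point,
            ci_low=s.point * math.exp(-z * se),
            ci_high=s.point * math.exp(z * se),
            tau2=0.0,
            per_study=tuple(study_risks),
            notes=tuple(notes),
        )
    if np.all(v == 0.0):
        # degenerate: no within-study variability anywhere
        tau2 = _dl_tau2(ell, np.ones_like(v)) if np.ptp(ell) > 0 else 0.0
        pooled = float(np.mean(ell))
        se = math.sqrt(tau2 / len(ell))
        notes.append("all within-study variances are zero")
    else:
        v = np.where(v == 0.0, 1e-300, v)
        tau2 = _dl_tau2(ell, v) if config.re_method == "dl" else _reml_tau2(ell, v)
        w = 1.0 / (v + tau2)
        pooled = float(np.sum(w * ell) / np.sum(w))
        se = math.sqrt(1.0 / float(np.sum(w)))
    return PooledRisk(
        point=math.exp(pooled),
        ci_low=math.exp(pooled - z * se),
        ci_high=math.exp(pooled + z * se),
        tau2=tau2,
        per_study=tuple(study_risks),
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Composition


def predict_many(
    profiles: Sequence[PatientProfile],
    studies: Sequence[Study],
    prevalences: PrevalenceTable,
    config: ModelConfig,
    factors: Sequence[RiskFactor] | None = None,
) -> list[PooledRisk]:
    """Predict pooled risks for many profiles, sharing Monte Carlo draws.

    The draws depend only on (seed, study, factor), never on the profile, so
    the per-study replicate matrices are computed once and reused.
    """
    if not studies:
        raise ValueError("no studies supplied")
    ref = reference_levels(studies, prevalences, factors)
    known: dict[str, set[str]] = {}
    for study in studies:
        for est in study.estimates:
            known.setdefault(est.factor_id, set()).add(est.level)
    samplers = [_StudySampler(s, prevalences, config) for s in studies]
    baselines = [baseline_risk(s, prevalences, config) for s in studies]
    out: list[PooledRisk] = []
    for profile in profiles:
        covered = any(
            profile.level(fid) in known.get(fid, set())
            for fid in profile.assignments
        )
        notes: list[str] = []
        if not covered:
            warnings.warn(
                f"{profile.patient_id}: no eligible study covers any "
                "non-reference assignment; prediction equals pooled baselines",
                stacklevel=2,
            )
            notes.append("no study covers any non-reference assignment")
        study_risks = []
        for study, sampler, r0k in zip(studies, samplers, baselines):
            point = patient_study_risk(profile, study, r0k, reference=ref)
            log_se = _sample_sd(sampler.log_risks(profile, ref))
            study_risks.append(
                StudyRisk(
                    study_id=study.study_id,
                    baseline=r0k,
                    point=point,
                    log_se=log_se,
                    n_factors_used=study.n_factors,
                )
            )
        pooled = pool_random_effects(study_risks, config)
        if notes:
            pooled = PooledRisk(
                point=pooled.point,
                ci_low=pooled.ci_low,
                ci_high=pooled.ci_high,
                tau2=pooled.tau2,
                per_study=pooled.per_study,
                notes=pooled.notes + tuple(notes),
            )
        out.append(pooled)
    return out


def predict(
    profile: PatientProfile,
    studies: Sequence[Study],
    prevalences: PrevalenceTable,
    config: ModelConfig,
    factors: Sequence[RiskFactor] | None = None,
) -> PooledRisk:
    """Predict the pooled disease risk for a single patient profile."""
    return predict_many([profile], studies, prevalences, config, factors)[0]
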