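"""Missing-data routines for the log-OR location/scale (mu, sigma).

Published case-control estimates rarely come with a usable standard error of
the log odds ratio. Four recovery routes are implemented, applied in order of
decreasing information content:

``reported``
    the SE of the log-OR (or of a regression coefficient) is given directly;
``from_ci``
    a 95% CI of the OR is given; the bounds are modelled as
    ``exp(mu + sigma^2/2 -/+ 1.96 sigma)`` and inverted in closed form;
``from_pvalue``
    only a p-value is given; the Altman-Bland approximation
    ``z = -0.862 + sqrt(0.743 - 2.404 ln p)`` yields ``sigma = |mu / z|``;
``from_chi2``
    the chi-square statistic and the case/control totals are given; the 2x2
    contingency table is reconstructed numerically and
    ``sigma^2 = 1/a + 1/b + 1/c + 1/d``.

A regression coefficient is converted to an odds ratio with the unbiased mean
estimate ``OR = exp(mu + sigma^2/2)``.

Prevalences missing from a study are imputed from the control groups of the
other studies (tier 4), falling back to an external population table; a level
with no source anywhere is signalled for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import replace
from statistics import fmean
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .study_data import (
    ContingencyTable,
    ImputationTrace,
    PrevalenceRecord,
    PrevalenceTable,
    Study,
    StudyEstimate,
)

__all__ = [
    "or_from_coefficient",
    "sigma_from_ci",
    "sigma_from_pvalue",
    "solve_contingency",
    "var_logor_from_table",
    "impute_estimate",
    "impute_studies",
    "impute_prevalence",
    "PrevalenceUnavailable",
]

Z_95 = 1.96  # conventional normal quantile used throughout the source equations


class PrevalenceUnavailable(LookupError):
    """No prevalence source exists for a level; the factor must be excluded."""

    def __init__(self, factor_id: str, level: str):
        super().__init__(
            f"no prevalence source for {factor_id}/{level}; "
            "the risk factor must be excluded from the model"
        )
        self.factor_id = factor_id
        self.level = level


def or_from_coefficient(mu: float, sigma: float) -> float:
    """Odds ratio from a log-scale regression coefficient and its SE.

    Uses the unbiased mean of a lognormal variable, ``exp(mu + sigma^2/2)``.
    """
    if not (math.isfinite(mu) and math.isfinite(sigma)):
        raise ValueError("mu and sigma must be finite")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    return math.exp(mu + sigma**2 / 2.0)


def sigma_from_ci(
    or_value: float, ci_low: float, ci_high: float
) -> tuple[float, float]:
    """Recover (mu, sigma) of the log-OR from a 95% CI of the OR.

    The bounds are taken to be ``exp(mu + sigma^2/2 -/+ 1.96 sigma)``, i.e.
    a symmetric interval around the unbiased mean on the log scale, so

    ``sigma = (ln hi - ln lo) / (2 * 1.96)`` and
    ``mu = (ln hi + ln lo)/2 - sigma^2/2``.

    ``or_value`` is accepted for interface symmetry; the bounds alone
    determine (mu, sigma).
    """
    if not ci_low > 0:
        raise ValueError("ci_low must be positive")
    if ci_high < ci_low:
        raise ValueError("requires ci_low <= ci_high")
    del or_value
    sigma = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    mu = (math.log(ci_high) + math.log(ci_low)) / 2.0 - sigma**2 / 2.0
    return mu, sigma


def sigma_from_pvalue(p: float, mu: float) -> tuple[float, float]:
    """Recover sigma of the log-OR from a two-sided p-value (Altman-Bland).

    ``z = -0.862 + sqrt(0.743 - 2.404 ln p)`` approximates the standard
    normal quantile of ``p/2`` (natural log); then ``sigma = |mu / z|``.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    if mu == 0.0 or not math.isfinite(mu):
        raise ValueError("sigma is undefined for mu = 0 (OR = 1)")
    z = -0.862 + math.sqrt(0.743 - 2.404 * math.log(p))
    if z <= 0:
        raise ValueError(f"Altman-Bland z is nonpositive for p = {p}")
    return abs(mu / z), z


def var_logor_from_table(table: ContingencyTable) -> float:
    """Woolf variance of the log odds ratio: sum of reciprocal cells."""
    if min(table.a, table.b, table.c, table.d) <= 0:
        raise ValueError("all contingency cells must be strictly positive")
    return 1.0 / table.a + 1.0 / table.b + 1.0 / table.c + 1.0 / table.d


def solve_contingency(
    total_cases: float,
    total_controls: float,
    ratio: float,
    chi2: float,
    direction: str = ">1",
    rtol: float = 1e-10,
) -> ContingencyTable:
    """Reconstruct a 2x2 table from totals, a risk ratio and a chi-square value.

    Solves the system ``a + c = total_cases``, ``b + d = total_controls``,
    ``[a/(a+b)]/[c/(c+d)] = ratio`` and the Pearson chi-square identity for
    ``(a, b, c, d)``, fractional cells allowed. The ratio equation makes
    ``b`` a closed-form function of ``a``, leaving a one-dimensional root
    search in ``a`` for the chi-square equation.

    The system generically admits two solutions. Roots whose implied odds
    ratio contradicts ``direction`` (``">1"`` or ``"<1"``, the sign of the
    reported log-OR) are discarded; among the remainder the table whose odds
    ratio is closest on the log scale to ``ratio`` is returned, the reported
    ratio being an odds ratio in origin.
    """
    if total_cases <= 0 or total_controls <= 0:
        raise ValueError("totals must be positive")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio == 1.0 or chi2 <= 0:
        raise ValueError(
            "degenerate system: ratio 1 (chi-square 0) leaves the table unidentified"
        )
    if direction not in (">1", "<1"):
        raise ValueError('direction must be ">1" or "<1"')

    n_ca, n_co = float(total_cases), float(total_controls)
    n = n_ca + n_co

    def b_of_a(a: float) -> float:
        c = n_ca - a
        return a * (c + n_co - ratio * c) / (a + ratio * c)

    def chi2_of_a(a: float) -> float:
        c = n_ca - a
        b = b_of_a(a)
        d = n_co - b
        if b < -1e-9 * n_co or d < -1e-9 * n_co:
            return math.nan
        b, d = max(b, 0.0), max(d, 0.0)
        num = (a * d - b * c) ** 2 * n
        den = (a + b) * (c + d) * (b + d) * (a + c)
        if den <= 0:
            return math.nan
        return num / den

    eps = 1e-9 * n_ca
    points = list(np.linspace(eps, n_ca - eps, 2048))
    # domain edges where a cell count hits zero (b = 0 or d = 0) are roots of
    # rational equations with closed forms; without them a solution lying in
    # a grid cell adjacent to the invalid region would be missed
    if ratio > 1.0:
        a_edge = n_ca - n_co / (ratio - 1.0)  # b = 0
    else:
        a_edge = ratio * n_co / (1.0 - ratio)  # d = 0
    if eps < a_edge < n_ca - eps:
        points.extend([a_edge, min(a_edge + 1e-9 * n_ca, n_ca - eps)])
    grid = np.array(sorted(points))
    vals = np.array([chi2_of_a(a) for a in grid]) - chi2

    roots: list[float] = []
    for i in range(len(grid) - 1):
        lo, hi = vals[i], vals[i + 1]
        if math.isnan(lo) or math.isnan(hi):
            continue
        if lo == 0.0:
            roots.append(grid[i])
        elif lo * hi < 0:
            roots.append(
                brentq(lambda a: chi2_of_a(a) - chi2, grid[i], grid[i + 1], xtol=1e-13)
            )
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # the target may sit at (or within rounding of) the maximum of chi2(a),
    # where the two solution branches merge and no sign change exists
    for i in range(1, len(grid) - 1):
        if math.isnan(vals[i - 1]) or math.isnan(vals[i]) or math.isnan(vals[i + 1]):
            continue
        if (
            vals[i] < 0.0
            and vals[i] >= vals[i - 1]
            and vals[i] >= vals[i + 1]
            and vals[i] > -1e-4 * chi2
        ):
            res = minimize_scalar(
                lambda a: chi2 - chi2_of_a(a),
                bounds=(grid[i - 1], grid[i + 1]),
                method="bounded",
                options={"xatol": 1e-12},
            )
            apex = float(res.x)
            gap = chi2_of_a(apex) - chi2
            if abs(gap) <= 1e-8 * chi2:
                roots.append(apex)
            elif gap > 0:  # the coarse grid straddled a narrow double crossing
                roots.append(brentq(lambda a: chi2_of_a(a) - chi2, grid[i - 1], apex, xtol=1e-13))
                roots.append(brentq(lambda a: chi2_of_a(a) - chi2, apex, grid[i + 1], xtol=1e-13))

    candidates = []
    for a in roots:
        b = b_of_a(a)
        table = ContingencyTable(a=a, b=b, c=n_ca - a, d=n_co - b)
        if min(table.a, table.b, table.c, table.d) <= 0:
            continue
        # residuals of all four defining equations, relative scale
        res = max(
            abs(table.a + table.c - n_ca) / n_ca,
            abs(table.b + table.d - n_co) / n_co,
            abs(table.risk_ratio - ratio) / ratio,
            abs(table.chi2 - chi2) / chi2,
        )
        if res > max(rtol, 1e-8):
            continue
        implied_gt1 = table.odds_ratio > 1.0
        if implied_gt1 != (direction == ">1"):
            continue
        candidates.append(table)

    if not candidates:
        raise ValueError(
            "inconsistent summary statistics: no nonnegative table reproduces "
            "the totals, ratio and chi-square"
        )
    return min(
        candidates, key=lambda t: abs(math.log(t.odds_ratio) - math.log(ratio))
    )


# ---------------------------------------------------------------------------
# Estimate-level dispatch


def impute_estimate(est: StudyEstimate) -> StudyEstimate:
    """Fill in (mu, sigma) for one estimate; exactly one route fires.

    Precedence: reported SE > 95% CI > p-value > chi-square + totals,
    in order of decreasing information content.
    """
    if est.imputed:
        return est
    if est.estimate_type == "coefficient":
        if est.se is None:
            raise ValueError(
                f"{est.study_id}/{est.factor_id}/{est.level}: a bare coefficient "
                "carries no variability information"
            )
        mu, sigma = est.value, est.se
        or_from_coefficient(mu, sigma)  # validates finiteness
        trace = ImputationTrace(method="from_coefficient")
    elif est.se is not None:
        mu, sigma = math.log(est.value), est.se
        trace = ImputationTrace(method="reported", rr_relabelled=est.rr_relabelled)
    elif est.ci_low is not None and est.ci_high is not None:
        mu, sigma = sigma_from_ci(est.value, est.ci_low, est.ci_high)
        trace = ImputationTrace(method="from_ci", rr_relabelled=est.rr_relabelled)
    elif est.p_value is not None:
        mu = math.log(est.value)
        sigma, z = sigma_from_pvalue(est.p_value, mu)
        trace = ImputationTrace(method="from_pvalue", z=z, rr_relabelled=est.rr_relabelled)
    elif est.chi2 is not None and est.n_cases is not None and est.n_controls is not None:
        mu = math.log(est.value)
        table = solve_contingency(
            est.n_cases,
            est.n_controls,
            est.value,
            est.chi2,
            direction=">1" if mu > 0 else "<1",
        )
        sigma = math.sqrt(var_logor_from_table(table))
        trace = ImputationTrace(
            method="from_chi2", table=table, rr_relabelled=est.rr_relabelled
        )
    else:
        raise ValueError(
            f"{est.study_id}/{est.factor_id}/{est.level}: no variability information"
        )
    return replace(est, mu=mu, sigma=sigma, trace=trace)


def impute_studies(studies: Iterable[Study]) -> list[Study]:
    """Impute (mu, sigma) for every estimate of every study."""
    return [
        Study(s.study_id, [impute_estimate(e) for e in s.estimates]) for s in studies
    ]


# ---------------------------------------------------------------------------
# Prevalence imputation


def impute_prevalence(
    factor_id: str,
    level: str,
    studies: Sequence[Study],
    fallback_table: PrevalenceTable | None = None,
    exclude_study: str | None = None,
) -> PrevalenceRecord:
    """Impute the population prevalence of one factor level.

    Control-group prevalences reported by the (other) case-control studies
    are averaged unweighted (tier 4); failing that, the external fallback
    table supplies its entry with its own tier; failing everything,
    :class:`PrevalenceUnavailable` signals that the factor must be excluded.
    """
    reported = [
        est.control_prevalence
        for study in studies
        if study.study_id != exclude_study
        for est in study.estimates
        if est.factor_id == factor_id
        and est.level == level
        and est.control_prevalence is not None
    ]
    if reported:
        return PrevalenceRecord(
            factor_id=factor_id,
            level=level,
            prevalence=fmean(reported),
            tier=4,
            source_note=f"mean control-group prevalence of {len(reported)} study estimate(s)",
        )
    if fallback_table is not None and (factor_id, level) in fallback_table:
        return fallback_table.record(factor_id, level)
    raise PrevalenceUnavailable(factor_id, level)
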