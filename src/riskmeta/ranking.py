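"""Pooled odds ratios and prevalences per risk factor, for ranking.

Ranking is a reporting aid for choosing which factors to keep in the model;
it does not feed the risk engine. Odds ratios below 1 are replaced by their
reciprocals before pooling so that protective and deleterious factors are
comparable on one scale; the variance of the log-OR is unchanged by the
inversion. The pooled value is an inverse-variance weighted arithmetic mean
on the OR scale (a log-scale geometric variant is available via ``scale``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .study_data import PrevalenceTable, Study, StudyEstimate

__all__ = ["FactorRanking", "pool_or", "pool_prevalence", "rank_factors", "factor_rankings"]

_Z95 = 1.96


@dataclass(frozen=True)
class FactorRanking:
    factor_id: str
    pooled_or: float
    pooled_or_ci_low: float
    pooled_prevalence: float
    n_studies: int

    def __post_init__(self) -> None:
        if self.pooled_or < 1.0 - 1e-12:
            raise ValueError("pooled OR must be >= 1 after the inversion convention")
        if self.n_studies < 1:
            raise ValueError("a ranking requires at least one study")


def pool_or(
    estimates: Sequence[StudyEstimate],
    pooled_prevalence: float = math.nan,
    scale: str = "or",
) -> FactorRanking:
    """Pool the (level) odds ratios of one risk factor across studies.

    Each estimate must carry an imputed ``sigma``; weights are the inverse
    log-OR variances. ORs below 1 are inverted first. ``scale="or"`` pools
    by arithmetic weighted mean of the ORs, ``scale="log"`` by weighted mean
    of the log-ORs. The lower CI bound comes from the pooled weight sum on
    the log scale: ``exp(ln pooled - 1.96 / sqrt(sum w))``.
    """
    if scale not in ("or", "log"):
        raise ValueError('scale must be "or" or "log"')
    if not estimates:
        raise ValueError("no estimates to pool")
    fids = {e.factor_id for e in estimates}
    if len(fids) != 1:
        raise ValueError(f"pool_or expects one factor, got {sorted(fids)}")
    ors, weights = [], []
    for est in estimates:
        if est.sigma is None:
            raise ValueError(
                f"{est.study_id}/{est.factor_id}/{est.level}: sigma not imputed"
            )
        value = est.or_point
        if value < 1.0:
            value = 1.0 / value
        if est.sigma == 0.0:
            weights.append(math.inf)
        else:
            weights.append(1.0 / est.sigma**2)
        ors.append(value)
    if all(math.isinf(w) for w in weights) or any(math.isinf(w) for w in weights):
        # zero-variance estimates dominate: pool those, equally weighted
        exact = [o for o, w in zip(ors, weights) if math.isinf(w)]
        ors, weights = exact, [1.0] * len(exact)
        w_sum_for_ci = math.inf
    else:
        w_sum_for_ci = sum(weights)
    if sum(weights) == 0.0:
        raise ValueError("all estimate variances are infinite; nothing to pool")
    w_sum = sum(weights)
    if scale == "or":
        pooled = sum(w * o for w, o in zip(weights, ors)) / w_sum
    else:
        pooled = math.exp(sum(w * math.log(o) for w, o in zip(weights, ors)) / w_sum)
    if math.isinf(w_sum_for_ci):
        ci_low = pooled
    else:
        ci_low = math.exp(math.log(pooled) - _Z95 / math.sqrt(w_sum_for_ci))
    return FactorRanking(
        factor_id=next(iter(fids)),
        pooled_or=pooled,
        pooled_or_ci_low=ci_low,
        pooled_prevalence=pooled_prevalence,
        n_studies=len({e.study_id for e in estimates}),
    )


def pool_prevalence(
    prevalences: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weighted mean prevalence over the non-reference levels of one factor.

    Weights default to equal; callers pass inverse log-OR variances when the
    paired estimates provide them.
    """
    if not prevalences:
        raise ValueError("no prevalences to pool")
    if weights is None:
        weights = [1.0] * len(prevalences)
    if len(weights) != len(prevalences):
        raise ValueError("weights and prevalences must align")
    w_sum = sum(weights)
    if w_sum <= 0:
        raise ValueError("weights must sum to a positive value")
    return sum(w * p for w, p in zip(weights, prevalences)) / w_sum


def rank_factors(
    rankings: Iterable[FactorRanking], top_n: int | None = None
) -> list[FactorRanking]:
    """Order factors by pooled OR (descending); ties by n_studies, factor_id."""
    ordered = sorted(
        rankings, key=lambda r: (-r.pooled_or, -r.n_studies, r.factor_id)
    )
    return ordered if top_n is None else ordered[:top_n]


def factor_rankings(
    studies: Sequence[Study],
    prevalences: PrevalenceTable | None = None,
    scale: str = "or",
) -> list[FactorRanking]:
    """Build one :class:`FactorRanking` per factor present in the studies.

    Prevalence pooling weights each non-reference level by the total inverse
    log-OR variance its estimates contribute, when a prevalence table is
    supplied.
    """
    by_factor: dict[str, list[StudyEstimate]] = {}
    for study in studies:
        for est in study.estimates:
            by_factor.setdefault(est.factor_id, []).append(est)
    out = []
    for fid, ests in by_factor.items():
        pooled_prev = math.nan
        if prevalences is not None and fid in prevalences.factors():
            level_w: dict[str, float] = {}
            for est in ests:
                if est.sigma and est.sigma > 0:
                    level_w[est.level] = level_w.get(est.level, 0.0) + 1.0 / est.sigma**2
            levels = [
                lvl
                for lvl in prevalences.levels(fid)
                if any(e.level == lvl for e in ests)
            ]
            if levels:
                prevs = [prevalences.get(fid, lvl) for lvl in levels]
                weights = (
                    [level_w[lvl] for lvl in levels]
                    if all(lvl in level_w for lvl in levels)
                    else None
                )
                pooled_prev = pool_prevalence(prevs, weights)
        out.append(pool_or(ests, pooled_prevalence=pooled_prev, scale=scale))
    return out
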