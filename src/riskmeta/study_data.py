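"""Data model, I/O and eligibility filters for case-control study estimates.

The meta-model consumes three tables:

* a **study-estimates table** — one row per (study, risk factor, level) carrying
  an odds ratio (or relative risk, or regression coefficient) together with
  whatever variability information the publication reported (CI, p-value,
  chi-square statistic plus totals, or a standard error);
* a **prevalence table** — the population share of every level of every risk
  factor, with a provenance tier (1 = national population database ...
  4 = control group of a source study, 5 = non-local source);
* **patient profiles** — one chosen level per risk factor, with the sentinel
  ``not_applicable`` for factors that cannot apply to the woman (e.g.
  gestational factors for a never-pregnant woman).

Eligibility mirrors the evidence-synthesis protocol: an estimate enters the
model only if its log-OR standard error is recoverable; a study enters only if
it contributes at least two risk factors; when both an adjusted (multivariate)
and an unadjusted estimate exist for the same level, only the adjusted one is
kept.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "NOT_APPLICABLE",
    "RiskFactor",
    "ContingencyTable",
    "ImputationTrace",
    "StudyEstimate",
    "PrevalenceRecord",
    "PrevalenceTable",
    "Study",
    "PatientProfile",
    "EligibilityResult",
    "read_study_table",
    "write_study_table",
    "read_prevalence_table",
    "write_prevalence_table",
    "read_profiles",
    "write_profiles",
    "filter_eligible",
]

#: Sentinel level for a factor that cannot apply to a given woman.
NOT_APPLICABLE = "not_applicable"

#: Aliases accepted on input for :data:`NOT_APPLICABLE`.
_NA_ALIASES = {"", "na", "n/a", "not_applicable", "none"}

ESTIMATE_TYPES = ("or", "rr", "coefficient")

#: Required columns of the study-estimates table, in canonical order.
STUDY_COLUMNS = (
    "study_id",
    "factor_id",
    "level",
    "estimate_type",
    "value",
    "ci_low",
    "ci_high",
    "p_value",
    "chi2",
    "n_cases",
    "n_controls",
    "adjusted",
)

#: Recognised optional columns (a directly reported SE of the log-OR /
#: coefficient, and the control-group prevalence of the level).
STUDY_OPTIONAL_COLUMNS = ("se", "control_prevalence")

PREVALENCE_COLUMNS = ("factor_id", "level", "prevalence", "tier", "source_note")


@dataclass(frozen=True)
class RiskFactor:
    """A risk-factor variable with its ordered category levels."""

    factor_id: str
    name: str
    levels: tuple[str, ...]
    reference_level: str

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.factor_id}: duplicate level identifiers")
        if self.reference_level not in self.levels:
            raise ValueError(
                f"{self.factor_id}: reference level {self.reference_level!r} "
                "is not among the declared levels"
            )

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference_level)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure table: a/c cases exposed/unexposed, b/d controls."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        return (self.a * self.d) / (self.b * self.c)

    @property
    def risk_ratio(self) -> float:
        return (self.a / (self.a + self.b)) / (self.c / (self.c + self.d))

    @property
    def chi2(self) -> float:
        num = (self.a * self.d - self.b * self.c) ** 2 * self.n
        den = (
            (self.a + self.b)
            * (self.c + self.d)
            * (self.b + self.d)
            * (self.a + self.c)
        )
        return num / den


@dataclass(frozen=True)
class ImputationTrace:
    """Provenance of a (mu, sigma) pair: which imputation route produced it."""

    method: str  # reported | from_coefficient | from_ci | from_pvalue | from_chi2
    z: float | None = None
    table: ContingencyTable | None = None
    rr_relabelled: bool = False

    def __post_init__(self) -> None:
        if (self.z is not None) != (self.method == "from_pvalue"):
            raise ValueError("z is recorded exactly for the p-value route")
        if (self.table is not None) != (self.method == "from_chi2"):
            raise ValueError("a contingency table is recorded exactly for the chi2 route")


@dataclass(frozen=True)
class StudyEstimate:
    """One (study, factor, level) effect estimate with variability provenance.

    ``mu``/``sigma`` (location and SE of the log-OR) are ``None`` until an
    imputation route has fired; ``trace`` then records which one.
    """

    study_id: str
    factor_id: str
    level: str
    estimate_type: str
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    chi2: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    adjusted: bool = True
    se: float | None = None
    control_prevalence: float | None = None
    rr_relabelled: bool = False
    mu: float | None = None
    sigma: float | None = None
    trace: ImputationTrace | None = None

    def __post_init__(self) -> None:
        if self.estimate_type not in ESTIMATE_TYPES:
            raise ValueError(f"unknown estimate_type {self.estimate_type!r}")
        if self.estimate_type in ("or", "rr") and not self.value > 0:
            raise ValueError(f"{self._key()}: OR/RR value must be positive")
        if not math.isfinite(self.value):
            raise ValueError(f"{self._key()}: non-finite value")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError(f"{self._key()}: both CI bounds required")
        if self.ci_low is not None and self.ci_high is not None:
            if not (0 < self.ci_low < self.ci_high):
                raise ValueError(f"{self._key()}: requires 0 < ci_low < ci_high")
        if self.p_value is not None and not (0 < self.p_value < 1):
            raise ValueError(f"{self._key()}: p_value must lie in (0, 1)")
        if self.chi2 is not None and self.chi2 < 0:
            raise ValueError(f"{self._key()}: chi2 must be nonnegative")
        for attr in ("n_cases", "n_controls"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{self._key()}: {attr} must be positive")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError(f"{self._key()}: sigma must be nonnegative")
        if self.mu is not None and not math.isfinite(self.mu):
            raise ValueError(f"{self._key()}: mu must be finite")

    def _key(self) -> str:
        return f"{self.study_id}/{self.factor_id}/{self.level}"

    @property
    def imputed(self) -> bool:
        return self.mu is not None and self.sigma is not None

    @property
    def or_point(self) -> float:
        """Plug-in odds-ratio point estimate used by the risk equations.

        For a regression coefficient the unbiased mean exp(mu + sigma^2/2);
        for a reported OR (or relabelled RR) the published value itself.
        """
        if self.estimate_type == "coefficient":
            if not self.imputed:
                raise ValueError(f"{self._key()}: coefficient estimate not yet imputed")
            return math.exp(self.mu + self.sigma**2 / 2.0)
        return self.value

    @property
    def log_or_point(self) -> float:
        return math.log(self.or_point)

    def has_variability_info(self) -> bool:
        """Whether sigma (SE of the log-OR) is recoverable for this row."""
        if self.sigma is not None or self.se is not None:
            return True
        if self.ci_low is not None and self.ci_high is not None:
            return True
        if self.estimate_type == "coefficient":
            # with no reported SE a bare coefficient carries no variability
            return False
        if self.p_value is not None and self.value != 1.0:
            return True
        if (
            self.chi2 is not None
            and self.chi2 > 0
            and self.n_cases is not None
            and self.n_controls is not None
            and self.value != 1.0
        ):
            return True
        return False


@dataclass(frozen=True)
class PrevalenceRecord:
    """Population prevalence of one factor level, with its source tier."""

    factor_id: str
    level: str
    prevalence: float
    tier: int = 1
    source_note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(
                f"{self.factor_id}/{self.level}: prevalence must lie strictly in (0, 1)"
            )
        if self.tier not in (1, 2, 3, 4, 5):
            raise ValueError(f"{self.factor_id}/{self.level}: tier must be 1-5")


class PrevalenceTable:
    """Lookup of level prevalences, normalised to a simplex within each factor.

    Input sums per factor may be off by rounding; sums further than ``rtol``
    from 1 raise, otherwise levels are rescaled so they sum to 1 exactly.
    """

    def __init__(self, records: Iterable[PrevalenceRecord], rtol: float = 1e-3):
        by_factor: dict[str, dict[str, PrevalenceRecord]] = {}
        for rec in records:
            lvls = by_factor.setdefault(rec.factor_id, {})
            if rec.level in lvls:
                raise ValueError(f"duplicate prevalence for {rec.factor_id}/{rec.level}")
            lvls[rec.level] = rec
        self._records: dict[str, dict[str, PrevalenceRecord]] = {}
        for fid, lvls in by_factor.items():
            total = sum(r.prevalence for r in lvls.values())
            if abs(total - 1.0) > rtol:
                raise ValueError(
                    f"{fid}: level prevalences sum to {total:.6f}, expected 1 "
                    f"(tolerance {rtol})"
                )
            self._records[fid] = {
                lvl: replace(rec, prevalence=rec.prevalence / total)
                for lvl, rec in lvls.items()
            }

    def factors(self) -> tuple[str, ...]:
        return tuple(self._records)

    def levels(self, factor_id: str) -> dict[str, float]:
        return {lvl: r.prevalence for lvl, r in self._records[factor_id].items()}

    def get(self, factor_id: str, level: str) -> float:
        try:
            return self._records[factor_id][level].prevalence
        except KeyError:
            raise KeyError(f"no prevalence for {factor_id}/{level}") from None

    def record(self, factor_id: str, level: str) -> PrevalenceRecord:
        return self._records[factor_id][level]

    def __contains__(self, key: tuple[str, str]) -> bool:
        fid, lvl = key
        return fid in self._records and lvl in self._records[fid]

    def records(self) -> list[PrevalenceRecord]:
        return [r for lvls in self._records.values() for r in lvls.values()]


@dataclass
class Study:
    """All eligible estimates extracted from one case-control study."""

    study_id: str
    estimates: list[StudyEstimate] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, bool]] = set()
        for est in self.estimates:
            if est.study_id != self.study_id:
                raise ValueError(
                    f"estimate {est._key()} does not belong to study {self.study_id}"
                )
            key = (est.factor_id, est.level, est.adjusted)
            if key in seen:
                raise ValueError(
                    f"{self.study_id}: duplicate estimate for "
                    f"{est.factor_id}/{est.level} (adjusted={est.adjusted})"
                )
            seen.add(key)

    @property
    def factor_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for est in self.estimates:
            if est.factor_id not in out:
                out.append(est.factor_id)
        return tuple(out)

    @property
    def n_factors(self) -> int:
        return len(self.factor_ids)

    def estimates_for(self, factor_id: str) -> list[StudyEstimate]:
        return [e for e in self.estimates if e.factor_id == factor_id]

    def get(self, factor_id: str, level: str) -> StudyEstimate | None:
        for e in self.estimates:
            if e.factor_id == factor_id and e.level == level:
                return e
        return None


@dataclass(frozen=True)
class PatientProfile:
    """One woman's risk-factor profile: a chosen level per factor.

    ``attributes`` optionally carries the underlying continuous values
    (e.g. exact ages) from which age-like levels were discretised.
    """

    patient_id: str
    assignments: Mapping[str, str]
    attributes: Mapping[str, float] = field(default_factory=dict)

    def level(self, factor_id: str) -> str:
        return self.assignments.get(factor_id, NOT_APPLICABLE)


# ---------------------------------------------------------------------------
# I/O


def _parse_optional_float(raw: str | float | None) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "" or raw.lower() in ("na", "nan", "none"):
            return None
    value = float(raw)
    if math.isnan(value):
        return None
    return value


def _parse_optional_int(raw) -> int | None:
    value = _parse_optional_float(raw)
    return None if value is None else int(round(value))


def _parse_bool(raw) -> bool:
    if isinstance(raw, bool):
        return raw
    text = str(raw).strip().lower()
    if text in ("1", "true", "yes", "y", "t", ""):  # missing defaults to adjusted
        return True
    if text in ("0", "false", "no", "n", "f"):
        return False
    raise ValueError(f"cannot interpret {raw!r} as a boolean")


def _estimate_from_record(rec: Mapping[str, object]) -> StudyEstimate:
    etype = str(rec["estimate_type"]).strip().lower()
    rr_relabelled = False
    if etype == "rr":
        # case-control designs cannot estimate an RR; treat as a mislabelled OR
        etype = "or"
        rr_relabelled = True
    return StudyEstimate(
        study_id=str(rec["study_id"]).strip(),
        factor_id=str(rec["factor_id"]).strip(),
        level=str(rec["level"]).strip(),
        estimate_type=etype,
        value=float(rec["value"]),
        ci_low=_parse_optional_float(rec.get("ci_low")),
        ci_high=_parse_optional_float(rec.get("ci_high")),
        p_value=_parse_optional_float(rec.get("p_value")),
        chi2=_parse_optional_float(rec.get("chi2")),
        n_cases=_parse_optional_int(rec.get("n_cases")),
        n_controls=_parse_optional_int(rec.get("n_controls")),
        adjusted=_parse_bool(rec.get("adjusted", True)),
        se=_parse_optional_float(rec.get("se")),
        control_prevalence=_parse_optional_float(rec.get("control_prevalence")),
        rr_relabelled=rr_relabelled,
    )


def _load_records(path: str | Path) -> list[dict]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise ValueError(f"{path}: expected a JSON array of row objects")
        return data
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def read_study_table(
    path: str | Path,
    factors: Sequence[RiskFactor] | None = None,
) -> list[Study]:
    """Read a study-estimates table (CSV or JSON) into validated studies.

    Rows typed ``rr`` are relabelled as odds ratios (a case-control design
    cannot estimate a relative risk) with a warning. Malformed rows are
    reported together by row number. When ``factors`` is given, factor and
    level identifiers are checked against it.
    """
    records = _load_records(path)
    if records:
        extra = set(records[0]) - set(STUDY_COLUMNS) - set(STUDY_OPTIONAL_COLUMNS)
        if extra:
            warnings.warn(
                f"{path}: ignoring unrecognised columns {sorted(extra)}",
                stacklevel=2,
            )
        missing = set(STUDY_COLUMNS) - set(records[0]) - {"adjusted"}
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    known = None
    if factors is not None:
        known = {f.factor_id: f for f in factors}

    estimates: list[StudyEstimate] = []
    errors: list[str] = []
    n_relabelled = 0
    for i, rec in enumerate(records, start=2):  # header is row 1
        try:
            if str(rec.get("estimate_type", "")).strip().lower() == "rr":
                n_relabelled += 1
            est = _estimate_from_record(rec)
            if known is not None:
                fac = known.get(est.factor_id)
                if fac is None:
                    raise ValueError(f"unknown factor_id {est.factor_id!r}")
                if est.level not in fac.levels:
                    raise ValueError(
                        f"unknown level {est.level!r} for factor {est.factor_id}"
                    )
                if est.level == fac.reference_level:
                    raise ValueError(
                        f"{est.factor_id}: estimates must target non-reference levels"
                    )
            estimates.append(est)
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError(f"{path}: malformed rows:\n  " + "\n  ".join(errors))
    if n_relabelled:
        warnings.warn(
            f"{path}: {n_relabelled} RR estimate(s) relabelled as OR "
            "(case-control design)",
            stacklevel=2,
        )

    by_study: dict[str, list[StudyEstimate]] = {}
    for est in estimates:
        by_study.setdefault(est.study_id, []).append(est)
    return [Study(sid, ests) for sid, ests in by_study.items()]


def write_study_table(studies: Iterable[Study], path: str | Path) -> None:
    """Write studies back to CSV (or JSON by extension); round-trip safe."""
    path = Path(path)
    rows = []
    for study in studies:
        for e in study.estimates:
            rows.append(
                {
                    "study_id": e.study_id,
                    "factor_id": e.factor_id,
                    "level": e.level,
                    "estimate_type": e.estimate_type,
                    "value": e.value,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p_value": e.p_value,
                    "chi2": e.chi2,
                    "n_cases": e.n_cases,
                    "n_controls": e.n_controls,
                    "adjusted": e.adjusted,
                    "se": e.se,
                    "control_prevalence": e.control_prevalence,
                }
            )
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
        return
    cols = list(STUDY_COLUMNS) + list(STUDY_OPTIONAL_COLUMNS)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: ("" if row[k] is None else row[k]) for k in cols})


def read_prevalence_table(path: str | Path) -> PrevalenceTable:
    """Read a prevalence table (CSV/JSON) and normalise it per factor."""
    records = _load_records(path)
    recs = []
    errors = []
    for i, rec in enumerate(records, start=2):
        try:
            recs.append(
                PrevalenceRecord(
                    factor_id=str(rec["factor_id"]).strip(),
                    level=str(rec["level"]).strip(),
                    prevalence=float(rec["prevalence"]),
                    tier=int(rec.get("tier") or 1),
                    source_note=str(rec.get("source_note") or ""),
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError(f"{path}: malformed rows:\n  " + "\n  ".join(errors))
    return PrevalenceTable(recs)


def write_prevalence_table(table: PrevalenceTable, path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "factor_id": r.factor_id,
            "level": r.level,
            "prevalence": r.prevalence,
            "tier": r.tier,
            "source_note": r.source_note,
        }
        for r in table.records()
    ]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(PREVALENCE_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)


def read_profiles(path: str | Path) -> list[PatientProfile]:
    """Read patient profiles from wide CSV (patient_id + factor columns) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        out = []
        for item in data:
            assignments = {
                fid: _canon_level(lvl) for fid, lvl in item["assignments"].items()
            }
            out.append(PatientProfile(str(item["patient_id"]), assignments))
        return out
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "patient_id" not in reader.fieldnames:
            raise ValueError(f"{path}: profiles CSV requires a patient_id column")
        out = []
        for rec in reader:
            pid = rec.pop("patient_id")
            out.append(
                PatientProfile(pid, {fid: _canon_level(v) for fid, v in rec.items()})
            )
        return out


def _canon_level(raw: object) -> str:
    text = str(raw).strip()
    if text.lower() in _NA_ALIASES:
        return NOT_APPLICABLE
    return text


def write_profiles(profiles: Iterable[PatientProfile], path: str | Path) -> None:
    path = Path(path)
    profiles = list(profiles)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(
                [
                    {"patient_id": p.patient_id, "assignments": dict(p.assignments)}
                    for p in profiles
                ],
                fh,
                indent=1,
            )
        return
    factor_ids: list[str] = []
    for p in profiles:
        for fid in p.assignments:
            if fid not in factor_ids:
                factor_ids.append(fid)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id"] + factor_ids)
        for p in profiles:
            writer.writerow([p.patient_id] + [p.level(f) for f in factor_ids])


# ---------------------------------------------------------------------------
# Eligibility filtering


@dataclass
class EligibilityResult:
    """Filtered studies plus a per-study exclusion report.

    Iterable as a collection of :class:`Study`, so the filter is idempotent:
    ``filter_eligible(filter_eligible(s))`` equals ``filter_eligible(s)``.
    """

    studies: list[Study]
    report: dict[str, dict]

    def __iter__(self) -> Iterator[Study]:
        return iter(self.studies)

    def __len__(self) -> int:
        return len(self.studies)


def filter_eligible(studies: Iterable[Study]) -> EligibilityResult:
    """Apply the eligibility rules to a collection of studies.

    1. drop estimates with no recoverable variability information;
    2. where a (factor, level) has both adjusted and unadjusted estimates,
       keep only the adjusted (multivariate) one;
    3. drop studies left with fewer than two distinct risk factors.
    """
    kept_studies: list[Study] = []
    report: dict[str, dict] = {}
    for study in studies:
        dropped: list[str] = []
        usable = []
        for est in study.estimates:
            if est.has_variability_info():
                usable.append(est)
            else:
                dropped.append(f"{est.factor_id}/{est.level}: no variability information")
        adjusted_keys = {
            (e.factor_id, e.level) for e in usable if e.adjusted
        }
        final = []
        for est in usable:
            if not est.adjusted and (est.factor_id, est.level) in adjusted_keys:
                dropped.append(
                    f"{est.factor_id}/{est.level}: unadjusted superseded by adjusted"
                )
            else:
                final.append(est)
        candidate = Study(study.study_id, final)
        entry: dict = {"dropped_estimates": dropped, "excluded": False, "reason": None}
        if candidate.n_factors < 2:
            entry["excluded"] = True
            entry["reason"] = (
                f"only {candidate.n_factors} risk factor(s) usable; at least two required"
            )
        else:
            kept_studies.append(candidate)
        report[study.study_id] = entry
    return EligibilityResult(kept_studies, report)
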