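"""Descriptive outputs: coding trends, cohort characteristics, death causes.

Covers the three descriptive analyses of a recording-validation study: yearly
primary-care code-usage counts (terminology drift), a demographic/clinical
profile of an algorithm-defined cohort, and the ranked underlying causes of
death among patients flagged by a source but lacking IPF on their death
certificate.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .casefinding import (
    DeathCauseMode,
    LinkedPatient,
    PositionRule,
    death_has_ipf,
    has_qualifying_admission,
)
from .core import ClinicalEvent, CodeList, IPF_ICD10_TARGETS
from .eligibility import StudyConfig, birthday_at_age
from .validation import source_membership

__all__ = ["TrendTable", "code_usage_by_year", "CohortProfile",
           "cohort_profile", "noncordant_death_causes"]


@dataclass(frozen=True)
class TrendTable:
    """Yearly event counts per code, with derived per-year shares."""

    frame: pd.DataFrame  # columns: year, code, term, event_count

    def shares(self) -> pd.DataFrame:
        """Per-year share of each code among that year's matching events."""
        out = self.frame.copy()
        totals = out.groupby("year")["event_count"].transform("sum")
        out["share"] = out["event_count"] / totals
        return out

    def top_codes_share(self, k: int = 4) -> float:
        """Aggregate share of the k most-used codes over the whole range."""
        by_code = (self.frame.groupby("code")["event_count"].sum()
                   .sort_values(ascending=False))
        total = by_code.sum()
        return float(by_code.head(k).sum() / total) if total else float("nan")


def code_usage_by_year(events: Iterable[ClinicalEvent], codelist: CodeList,
                       year_range: tuple[int, int]) -> TrendTable:
    """Count matching (broad-subset) events per calendar year and code."""
    first, last = year_range
    if first > last:
        raise ValueError("empty year range")
    broad = codelist.broad
    counts: dict[tuple[int, str], int] = {}
    for event in events:
        year = event.event_date.year
        if event.code in broad and first <= year <= last:
            counts[(year, event.code)] = counts.get((year, event.code), 0) + 1
    rows = [{"year": year, "code": code, "term": codelist.term_for(code),
             "event_count": n}
            for (year, code), n in sorted(counts.items())]
    frame = pd.DataFrame(rows, columns=["year", "code", "term", "event_count"])
    return TrendTable(frame)


@dataclass(frozen=True)
class CohortProfile:
    """Characteristics of an algorithm-defined cohort at its index date."""

    n: int
    median_age: float
    iqr_age: float
    pct_65_plus: float
    pct_male: float
    median_survival_years: float | None
    iqr_survival_years: float | None
    pct_ever_current_smoker: float | None
    n_smoking_known: int
    comorbidity_pct: dict[str, float]


def _iqr(values: Sequence[float]) -> float:
    q = statistics.quantiles(values, n=4, method="inclusive")
    return q[2] - q[0]


def cohort_profile(cohort: Sequence[LinkedPatient],
                   index_rule: str = "earliest_aurum_code",
                   comorbidity_codelists: Mapping[str, CodeList] | None = None,
                   smoking_codes: Mapping[str, str] | None = None,
                   config: StudyConfig | None = None,
                   targets=IPF_ICD10_TARGETS) -> CohortProfile:
    """Profile a cohort at its index date.

    ``index_rule`` is "earliest_aurum_code" (earliest broad primary-care
    code) or "earliest_admission" (first qualifying hospital admission).
    Smoking uses the record closest to, at or before, the index date (the
    later record wins date ties); a patient with no smoking record falls in
    an unknown bucket excluded from numerator and denominator. Comorbidity
    codes must be strictly before the index date.
    """
    if not cohort:
        raise ValueError("empty cohort")
    config = config or StudyConfig()

    def index_date(p: LinkedPatient) -> date | None:
        if index_rule == "earliest_aurum_code":
            return p.earliest_broad
        if index_rule == "earliest_admission":
            return has_qualifying_admission(
                p.spells, targets, PositionRule.PRIMARY_OR_SECONDARY,
                p.window(config, with_diagnosis=False))
        raise ValueError(f"unknown index rule {index_rule!r}")

    indexed = [(p, index_date(p)) for p in cohort]
    indexed = [(p, d) for p, d in indexed if d is not None]
    if not indexed:
        raise ValueError("no patient has an index date under this rule")

    ages = []
    n_male = 0
    n_65 = 0
    survivals = []
    smoker_status: list[str] = []
    comorbid_counts = {name: 0 for name in (comorbidity_codelists or {})}
    for patient, idx in indexed:
        # completed years at index
        age = idx.year - patient.registry.birth_date.year
        if birthday_at_age(patient.registry.birth_date, age) > idx:
            age -= 1
        ages.append(age)
        if age >= 65:
            n_65 += 1
        if patient.registry.sex.value == "male":
            n_male += 1
        death = patient.registry.death_date
        if death is not None and death >= idx:
            survivals.append((death - idx).days / 365.25)
        if smoking_codes:
            candidates = [e for e in patient.events
                          if e.code in smoking_codes and e.event_date <= idx]
            if candidates:
                # closest record wins; the later record in the stream breaks
                # same-date ties, so iterate in order and keep >= matches
                best = candidates[0]
                for e in candidates[1:]:
                    if e.event_date >= best.event_date:
                        best = e
                smoker_status.append(smoking_codes[best.code])
        for name, codes in (comorbidity_codelists or {}).items():
            codeset = codes.broad if isinstance(codes, CodeList) else set(codes)
            if any(e.code in codeset and e.event_date < idx
                   for e in patient.events):
                comorbid_counts[name] += 1

    n = len(indexed)
    ever_current = sum(1 for s in smoker_status if s in ("ex", "former", "current"))
    return CohortProfile(
        n=n,
        median_age=float(statistics.median(ages)),
        iqr_age=float(_iqr(ages)) if len(ages) > 1 else 0.0,
        pct_65_plus=100.0 * n_65 / n,
        pct_male=100.0 * n_male / n,
        median_survival_years=(float(statistics.median(survivals))
                               if survivals else None),
        iqr_survival_years=(float(_iqr(survivals))
                            if len(survivals) > 1 else None),
        pct_ever_current_smoker=(100.0 * ever_current / len(smoker_status)
                                 if smoker_status else None),
        n_smoking_known=len(smoker_status),
        comorbidity_pct={name: 100.0 * count / n
                         for name, count in comorbid_counts.items()},
    )


def noncordant_death_causes(cohort: Sequence[LinkedPatient],
                            source: str = "aurum",
                            config: StudyConfig | None = None,
                            targets=IPF_ICD10_TARGETS) -> list[tuple[str, int]]:
    """Ranked underlying causes of death among deceased patients flagged by
    ``source`` ("aurum" or "hes") whose certificate nowhere mentions IPF.

    Ties are broken lexicographically by ICD-10 code.
    """
    if source not in ("aurum", "hes"):
        raise ValueError("source must be 'aurum' or 'hes'")
    config = config or StudyConfig()
    membership = source_membership(cohort, config, targets=targets)
    flagged = membership.aurum if source == "aurum" else membership.hes
    counts: dict[str, int] = {}
    for patient in cohort:
        if patient.patient_id not in flagged or patient.death is None:
            continue
        if death_has_ipf(patient.death, targets, DeathCauseMode.ANYWHERE):
            continue
        cause = patient.death.underlying_cause
        counts[cause] = counts.get(cause, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
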