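"""Gold-standard validation of case-finding algorithms.

The national death registration is used as the reference standard: a patient
whose certificate carries an IPF code (anywhere, or — for sensitivity
analysis — as the underlying cause) is taken to truly have had IPF. Because
the reference is a death, validation is restricted to patients who died
within the study period.

PPV  = n_true / n_found   (certificate-confirmed among algorithm-flagged)
Sens = n_true / n_gold    (algorithm-flagged among all certificate cases)

Confidence intervals are Wilson score intervals; the certificate-case
denominator n_gold is shared across algorithms so sensitivities are
comparable.

The module is organised around :class:`ValidationStudy`, built from a linked
cohort, whose :meth:`ValidationStudy.fit` returns a
:class:`ValidationResults` object carrying the per-algorithm estimates, the
three-source concordance partition and both sensitivity analyses, with a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .casefinding import (
    ALGORITHM_PRESETS,
    AlgorithmDefinition,
    DeathCauseMode,
    LinkedPatient,
    PositionRule,
    apply_algorithm,
    death_has_ipf,
    has_qualifying_admission,
)
from .core import IPF_ICD10_TARGETS
from .eligibility import StudyConfig
from .errors import InfeasibleRecipeError

__all__ = [
    "proportion_ci",
    "round_pct",
    "ValidationResult",
    "ConcordancePartition",
    "SourceMembership",
    "GoldSensitivityResult",
    "PositionSensitivityResult",
    "validate",
    "concordance",
    "derive_pairwise_from_marginals",
    "source_membership",
    "sensitivity_analysis_gold",
    "sensitivity_analysis_positions",
    "ValidationStudy",
    "ValidationResults",
]


def proportion_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion, clipped to
    [0, 1]."""
    if n < 1:
        raise ValueError("proportion_ci undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError(f"successes {x} outside [0, {n}]")
    low, high = proportion_confint(x, n, alpha=1.0 - level, method="wilson")
    # the score interval hits the boundary exactly at x = 0 and x = n;
    # pin it there rather than keeping float round-off
    low = 0.0 if x == 0 else max(0.0, float(low))
    high = 1.0 if x == n else min(1.0, float(high))
    return (low, high)


def round_pct(fraction: float, ndigits: int = 1) -> float:
    """A proportion as a percentage, rounded half away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    # go through the shortest decimal repr so 64.35 is a true half case
    return float(Decimal(str(fraction * 100)).quantize(quantum,
                                                       rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ValidationResult:
    """PPV and sensitivity of one algorithm against the death-record gold
    standard, over the deceased members of the study cohort."""

    algorithm_id: str
    n_found: int
    n_true: int
    n_gold: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_true > self.n_found or self.n_true > self.n_gold:
            raise ValueError("n_true cannot exceed n_found or n_gold")

    @property
    def ppv(self) -> float | None:
        """Undefined (None) when the algorithm found nobody."""
        return self.n_true / self.n_found if self.n_found else None

    @property
    def ppv_ci(self) -> tuple[float, float] | None:
        if not self.n_found:
            return None
        return proportion_ci(self.n_true, self.n_found, self.level)

    @property
    def sensitivity(self) -> float | None:
        return self.n_true / self.n_gold if self.n_gold else None

    @property
    def sensitivity_ci(self) -> tuple[float, float] | None:
        if not self.n_gold:
            return None
        return proportion_ci(self.n_true, self.n_gold, self.level)


@dataclass(frozen=True)
class ConcordancePartition:
    """Exclusive seven-region membership counts for three patient-id sets
    (primary care = Aurum-like, hospital = HES-like, deaths = ONS-like)."""

    aurum_only: int
    hes_only: int
    ons_only: int
    aurum_hes: int
    aurum_ons: int
    hes_ons: int
    all_three: int

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise InfeasibleRecipeError(f"negative region count {name}={value}")

    def as_dict(self) -> dict[str, int]:
        return {
            "aurum_only": self.aurum_only, "hes_only": self.hes_only,
            "ons_only": self.ons_only, "aurum_hes": self.aurum_hes,
            "aurum_ons": self.aurum_ons, "hes_ons": self.hes_ons,
            "all_three": self.all_three,
        }

    @property
    def total(self) -> int:
        return sum(self.as_dict().values())

    # Marginal totals (inclusive memberships).
    @property
    def n_aurum(self) -> int:
        return self.aurum_only + self.aurum_hes + self.aurum_ons + self.all_three

    @property
    def n_hes(self) -> int:
        return self.hes_only + self.aurum_hes + self.hes_ons + self.all_three

    @property
    def n_ons(self) -> int:
        return self.ons_only + self.aurum_ons + self.hes_ons + self.all_three

    @property
    def n_aurum_or_hes_and_ons(self) -> int:
        """Certificate cases captured by either of the living-record sources."""
        return self.aurum_ons + self.hes_ons + self.all_three


def concordance(aurum_ids: Iterable[str], hes_ids: Iterable[str],
                ons_ids: Iterable[str]) -> ConcordancePartition:
    """Partition three membership sets into the seven exclusive regions."""
    a, h, o = set(aurum_ids), set(hes_ids), set(ons_ids)
    aho = a & h & o
    return ConcordancePartition(
        aurum_only=len(a - h - o),
        hes_only=len(h - a - o),
        ons_only=len(o - a - h),
        aurum_hes=len((a & h) - o),
        aurum_ons=len((a & o) - h),
        hes_ons=len((h & o) - a),
        all_three=len(aho),
    )


def derive_pairwise_from_marginals(total: int, n_aurum: int, n_hes: int,
                                   n_ons: int, aurum_ons: int, hes_ons: int,
                                   all_three: int,
                                   aurum_or_hes_and_ons: int | None = None,
                                   ) -> ConcordancePartition:
    """Reconstruct the full seven-region partition from printed marginals.

    Solves |A∩H| by inclusion–exclusion from the union total, then derives
    every exclusive region; raises when any derived region is negative or the
    (A∪H)∩O cross-check fails.
    """
    if aurum_or_hes_and_ons is not None:
        implied = aurum_ons + hes_ons - all_three
        if implied != aurum_or_hes_and_ons:
            raise InfeasibleRecipeError(
                f"(A∪H)∩O = {aurum_or_hes_and_ons} inconsistent with "
                f"|A∩O|+|H∩O|-|A∩H∩O| = {implied}"
            )
    aurum_hes = n_aurum + n_hes + n_ons - aurum_ons - hes_ons + all_three - total
    regions = {
        "aurum_hes_total": aurum_hes,
        "aurum_hes": aurum_hes - all_three,
        "aurum_ons": aurum_ons - all_three,
        "hes_ons": hes_ons - all_three,
    }
    regions["aurum_only"] = (n_aurum - regions["aurum_hes"]
                             - regions["aurum_ons"] - all_three)
    regions["hes_only"] = (n_hes - regions["aurum_hes"]
                           - regions["hes_ons"] - all_three)
    regions["ons_only"] = (n_ons - regions["aurum_ons"]
                           - regions["hes_ons"] - all_three)
    for name, value in regions.items():
        if value < 0:
            raise InfeasibleRecipeError(f"region {name} is negative ({value})")
    return ConcordancePartition(
        aurum_only=regions["aurum_only"], hes_only=regions["hes_only"],
        ons_only=regions["ons_only"], aurum_hes=regions["aurum_hes"],
        aurum_ons=regions["aurum_ons"], hes_ons=regions["hes_ons"],
        all_three=all_three,
    )


def _deceased_in_study(patient: LinkedPatient, config: StudyConfig) -> bool:
    death = patient.registry.death_date
    return death is not None and config.study_start <= death <= config.study_end


def validate(da: AlgorithmDefinition, cohort: Sequence[LinkedPatient],
             gold_mode: DeathCauseMode = DeathCauseMode.ANYWHERE,
             config: StudyConfig | None = None,
             targets: frozenset[str] = IPF_ICD10_TARGETS) -> ValidationResult:
    """PPV and sensitivity of one algorithm over the deceased cohort members."""
    config = config or StudyConfig()
    deceased = [p for p in cohort if _deceased_in_study(p, config)]
    n_gold = sum(death_has_ipf(p.death, targets, gold_mode) for p in deceased)
    flagged = [p for p in deceased if apply_algorithm(da, p, config, targets)]
    n_true = sum(death_has_ipf(p.death, targets, gold_mode) for p in flagged)
    return ValidationResult(da.id, n_found=len(flagged), n_true=n_true,
                            n_gold=n_gold)


@dataclass(frozen=True)
class SourceMembership:
    """Patient-id sets for the three sources, restricted to the deceased."""

    aurum: frozenset[str]
    hes: frozenset[str]
    ons: frozenset[str]

    def partition(self) -> ConcordancePartition:
        return concordance(self.aurum, self.hes, self.ons)


def source_membership(cohort: Sequence[LinkedPatient],
                      config: StudyConfig | None = None,
                      gold_mode: DeathCauseMode = DeathCauseMode.ANYWHERE,
                      position_rule: PositionRule = PositionRule.PRIMARY_OR_SECONDARY,
                      targets: frozenset[str] = IPF_ICD10_TARGETS,
                      ) -> SourceMembership:
    """Concordance membership per source, among patients who died in-study.

    Primary care: any broad code dated up to ``death_grace_days`` after death
    (late data entry around the death is tolerated). Hospital: a qualifying
    admission inside follow-up and no later than death. Deaths: an IPF code on
    the certificate under ``gold_mode``.
    """
    from datetime import timedelta

    config = config or StudyConfig()
    grace = timedelta(days=config.death_grace_days)
    aurum, hes, ons = set(), set(), set()
    for patient in cohort:
        if not _deceased_in_study(patient, config):
            continue
        death_date = patient.registry.death_date
        pid = patient.patient_id
        if (patient.earliest_broad is not None
                and patient.earliest_broad <= death_date + grace):
            aurum.add(pid)
        window = patient.window(config, with_diagnosis=False)
        if window is not None:
            admission = has_qualifying_admission(
                patient.spells, targets, position_rule, window)
            if admission is not None and admission <= death_date:
                hes.add(pid)
        if death_has_ipf(patient.death, targets, gold_mode):
            ons.add(pid)
    return SourceMembership(frozenset(aurum), frozenset(hes), frozenset(ons))


@dataclass(frozen=True)
class GoldSensitivityResult:
    """Concordance under the two gold-standard definitions."""

    anywhere: ConcordancePartition
    underlying: ConcordancePartition
    #: share of the primary-care cohort confirmed under the stricter standard
    aurum_confirmed_share: float
    #: share of the hospital cohort confirmed under the stricter standard
    hes_confirmed_share: float
    #: all-three region share of the restricted union total
    triple_share: float


def sensitivity_analysis_gold(cohort: Sequence[LinkedPatient],
                              config: StudyConfig | None = None,
                              targets: frozenset[str] = IPF_ICD10_TARGETS,
                              ) -> GoldSensitivityResult:
    """Re-run concordance with certificate membership restricted to deaths
    where IPF is the *underlying* cause."""
    config = config or StudyConfig()
    base = source_membership(cohort, config, DeathCauseMode.ANYWHERE,
                             targets=targets)
    strict = source_membership(cohort, config, DeathCauseMode.UNDERLYING_ONLY,
                               targets=targets)
    part_any = base.partition()
    part_und = strict.partition()
    n_aurum = len(base.aurum)
    n_hes = len(base.hes)
    return GoldSensitivityResult(
        anywhere=part_any,
        underlying=part_und,
        aurum_confirmed_share=(len(base.aurum & strict.ons) / n_aurum
                               if n_aurum else float("nan")),
        hes_confirmed_share=(len(base.hes & strict.ons) / n_hes
                             if n_hes else float("nan")),
        triple_share=(part_und.all_three / part_und.total
                      if part_und.total else float("nan")),
    )


@dataclass(frozen=True)
class PositionSensitivityResult:
    """Hospital-cohort size and certificate coverage under the two position
    rules (primary/secondary vs top three diagnostic positions)."""

    n_primary_or_secondary: int
    n_top3: int
    ons_share_primary_or_secondary: float
    ons_share_top3: float


def sensitivity_analysis_positions(cohort: Sequence[LinkedPatient],
                                   config: StudyConfig | None = None,
                                   targets: frozenset[str] = IPF_ICD10_TARGETS,
                                   ) -> PositionSensitivityResult:
    """Widen the hospital case definition from positions 1-2 to 1-3 and
    report the cohort growth and the change in certificate coverage."""
    config = config or StudyConfig()
    narrow_rule = source_membership(
        cohort, config, position_rule=PositionRule.PRIMARY_OR_SECONDARY,
        targets=targets)
    wide_rule = source_membership(
        cohort, config, position_rule=PositionRule.TOP3, targets=targets)
    n12, n123 = len(narrow_rule.hes), len(wide_rule.hes)
    return PositionSensitivityResult(
        n_primary_or_secondary=n12,
        n_top3=n123,
        ons_share_primary_or_secondary=(
            len(narrow_rule.hes & narrow_rule.ons) / n12 if n12 else float("nan")),
        ons_share_top3=(
            len(wide_rule.hes & wide_rule.ons) / n123 if n123 else float("nan")),
    )


class ValidationStudy:
    """A validation study over a linked, study-eligible cohort.

    Parameters
    ----------
    cohort : sequence of LinkedPatient
        Study-eligible patients (see :func:`ipflink.casefinding.link_cohort`).
    algorithms : mapping or sequence of AlgorithmDefinition, optional
        Defaults to the eight canonical algorithms.
    gold_mode : DeathCauseMode
        The gold-standard definition (default: IPF anywhere on certificate).
    config : StudyConfig
    """

    def __init__(self, cohort: Sequence[LinkedPatient],
                 algorithms: Mapping[str, AlgorithmDefinition] | Sequence[AlgorithmDefinition] | None = None,
                 gold_mode: DeathCauseMode = DeathCauseMode.ANYWHERE,
                 config: StudyConfig | None = None,
                 targets: frozenset[str] = IPF_ICD10_TARGETS):
        if algorithms is None:
            algorithms = ALGORITHM_PRESETS
        if isinstance(algorithms, Mapping):
            algorithms = list(algorithms.values())
        if not algorithms:
            raise ValueError("at least one algorithm required")
        self.cohort = list(cohort)
        self.algorithms = list(algorithms)
        self.gold_mode = gold_mode
        self.config = config or StudyConfig()
        self.targets = targets

    def fit(self) -> "ValidationResults":
        """Run every algorithm, the concordance partition and both
        sensitivity analyses."""
        results = {
            da.id: validate(da, self.cohort, self.gold_mode, self.config,
                            self.targets)
            for da in self.algorithms
        }
        membership = source_membership(self.cohort, self.config, self.gold_mode,
                                       targets=self.targets)
        return ValidationResults(
            study=self,
            results=results,
            membership=membership,
            concordance=membership.partition(),
            gold_sensitivity=sensitivity_analysis_gold(
                self.cohort, self.config, self.targets),
            position_sensitivity=sensitivity_analysis_positions(
                self.cohort, self.config, self.targets),
        )


@dataclass
class ValidationResults:
    """Fitted results of a :class:`ValidationStudy`."""

    study: ValidationStudy
    results: dict[str, ValidationResult]
    membership: SourceMembership
    concordance: ConcordancePartition
    gold_sensitivity: GoldSensitivityResult
    position_sensitivity: PositionSensitivityResult

    def frame(self) -> pd.DataFrame:
        """Per-algorithm results as a DataFrame (one row per algorithm)."""
        rows = []
        for rid, r in self.results.items():
            ppv_ci = r.ppv_ci or (float("nan"), float("nan"))
            sens_ci = r.sensitivity_ci or (float("nan"), float("nan"))
            rows.append({
                "algorithm": rid,
                "n_found": r.n_found,
                "n_true": r.n_true,
                "ppv_pct": round_pct(r.ppv) if r.ppv is not None else float("nan"),
                "ppv_ci_low_pct": round_pct(ppv_ci[0]),
                "ppv_ci_high_pct": round_pct(ppv_ci[1]),
                "sensitivity_pct": (round_pct(r.sensitivity)
                                    if r.sensitivity is not None else float("nan")),
                "sens_ci_low_pct": round_pct(sens_ci[0]),
                "sens_ci_high_pct": round_pct(sens_ci[1]),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """A printable validation table plus the concordance headline."""
        lines = []
        n_gold = next(iter(self.results.values())).n_gold if self.results else 0
        lines.append("Case-finding algorithm validation "
                     f"(gold standard: IPF {self.study.gold_mode.value}, "
                     f"n_gold = {n_gold:,})")
        lines.append("-" * 78)
        lines.append(f"{'algorithm':<10}{'found':>8}{'true':>8}"
                     f"{'PPV %':>9}{'95% CI':>16}{'sens %':>9}{'95% CI':>16}")
        for rid, r in self.results.items():
            ppv_ci = r.ppv_ci or (float("nan"),) * 2
            sens_ci = r.sensitivity_ci or (float("nan"),) * 2
            ppv = round_pct(r.ppv) if r.ppv is not None else float("nan")
            sens = (round_pct(r.sensitivity) if r.sensitivity is not None
                    else float("nan"))
            lines.append(
                f"{rid:<10}{r.n_found:>8,}{r.n_true:>8,}{ppv:>9.1f}"
                f"{round_pct(ppv_ci[0]):>7.1f}-{round_pct(ppv_ci[1]):<8.1f}"
                f"{sens:>9.1f}"
                f"{round_pct(sens_ci[0]):>7.1f}-{round_pct(sens_ci[1]):<8.1f}"
            )
        c = self.concordance
        lines.append("-" * 78)
        lines.append(f"Three-source concordance: total {c.total:,}; "
                     f"all three sources {c.all_three:,} "
                     f"({round_pct(c.all_three / c.total):.1f}%)")
        lines.append(
            f"Certificate cases captured by either living-record source: "
            f"{c.n_aurum_or_hes_and_ons:,} of {c.n_ons:,} "
            f"({round_pct(c.n_aurum_or_hes_and_ons / c.n_ons):.1f}%)")
        return "\n".join(lines)
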