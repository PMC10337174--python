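"""Case definitions and the eight diagnostic case-finding algorithms.

Each algorithm is a Boolean conjunction over a patient's linked records:

==== ==========================================================================
DA1  any broad primary-care code
DA2  broad code + thoracic CT evidence + no other recorded ILD cause
DA3  any narrow primary-care code
DA4  narrow code + thoracic CT evidence + no other recorded ILD cause
DA5  IPF ICD-10 code in diagnostic position 1-2 of any hospital episode
DA6  DA5 + thoracic CT evidence
DA7  broad code + qualifying hospital admission
DA8  narrow code + qualifying hospital admission
==== ==========================================================================

A "qualifying admission" carries J84.1/J84.8/J84.9 at a position allowed by the
position rule, in any episode of the spell, with the admission date inside the
patient's follow-up window.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

from .core import (
    ClinicalEvent,
    CodeList,
    DeathRecord,
    HospitalSpell,
    ImagingEvent,
    IPF_ICD10_TARGETS,
    BodyRegion,
    Modality,
    PatientRegistryRow,
    icd10_matches,
)
from .eligibility import FollowUpWindow, StudyConfig, followup_window
from .errors import ConfigurationError

__all__ = [
    "PositionRule",
    "DeathCauseMode",
    "AlgorithmDefinition",
    "LinkedPatient",
    "ALGORITHM_PRESETS",
    "earliest_code_match",
    "has_qualifying_admission",
    "death_has_ipf",
    "has_hrct_evidence",
    "has_other_ild_cause",
    "apply_algorithm",
    "link_cohort",
]


class PositionRule(enum.Enum):
    """Which diagnostic positions of a hospital episode may qualify."""

    PRIMARY_OR_SECONDARY = "primary_or_secondary_any_episode"
    TOP3 = "top3_any_episode"
    ANY = "any_position"

    @property
    def allowed_positions(self) -> frozenset[int]:
        if self is PositionRule.PRIMARY_OR_SECONDARY:
            return frozenset({1, 2})
        if self is PositionRule.TOP3:
            return frozenset({1, 2, 3})
        return frozenset(range(1, 21))


class DeathCauseMode(enum.Enum):
    """Whether an IPF death means IPF anywhere on the certificate or only as
    the underlying cause."""

    ANYWHERE = "anywhere"
    UNDERLYING_ONLY = "underlying_only"


@dataclass(frozen=True)
class AlgorithmDefinition:
    """A declarative case-finding algorithm: a conjunction of source criteria."""

    id: str
    aurum_codeset: str = "none"  # broad | narrow | none
    require_hospitalisation: bool = False
    position_rule: PositionRule = PositionRule.PRIMARY_OR_SECONDARY
    require_hrct: bool = False
    exclude_other_ild: bool = False

    def __post_init__(self) -> None:
        if self.aurum_codeset not in ("broad", "narrow", "none"):
            raise ConfigurationError(
                f"algorithm {self.id}: aurum_codeset must be broad/narrow/none"
            )
        if self.aurum_codeset == "none" and not self.require_hospitalisation:
            raise ConfigurationError(
                f"algorithm {self.id}: at least one source criterion required"
            )


#: The eight canonical algorithms.
ALGORITHM_PRESETS: dict[str, AlgorithmDefinition] = {
    "DA1": AlgorithmDefinition("DA1", aurum_codeset="broad"),
    "DA2": AlgorithmDefinition("DA2", aurum_codeset="broad",
                               require_hrct=True, exclude_other_ild=True),
    "DA3": AlgorithmDefinition("DA3", aurum_codeset="narrow"),
    "DA4": AlgorithmDefinition("DA4", aurum_codeset="narrow",
                               require_hrct=True, exclude_other_ild=True),
    "DA5": AlgorithmDefinition("DA5", require_hospitalisation=True),
    "DA6": AlgorithmDefinition("DA6", require_hospitalisation=True,
                               require_hrct=True),
    "DA7": AlgorithmDefinition("DA7", aurum_codeset="broad",
                               require_hospitalisation=True),
    "DA8": AlgorithmDefinition("DA8", aurum_codeset="narrow",
                               require_hospitalisation=True),
}


def earliest_code_match(events: Iterable[ClinicalEvent],
                        codeset: frozenset[str] | set[str]) -> date | None:
    """Earliest event date whose code is in ``codeset``, or None."""
    dates = [e.event_date for e in events if e.code in codeset]
    return min(dates) if dates else None


def has_qualifying_admission(spells: Sequence[HospitalSpell],
                             targets: frozenset[str] | set[str] = IPF_ICD10_TARGETS,
                             rule: PositionRule = PositionRule.PRIMARY_OR_SECONDARY,
                             window: FollowUpWindow | None = None) -> date | None:
    """Date of the first admission with a target code at an allowed position.

    When a window is supplied, only admissions whose admission date falls
    inside it qualify. Episode order within a spell is irrelevant; only
    positions matter.
    """
    allowed = rule.allowed_positions
    best: date | None = None
    for spell in spells:
        if window is not None and spell.admission_date not in window:
            continue
        hit = any(
            position in allowed and icd10_matches(code, targets)
            for episode in spell.episodes
            for position, code in episode.diagnoses
        )
        if hit and (best is None or spell.admission_date < best):
            best = spell.admission_date
    return best


def death_has_ipf(death: DeathRecord | None,
                  targets: frozenset[str] | set[str] = IPF_ICD10_TARGETS,
                  mode: DeathCauseMode = DeathCauseMode.ANYWHERE) -> bool:
    """IPF on the death certificate, anywhere or as underlying cause only."""
    if death is None:
        return False
    if mode is DeathCauseMode.UNDERLYING_ONLY:
        causes: tuple[str, ...] = (death.underlying_cause,)
    else:
        causes = death.all_causes()
    return any(icd10_matches(c, targets) for c in causes)


def has_hrct_evidence(imaging: Iterable[ImagingEvent]) -> bool:
    """Any thoracic CT record, at any time (the imaging dataset does not
    distinguish high-resolution CT, so any thoracic CT qualifies)."""
    return any(e.modality is Modality.CT and e.body_region is BodyRegion.THORAX
               for e in imaging)


def has_other_ild_cause(events: Iterable[ClinicalEvent],
                        exclusion_codelist: CodeList) -> bool:
    """Any primary-care record, at any date, of a non-IPF ILD cause
    (connective tissue disease, sarcoidosis, exposures, drug toxicity...)."""
    excl = exclusion_codelist.broad
    return any(e.code in excl for e in events)


@dataclass
class LinkedPatient:
    """One patient's records across the three linked sources, with the
    derived quantities the algorithms consume precomputed at link time."""

    registry: PatientRegistryRow
    events: tuple[ClinicalEvent, ...] = ()
    spells: tuple[HospitalSpell, ...] = ()
    imaging: tuple[ImagingEvent, ...] = ()
    death: DeathRecord | None = None
    earliest_broad: date | None = None
    earliest_narrow: date | None = None
    hrct: bool = False
    other_ild: bool = False

    @property
    def patient_id(self) -> str:
        return self.registry.patient_id

    def window(self, config: StudyConfig,
               with_diagnosis: bool = True) -> FollowUpWindow | None:
        """Follow-up window; the diagnosis term is the earliest broad code."""
        diagnosis = self.earliest_broad if with_diagnosis else None
        return followup_window(self.registry, diagnosis, config)


def link_cohort(registry: Sequence[PatientRegistryRow],
                events: Sequence[ClinicalEvent] = (),
                spells: Sequence[HospitalSpell] = (),
                deaths: Sequence[DeathRecord] = (),
                imaging: Sequence[ImagingEvent] = (),
                codelist: CodeList | None = None,
                exclusion_codelist: CodeList | None = None) -> list[LinkedPatient]:
    """Assemble per-patient linked records and precompute derived fields."""
    by_pid_events: dict[str, list[ClinicalEvent]] = {}
    for e in events:
        by_pid_events.setdefault(e.patient_id, []).append(e)
    by_pid_spells: dict[str, list[HospitalSpell]] = {}
    for s in spells:
        by_pid_spells.setdefault(s.patient_id, []).append(s)
    by_pid_imaging: dict[str, list[ImagingEvent]] = {}
    for im in imaging:
        by_pid_imaging.setdefault(im.patient_id, []).append(im)
    by_pid_death: dict[str, DeathRecord] = {d.patient_id: d for d in deaths}

    broad = codelist.broad if codelist is not None else frozenset()
    narrow = codelist.narrow if codelist is not None else frozenset()
    excl = exclusion_codelist.broad if exclusion_codelist is not None else frozenset()

    cohort = []
    for row in registry:
        pid = row.patient_id
        p_events = tuple(by_pid_events.get(pid, ()))
        p_imaging = tuple(by_pid_imaging.get(pid, ()))
        cohort.append(LinkedPatient(
            registry=row,
            events=p_events,
            spells=tuple(sorted(by_pid_spells.get(pid, ()),
                                key=lambda s: s.admission_date)),
            imaging=p_imaging,
            death=by_pid_death.get(pid),
            earliest_broad=earliest_code_match(p_events, broad),
            earliest_narrow=earliest_code_match(p_events, narrow),
            hrct=has_hrct_evidence(p_imaging),
            other_ild=any(e.code in excl for e in p_events),
        ))
    return cohort


def apply_algorithm(da: AlgorithmDefinition, patient: LinkedPatient,
                    config: StudyConfig,
                    targets: frozenset[str] = IPF_ICD10_TARGETS) -> bool:
    """Evaluate one algorithm for one patient (pure: no state is touched).

    The primary-care criterion requires the earliest matching code to fall
    inside the patient's follow-up window; the hospitalisation criterion
    requires a qualifying admission inside the window (computed without the
    primary-care diagnosis term when the algorithm uses no code set).
    """
    if da.aurum_codeset != "none":
        code_date = (patient.earliest_broad if da.aurum_codeset == "broad"
                     else patient.earliest_narrow)
        if code_date is None:
            return False
        window = patient.window(config, with_diagnosis=True)
        if window is None or code_date not in window:
            return False
    else:
        window = patient.window(config, with_diagnosis=False)
        if window is None:
            return False

    if da.require_hospitalisation:
        admission = has_qualifying_admission(
            patient.spells, targets, da.position_rule, window)
        if admission is None:
            return False

    if da.require_hrct and not patient.hrct:
        return False

    if da.exclude_other_ild and patient.other_ild:
        return False

    return True
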