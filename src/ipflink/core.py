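"""Domain types for linked electronic-healthcare records.

The data model mirrors the three-source linkage used in UK respiratory
epidemiology: a primary-care event stream (SNOMED-like clinical codes), hospital
admitted-patient-care spells whose episodes carry positioned ICD-10 diagnoses,
death registrations distinguishing the underlying cause from contributory
causes, and a diagnostic-imaging event table. A rated codelist (yes / maybe /
no) yields the "narrow" (yes only) and "broad" (yes or maybe) case-definition
subsets; "no"-rated codes are never matchable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date

from .errors import IntegrityError

__all__ = [
    "Sex",
    "Modality",
    "BodyRegion",
    "Rating",
    "CodeSystem",
    "PatientRegistryRow",
    "ClinicalEvent",
    "Episode",
    "HospitalSpell",
    "DeathRecord",
    "ImagingEvent",
    "CodeList",
    "normalize_icd10",
    "icd10_matches",
    "IPF_ICD10_TARGETS",
]

#: ICD-10 codes taken to denote IPF in hospital and mortality data
#: (canonical, dot-stripped form): other interstitial pulmonary diseases
#: with fibrosis, other specified, and unspecified.
IPF_ICD10_TARGETS = frozenset({"J841", "J848", "J849"})


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Modality(enum.Enum):
    CT = "CT"
    XRAY = "XRAY"
    MRI = "MRI"
    OTHER = "OTHER"


class BodyRegion(enum.Enum):
    THORAX = "thorax"
    OTHER = "other"


class Rating(enum.Enum):
    YES = "yes"
    MAYBE = "maybe"
    NO = "no"


class CodeSystem(enum.Enum):
    SNOMED_LIKE = "SNOMED_LIKE"
    ICD10 = "ICD10"


@dataclass(frozen=True)
class PatientRegistryRow:
    """Administrative dates governing a patient's eligibility and follow-up."""

    patient_id: str
    birth_date: date
    sex: Sex
    registration_start: date
    last_collection_date: date | None = None
    transfer_out_date: date | None = None
    death_date: date | None = None

    def validate(self) -> None:
        for name in ("registration_start", "last_collection_date",
                     "transfer_out_date", "death_date"):
            value = getattr(self, name)
            if value is not None and value <= self.birth_date:
                raise IntegrityError(
                    f"patient {self.patient_id}: birth_date {self.birth_date} "
                    f"is not strictly before {name} {value}"
                )
        if (self.transfer_out_date is not None
                and self.registration_start > self.transfer_out_date):
            raise IntegrityError(
                f"patient {self.patient_id}: registration_start after transfer_out_date"
            )


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated, coded primary-care record."""

    patient_id: str
    event_date: date
    code: str
    term: str = ""

    def validate(self) -> None:
        if not self.code:
            raise IntegrityError(f"patient {self.patient_id}: empty clinical code")


@dataclass(frozen=True)
class Episode:
    """A consultant episode within a hospital spell.

    ``diagnoses`` is an ordered list of ``(position, icd10_code)`` pairs;
    position 1 is the primary discharge diagnosis and up to 20 are allowed.
    """

    episode_index: int
    diagnoses: tuple[tuple[int, str], ...]

    def validate(self) -> None:
        if self.episode_index < 1:
            raise IntegrityError("episode_index must be >= 1")
        positions = [p for p, _ in self.diagnoses]
        if len(positions) > 20:
            raise IntegrityError("more than 20 diagnosis positions in an episode")
        if positions != list(range(1, len(positions) + 1)):
            raise IntegrityError(
                f"gap in diagnosis positions: got {positions}, expected 1..{len(positions)}"
            )


@dataclass(frozen=True)
class HospitalSpell:
    """An admitted-patient-care stay, subdivided into episodes."""

    patient_id: str
    admission_date: date
    discharge_date: date
    episodes: tuple[Episode, ...]

    def validate(self) -> None:
        if self.admission_date > self.discharge_date:
            raise IntegrityError(
                f"patient {self.patient_id}: admission after discharge"
            )
        if not self.episodes:
            raise IntegrityError(f"patient {self.patient_id}: spell with no episodes")
        for episode in self.episodes:
            episode.validate()


@dataclass(frozen=True)
class DeathRecord:
    """A death registration with an underlying and any contributory causes."""

    patient_id: str
    death_date: date
    underlying_cause: str
    contributory_causes: tuple[str, ...] = ()

    def validate(self) -> None:
        if not self.underlying_cause:
            raise IntegrityError(f"patient {self.patient_id}: empty underlying cause")

    def all_causes(self) -> tuple[str, ...]:
        return (self.underlying_cause,) + self.contributory_causes


@dataclass(frozen=True)
class ImagingEvent:
    """A diagnostic-imaging record (modality and body region)."""

    patient_id: str
    event_date: date
    modality: Modality
    body_region: BodyRegion


@dataclass(frozen=True)
class CodeList:
    """A rated terminology set.

    The narrow subset is the codes rated "yes" (strongly indicative); the
    broad subset adds the "maybe"-rated codes; "no"-rated entries are kept for
    audit but never match.
    """

    name: str
    system: CodeSystem
    entries: tuple[tuple[str, str, Rating], ...]

    def __post_init__(self) -> None:
        codes = [code for code, _, _ in self.entries]
        if len(codes) != len(set(codes)):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise IntegrityError(f"codelist {self.name}: duplicate codes {dupes}")

    @property
    def narrow(self) -> frozenset[str]:
        return frozenset(c for c, _, r in self.entries if r is Rating.YES)

    @property
    def broad(self) -> frozenset[str]:
        return frozenset(
            c for c, _, r in self.entries if r in (Rating.YES, Rating.MAYBE)
        )

    def subset(self, which: str) -> frozenset[str]:
        if which == "narrow":
            return self.narrow
        if which == "broad":
            return self.broad
        raise ValueError(f"unknown codelist subset {which!r}")

    def term_for(self, code: str) -> str:
        for c, term, _ in self.entries:
            if c == code:
                return term
        raise KeyError(code)


def normalize_icd10(code: str) -> str:
    """Canonicalise an ICD-10 code: strip whitespace and dots, upper-case.

    >>> normalize_icd10("J84.1")
    'J841'
    """
    if code is None or not str(code).strip():
        raise ValueError("empty ICD-10 code")
    return str(code).strip().replace(".", "").upper()


def icd10_matches(code: str, targets: frozenset[str] | set[str],
                  exact: bool = False) -> bool:
    """True if ``code`` equals or extends (4th/5th character) a target code.

    ``targets`` must already be canonical. Prefix semantics are the default so
    that national-data subdivisions such as J84.10 still match a listed J84.1;
    pass ``exact=True`` for equality-only matching.
    """
    canon = normalize_icd10(code)
    if exact:
        return canon in targets
    return any(canon == t or canon.startswith(t) for t in targets)
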