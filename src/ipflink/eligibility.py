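"""Study eligibility and usable follow-up windows.

Follow-up starts at the latest of the study start, the diagnosis date (the
earliest qualifying primary-care code, where one exists), the start of the
patient's current registration and their 18th birthday, and ends at the
earliest of the study end, death, the practice's last collection date and the
patient's transfer-out date. A window exists when it covers at least one
calendar day (start <= end, start day inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from .core import PatientRegistryRow

__all__ = ["StudyConfig", "FollowUpWindow", "birthday_at_age",
           "followup_window", "is_study_eligible"]


@dataclass(frozen=True)
class StudyConfig:
    """Study-period parameters.

    ``death_grace_days`` is the post-death window within which a primary-care
    IPF code still counts towards the primary-care arm of the concordance
    analysis (codes are often entered when the death is processed); it is not
    used for follow-up windows.
    """

    study_start: date = date(2008, 1, 1)
    study_end: date = date(2018, 12, 31)
    adult_age_years: int = 18
    death_grace_days: int = 60

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.adult_age_years < 0 or self.death_grace_days < 0:
            raise ValueError("adult_age_years and death_grace_days must be >= 0")


@dataclass(frozen=True)
class FollowUpWindow:
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start after end")

    def __contains__(self, day: date) -> bool:
        return self.start <= day <= self.end


def birthday_at_age(birth_date: date, years: int) -> date:
    """The date a person born on ``birth_date`` turns ``years`` old.

    A 29 February birthday rolls to 1 March in non-leap years.
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    target_year = birth_date.year + years
    try:
        return birth_date.replace(year=target_year)
    except ValueError:
        return date(target_year, 3, 1)


def followup_window(patient: PatientRegistryRow,
                    diagnosis_date: date | None,
                    config: StudyConfig) -> FollowUpWindow | None:
    """Usable follow-up for one patient, or None when none exists.

    Absent optional dates are skipped, never defaulted.
    """
    starts = [config.study_start,
              patient.registration_start,
              birthday_at_age(patient.birth_date, config.adult_age_years)]
    if diagnosis_date is not None:
        starts.append(diagnosis_date)
    ends = [config.study_end]
    for candidate in (patient.death_date, patient.last_collection_date,
                      patient.transfer_out_date):
        if candidate is not None:
            ends.append(candidate)
    start, end = max(starts), min(ends)
    if start > end:
        return None
    return FollowUpWindow(start, end)


def is_study_eligible(patient: PatientRegistryRow,
                      diagnosis_date: date | None,
                      config: StudyConfig) -> bool:
    """Adult at study start and at diagnosis, with non-empty follow-up."""
    adult_on = birthday_at_age(patient.birth_date, config.adult_age_years)
    if adult_on > config.study_start:
        return False
    if diagnosis_date is not None and adult_on > diagnosis_date:
        return False
    return followup_window(patient, diagnosis_date, config) is not None
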