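"""Synthetic linked three-source cohorts.

Two builders are provided:

* :func:`generate` — a stochastic generator with known ground truth, for
  parameter-recovery and property tests. Each patient receives a latent IPF
  label and then, conditionally, primary-care codes (with calendar drift in
  code choice), IPF-coded hospital admissions, a death certificate that may
  carry IPF anywhere or as the underlying cause, thoracic-CT imaging and
  non-IPF-ILD exclusion codes. Non-IPF patients never receive certificate IPF
  codes, which keeps the analytic PPV oracle :func:`expected_ppv` closed-form.

* :func:`build_fixture` — a deterministic patient-level dataset whose
  three-source membership partition and per-algorithm counts equal a printed
  set of marginals (:class:`FixtureRecipe`). Narrow-code, CT and
  underlying-cause flags are assigned by a fixed waterfall, filling the most
  constrained intersection first; dates are schematic (all deaths mid-study)
  because no recipe quantity depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BodyRegion,
    ClinicalEvent,
    CodeList,
    CodeSystem,
    DeathRecord,
    Episode,
    HospitalSpell,
    ImagingEvent,
    Modality,
    PatientRegistryRow,
    Rating,
    Sex,
)
from .errors import ConfigurationError, InfeasibleRecipeError
from .io import write_codelist, write_table
from .validation import derive_pairwise_from_marginals

__all__ = [
    "default_ipf_codelist",
    "default_exclusion_codelist",
    "default_code_drift",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate",
    "expected_ppv",
    "FixtureRecipe",
    "build_fixture",
]


def default_ipf_codelist() -> CodeList:
    """A rated pulmonary-fibrosis codelist in the style of a clinician-rated
    SNOMED set: "yes" codes are strongly indicative of IPF (the narrow set),
    "maybe" codes denote pulmonary fibrosis of any aetiology (broad set adds
    these), "no" codes never match."""
    return CodeList(
        name="ipf_primary_care",
        system=CodeSystem.SNOMED_LIKE,
        entries=(
            ("10001", "idiopathic pulmonary fibrosis", Rating.YES),
            ("10002", "idiopathic fibrosing alveolitis", Rating.YES),
            ("10003", "cryptogenic fibrosing alveolitis", Rating.YES),
            ("10004", "usual interstitial pneumonia", Rating.YES),
            ("20001", "pulmonary fibrosis", Rating.MAYBE),
            ("20002", "diffuse pulmonary fibrosis", Rating.MAYBE),
            ("20003", "fibrosing alveolitis", Rating.MAYBE),
            ("20004", "interstitial pulmonary fibrosis", Rating.MAYBE),
            ("30001", "apical pulmonary fibrosis", Rating.NO),
        ),
    )


def default_exclusion_codelist() -> CodeList:
    """Known non-IPF causes of interstitial lung disease."""
    return CodeList(
        name="other_ild_causes",
        system=CodeSystem.SNOMED_LIKE,
        entries=(
            ("40001", "systemic sclerosis", Rating.YES),
            ("40002", "rheumatoid lung disease", Rating.YES),
            ("40003", "sarcoidosis", Rating.YES),
            ("40004", "hypersensitivity pneumonitis", Rating.YES),
            ("40005", "asbestosis", Rating.YES),
            ("40006", "drug-induced interstitial lung disease", Rating.YES),
        ),
    )


def default_code_drift(start_year: int = 2008,
                       end_year: int = 2018) -> dict[int, dict[str, float]]:
    """Per-year multinomial weights over primary-care codes.

    Emulates the observed drift in UK coding practice over 2008-2018: older
    terms (cryptogenic fibrosing alveolitis, diffuse pulmonary fibrosis)
    decline while the specific "idiopathic pulmonary fibrosis" code and the
    generic "pulmonary fibrosis" code rise.
    """
    first = {"10001": 0.05, "10002": 0.08, "10003": 0.20, "10004": 0.02,
             "20001": 0.25, "20002": 0.28, "20003": 0.10, "20004": 0.02}
    last = {"10001": 0.35, "10002": 0.05, "10003": 0.02, "10004": 0.04,
            "20001": 0.33, "20002": 0.10, "20003": 0.04, "20004": 0.07}
    span = max(end_year - start_year, 1)
    drift = {}
    for year in range(start_year, end_year + 1):
        frac = (year - start_year) / span
        weights = {c: first[c] + frac * (last[c] - first[c]) for c in first}
        total = sum(weights.values())
        drift[year] = {c: w / total for c, w in weights.items()}
    return drift


#: Underlying causes of death assigned to patients whose certificate does not
#: carry IPF as underlying cause (pneumonia, lung cancer, COPD, MI, heart
#: failure, sepsis, respiratory failure, ill-defined).
_OTHER_UNDERLYING = ("J189", "J180", "C349", "J449", "I219", "I500", "A419",
                    "J969", "R688")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the stochastic cohort generator.

    All probabilities are per-patient Bernoulli rates; ``code_drift`` maps a
    calendar year to multinomial weights over primary-care code identifiers.
    Defaults are set so the generated population resembles the study
    conditions: a deceased population enriched for IPF (about 40% true
    cases), broad-code sensitivity of primary-care recording around 70%,
    one in five coded patients carrying a highly specific (narrow) code, and
    certificates capturing about 85% of true cases, roughly 60% of those as
    the underlying cause.
    """

    n_patients: int = 20_000
    seed: int = 0
    p_true_ipf: float = 0.4
    p_gp_broad_given_ipf: float = 0.7
    p_gp_broad_given_not: float = 0.15
    p_narrow_given_broad: float = 0.2
    p_hosp_given_ipf: float = 0.6
    p_hosp_given_not: float = 0.05
    p_death_cert_given_ipf: float = 0.85
    p_underlying_given_cert: float = 0.62
    p_hrct: float = 0.35
    p_other_ild: float = 0.05
    p_position3_only: float = 0.05
    code_drift: dict[int, dict[str, float]] | None = None
    birth_range: tuple[date, date] = (date(1930, 1, 1), date(1960, 12, 31))
    registration_range: tuple[date, date] = (date(2000, 1, 1), date(2014, 12, 31))
    diagnosis_range: tuple[date, date] = (date(2008, 1, 1), date(2017, 12, 31))
    death_range: tuple[date, date] = (date(2008, 6, 1), date(2018, 12, 31))

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for f in fields(self):
            if f.name.startswith("p_"):
                value = getattr(self, f.name)
                if not 0.0 <= value <= 1.0:
                    raise ConfigurationError(
                        f"{f.name}={value} outside [0, 1]")
        for name in ("birth_range", "registration_range", "diagnosis_range",
                     "death_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: start after end")
        drift = self.code_drift if self.code_drift is not None else default_code_drift()
        for year, weights in drift.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"code_drift weights for {year} sum to {total}, not 1")

    def resolved_drift(self) -> dict[int, dict[str, float]]:
        return self.code_drift if self.code_drift is not None else default_code_drift()


@dataclass
class SyntheticCohort:
    """A generated or fixture-built linked dataset plus ground-truth labels."""

    registry: list[PatientRegistryRow]
    events: list[ClinicalEvent]
    spells: list[HospitalSpell]
    deaths: list[DeathRecord]
    imaging: list[ImagingEvent]
    labels: pd.DataFrame
    codelist: CodeList = field(default_factory=default_ipf_codelist)
    exclusion_codelist: CodeList = field(default_factory=default_exclusion_codelist)

    def write(self, out_dir: str | Path) -> None:
        """Write the five tables, the codelists and the label table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.registry, "registry", out / "registry.csv")
        write_table(self.events, "events", out / "events.csv")
        write_table(self.spells, "spells", out / "spells.csv")
        write_table(self.deaths, "deaths", out / "deaths.csv")
        write_table(self.imaging, "imaging", out / "imaging.csv")
        write_codelist(self.codelist, out / "codelist_ipf.tsv")
        write_codelist(self.exclusion_codelist, out / "codelist_exclusions.tsv")
        self.labels.to_csv(out / "labels.tsv", sep="\t", index=False)

    def link(self, config=None):
        """Convenience: assemble LinkedPatient objects with default codelists."""
        from .casefinding import link_cohort

        return link_cohort(self.registry, self.events, self.spells,
                           self.deaths, self.imaging,
                           codelist=self.codelist,
                           exclusion_codelist=self.exclusion_codelist)


def _uniform_dates(rng: np.random.Generator, lo: date, hi: date,
                   n: int) -> np.ndarray:
    lo_ord, hi_ord = lo.toordinal(), hi.toordinal()
    return rng.integers(lo_ord, hi_ord + 1, size=n)


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a linked cohort from the generative model; reproducible by seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    drift = config.resolved_drift()
    drift_years = sorted(drift)
    codelist = default_ipf_codelist()
    exclusions = default_exclusion_codelist()
    narrow_codes = sorted(codelist.narrow)
    broad_codes = sorted(codelist.broad)
    excl_codes = sorted(exclusions.broad)

    true_ipf = rng.random(n) < config.p_true_ipf
    p_code = np.where(true_ipf, config.p_gp_broad_given_ipf,
                      config.p_gp_broad_given_not)
    broad = rng.random(n) < p_code
    narrow = broad & (rng.random(n) < config.p_narrow_given_broad)
    p_hosp = np.where(true_ipf, config.p_hosp_given_ipf, config.p_hosp_given_not)
    hosp = rng.random(n) < p_hosp
    pos3_only = (~hosp) & (rng.random(n) < config.p_position3_only)
    cert = true_ipf & (rng.random(n) < config.p_death_cert_given_ipf)
    underlying = cert & (rng.random(n) < config.p_underlying_given_cert)
    hrct = rng.random(n) < config.p_hrct
    other_ild = rng.random(n) < config.p_other_ild

    births = _uniform_dates(rng, *config.birth_range, n)
    regs = _uniform_dates(rng, *config.registration_range, n)
    diag_lo = np.maximum(regs, config.diagnosis_range[0].toordinal())
    diag_hi = config.diagnosis_range[1].toordinal()
    diag_lo = np.minimum(diag_lo, diag_hi)
    index_dates = diag_lo + (rng.random(n)
                             * (diag_hi - diag_lo + 1)).astype(np.int64)
    death_lo = np.maximum(index_dates, config.death_range[0].toordinal())
    death_hi = max(config.death_range[1].toordinal(), int(death_lo.max()))
    deaths_ord = death_lo + (rng.random(n)
                             * (death_hi - death_lo + 1)).astype(np.int64)
    deaths_ord = np.minimum(deaths_ord, death_hi)

    sex_draw = rng.random(n) < 0.63  # male share as seen in IPF populations
    other_underlying_idx = rng.integers(0, len(_OTHER_UNDERLYING), size=n)
    spell_secondary = rng.random(n) < 0.5  # IPF at position 1 vs 2

    registry, events, spells, death_records, imaging = [], [], [], [], []
    label_rows = []
    for i in range(n):
        pid = f"G{i:07d}"
        index_day = date.fromordinal(int(index_dates[i]))
        death_day = date.fromordinal(int(deaths_ord[i]))
        registry.append(PatientRegistryRow(
            patient_id=pid,
            birth_date=date.fromordinal(int(births[i])),
            sex=Sex.MALE if sex_draw[i] else Sex.FEMALE,
            registration_start=date.fromordinal(int(regs[i])),
            death_date=death_day,
        ))
        if broad[i]:
            year = index_day.year
            if year not in drift:
                year = min(drift_years, key=lambda y: abs(y - year))
            pool = narrow_codes if narrow[i] else [
                c for c in broad_codes if c not in codelist.narrow]
            weights = np.array([drift[year].get(c, 0.0) for c in pool])
            if weights.sum() <= 0:
                weights = np.ones(len(pool))
            weights = weights / weights.sum()
            code = pool[int(rng.choice(len(pool), p=weights))]
            events.append(ClinicalEvent(pid, index_day, code,
                                        codelist.term_for(code)))
        if other_ild[i]:
            code = excl_codes[i % len(excl_codes)]
            events.append(ClinicalEvent(
                pid, index_day - timedelta(days=180), code,
                exclusions.term_for(code)))
        if hosp[i] or pos3_only[i]:
            admission = min(index_day + timedelta(days=90), death_day)
            if pos3_only[i]:
                diagnoses = ((1, "I500"), (2, "J449"), (3, "J841"))
            elif spell_secondary[i]:
                diagnoses = ((1, "I500"), (2, "J841"))
            else:
                diagnoses = ((1, "J841"),)
            spells.append(HospitalSpell(
                pid, admission, min(admission + timedelta(days=7), death_day)
                if admission <= death_day else admission,
                (Episode(1, diagnoses),)))
        if underlying[i]:
            death_records.append(DeathRecord(pid, death_day, "J841", ("J969",)))
        elif cert[i]:
            death_records.append(DeathRecord(
                pid, death_day,
                _OTHER_UNDERLYING[int(other_underlying_idx[i])], ("J841",)))
        else:
            death_records.append(DeathRecord(
                pid, death_day,
                _OTHER_UNDERLYING[int(other_underlying_idx[i])]))
        if hrct[i]:
            imaging.append(ImagingEvent(pid, index_day + timedelta(days=30),
                                        Modality.CT, BodyRegion.THORAX))
        label_rows.append({
            "patient_id": pid, "true_ipf": bool(true_ipf[i]),
            "broad_coded": bool(broad[i]), "narrow_coded": bool(narrow[i]),
            "hospitalised": bool(hosp[i]), "pos3_only": bool(pos3_only[i]),
            "cert_ipf": bool(cert[i]), "cert_underlying": bool(underlying[i]),
            "hrct": bool(hrct[i]), "other_ild": bool(other_ild[i]),
            "index_date": index_day.isoformat(),
            "death_date": death_day.isoformat(),
        })
    return SyntheticCohort(registry, events, spells, death_records, imaging,
                           labels=pd.DataFrame(label_rows),
                           codelist=codelist, exclusion_codelist=exclusions)


def expected_ppv(config: GeneratorConfig) -> float:
    """Analytic PPV of the broad-code algorithm under the generative model.

    Conditioning on a deceased, broad-coded patient:
    P(certificate IPF) = p_true * p_code|ipf * p_cert /
                         (p_true * p_code|ipf + (1 - p_true) * p_code|not),
    using the model convention that non-IPF patients never receive
    certificate IPF codes. Coding, hospitalisation and death timing are
    mutually independent given the latent label, so the deceased restriction
    leaves the ratio unchanged.
    """
    num = (config.p_true_ipf * config.p_gp_broad_given_ipf
           * config.p_death_cert_given_ipf)
    den = (config.p_true_ipf * config.p_gp_broad_given_ipf
           + (1.0 - config.p_true_ipf) * config.p_gp_broad_given_not)
    if den == 0:
        raise ValueError("expected_ppv undefined: nobody is broad-coded")
    return num / den


@dataclass(frozen=True)
class FixtureRecipe:
    """Printed marginal counts that the deterministic fixture reproduces.

    Defaults are the counts of the validation study this package models:
    17,559 deceased adults with an IPF record in at least one of the three
    linked sources, the per-algorithm found/confirmed counts, the pairwise
    and triple source overlaps, the underlying-cause subsets, and the
    hospital-cohort size under the relaxed top-3 position rule.
    """

    total: int = 17_559
    n_aurum: int = 9_498
    n_hes: int = 10_714
    n_ons: int = 11_295
    aurum_ons: int = 6_113
    hes_ons: int = 6_651
    all_three: int = 4_304
    aurum_or_hes_and_ons: int = 8_460
    da2_found: int = 4_721
    da2_true: int = 3_187
    da3_found: int = 1_828
    da3_true: int = 1_370
    da4_found: int = 891
    da4_true: int = 706
    da6_found: int = 2_985
    da6_true: int = 2_379
    da8_found: int = 1_190
    da8_true: int = 974
    ons_underlying: int = 7_029
    aurum_ons_underlying: int = 4_159
    hes_ons_underlying: int = 4_756
    triple_underlying: int = 3_119
    top3_total: int = 13_957


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise InfeasibleRecipeError(message)


def build_fixture(recipe: FixtureRecipe | None = None) -> SyntheticCohort:
    """Build the deterministic marginal-matched fixture dataset.

    The seven exclusive membership regions are derived from the recipe by
    inclusion–exclusion; narrow-code, thoracic-CT and underlying-cause flags
    are then allocated region by region, most-constrained intersection first,
    so that every algorithm's (found, confirmed) pair equals the recipe. The
    build involves no randomness: two builds are identical.
    """
    recipe = recipe or FixtureRecipe()
    partition = derive_pairwise_from_marginals(
        recipe.total, recipe.n_aurum, recipe.n_hes, recipe.n_ons,
        recipe.aurum_ons, recipe.hes_ons, recipe.all_three,
        recipe.aurum_or_hes_and_ons)

    region_sizes = {
        "all_three": partition.all_three,
        "aurum_hes": partition.aurum_hes,
        "aurum_ons": partition.aurum_ons,
        "hes_ons": partition.hes_ons,
        "aurum_only": partition.aurum_only,
        "hes_only": partition.hes_only,
        "ons_only": partition.ons_only,
    }

    # -- narrow-code allocation (tightest constraint first: the triple region
    #    carries the hospital-confirmed narrow patients) --------------------
    narrow = {name: 0 for name in region_sizes}
    narrow["all_three"] = recipe.da8_true
    narrow["aurum_hes"] = recipe.da8_found - recipe.da8_true
    narrow["aurum_ons"] = recipe.da3_true - recipe.da8_true
    narrow["aurum_only"] = (recipe.da3_found - recipe.da3_true
                            - narrow["aurum_hes"])
    for name, count in narrow.items():
        _require(count >= 0, f"narrow allocation negative in region {name}")
        _require(count <= region_sizes[name],
                 f"narrow allocation exceeds region {name} "
                 f"({count} > {region_sizes[name]})")

    # -- thoracic-CT allocation. All CT evidence is placed in the four
    #    primary-care regions: the certificate-confirmed CT margin of the
    #    hospital algorithm goes to the triple region, its unconfirmed margin
    #    to Aurum∩HES, and the broad-code CT margins fill Aurum∩ONS and
    #    Aurum-only. Narrow CT patients are nested inside those counts. ------
    narrow_hrct = {name: 0 for name in region_sizes}
    narrow_hrct["all_three"] = min(recipe.da4_true, narrow["all_three"])
    narrow_hrct["aurum_ons"] = recipe.da4_true - narrow_hrct["all_three"]
    non_confirmed_narrow_ct = recipe.da4_found - recipe.da4_true
    _require(non_confirmed_narrow_ct >= 0, "da4_true exceeds da4_found")
    narrow_hrct["aurum_hes"] = min(non_confirmed_narrow_ct, narrow["aurum_hes"])
    narrow_hrct["aurum_only"] = (non_confirmed_narrow_ct
                                 - narrow_hrct["aurum_hes"])
    hrct = {name: 0 for name in region_sizes}
    hrct["all_three"] = recipe.da6_true
    hrct["aurum_ons"] = recipe.da2_true - recipe.da6_true
    hrct["aurum_hes"] = recipe.da6_found - recipe.da6_true
    hrct["aurum_only"] = (recipe.da2_found - recipe.da2_true
                          - hrct["aurum_hes"])
    for name in region_sizes:
        _require(narrow_hrct[name] <= narrow[name],
                 f"narrow CT allocation exceeds narrow block in {name}")
        _require(hrct[name] >= narrow_hrct[name],
                 f"CT allocation below its narrow share in {name}")
        _require(0 <= hrct[name] <= region_sizes[name],
                 f"CT allocation infeasible in region {name} ({hrct[name]})")

    # -- underlying-cause allocation within the certificate regions --------
    und = {name: 0 for name in region_sizes}
    und["all_three"] = recipe.triple_underlying
    und["aurum_ons"] = recipe.aurum_ons_underlying - recipe.triple_underlying
    und["hes_ons"] = recipe.hes_ons_underlying - recipe.triple_underlying
    und["ons_only"] = (recipe.ons_underlying - und["all_three"]
                       - und["aurum_ons"] - und["hes_ons"])
    for name in ("all_three", "aurum_ons", "hes_ons", "ons_only"):
        _require(0 <= und[name] <= region_sizes[name],
                 f"underlying-cause allocation infeasible in region {name}")

    n_top3_extra = recipe.top3_total - recipe.n_hes
    _require(n_top3_extra >= 0, "top3_total below the hospital cohort size")

    # -- emit patients ------------------------------------------------------
    codelist = default_ipf_codelist()
    exclusions = default_exclusion_codelist()
    narrow_code, broad_code = "10001", "20001"

    membership = {
        "all_three": (True, True, True),
        "aurum_hes": (True, True, False),
        "aurum_ons": (True, False, True),
        "hes_ons": (False, True, True),
        "aurum_only": (True, False, False),
        "hes_only": (False, True, False),
        "ons_only": (False, False, True),
    }
    birth = date(1940, 1, 15)
    registration = date(2005, 1, 1)
    code_date = date(2012, 3, 1)
    admission = date(2013, 5, 1)
    death_day = date(2015, 6, 30)

    registry, events, spells, death_records, imaging = [], [], [], [], []
    label_rows = []
    counter = 0
    for region, size in region_sizes.items():
        in_a, in_h, in_o = membership[region]
        n_narrow = narrow[region]
        n_narrow_ct = narrow_hrct[region]
        n_ct = hrct[region]
        n_und = und[region]
        for j in range(size):
            pid = f"F{counter:06d}"
            counter += 1
            is_narrow = in_a and j < n_narrow
            # CT flags cover a prefix of the narrow block and a prefix of the
            # non-narrow block, so narrow∩CT and CT margins both land exactly.
            if j < n_narrow:
                has_ct = j < n_narrow_ct
            else:
                has_ct = (j - n_narrow) < (n_ct - n_narrow_ct)
            is_underlying = in_o and j < n_und
            registry.append(PatientRegistryRow(
                pid, birth, Sex.MALE if counter % 2 else Sex.FEMALE,
                registration, death_date=death_day))
            if in_a:
                code = narrow_code if is_narrow else broad_code
                events.append(ClinicalEvent(pid, code_date, code,
                                            codelist.term_for(code)))
            if in_h:
                spells.append(HospitalSpell(
                    pid, admission, admission + timedelta(days=7),
                    (Episode(1, ((1, "J841"),)),)))
            if in_o:
                if is_underlying:
                    death_records.append(
                        DeathRecord(pid, death_day, "J841", ("J969",)))
                else:
                    death_records.append(
                        DeathRecord(pid, death_day, "J189", ("J841",)))
            else:
                death_records.append(DeathRecord(pid, death_day, "I219"))
            if has_ct:
                imaging.append(ImagingEvent(pid, admission, Modality.CT,
                                            BodyRegion.THORAX))
            label_rows.append({
                "patient_id": pid, "region": region,
                "in_aurum": in_a, "in_hes": in_h, "in_ons": in_o,
                "narrow_coded": is_narrow, "hrct": bool(has_ct),
                "cert_underlying": bool(is_underlying),
            })

    # Patients visible to the hospital source only under the relaxed top-3
    # position rule: IPF strictly at position 3, no other IPF records.
    for j in range(n_top3_extra):
        pid = f"T{counter:06d}"
        counter += 1
        registry.append(PatientRegistryRow(
            pid, birth, Sex.MALE if counter % 2 else Sex.FEMALE,
            registration, death_date=death_day))
        spells.append(HospitalSpell(
            pid, admission, admission + timedelta(days=7),
            (Episode(1, ((1, "I500"), (2, "J449"), (3, "J841"))),)))
        death_records.append(DeathRecord(pid, death_day, "J189"))
        label_rows.append({
            "patient_id": pid, "region": "top3_only",
            "in_aurum": False, "in_hes": False, "in_ons": False,
            "narrow_coded": False, "hrct": False, "cert_underlying": False,
        })

    return SyntheticCohort(registry, events, spells, death_records, imaging,
                           labels=pd.DataFrame(label_rows),
                           codelist=codelist, exclusion_codelist=exclusions)
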