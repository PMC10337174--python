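"""Case-definition predicates and the eight diagnostic algorithms."""

import random
from datetime import date, timedelta

import pytest

from ipflink.casefinding import (
    ALGORITHM_PRESETS,
    AlgorithmDefinition,
    DeathCauseMode,
    PositionRule,
    apply_algorithm,
    death_has_ipf,
    earliest_code_match,
    has_hrct_evidence,
    has_other_ild_cause,
    has_qualifying_admission,
    link_cohort,
)
from ipflink.core import (
    BodyRegion,
    ClinicalEvent,
    DeathRecord,
    Episode,
    HospitalSpell,
    ImagingEvent,
    Modality,
)
from ipflink.eligibility import FollowUpWindow, StudyConfig
from ipflink.errors import ConfigurationError
from ipflink.synthetic import (
    GeneratorConfig,
    default_exclusion_codelist,
    default_ipf_codelist,
    generate,
)
from ipflink.validation import validate

from conftest import make_event, make_registry_row

CONFIG = StudyConfig()


def spell(pid="P1", admission=date(2013, 5, 1), diagnoses=((1, "J841"),),
          episode_index=1):
    return HospitalSpell(pid, admission, admission + timedelta(days=7),
                         (Episode(episode_index, diagnoses),))


class TestEarliestCodeMatch:
    def test_minimum_of_matches(self):
        events = [make_event(day=date(2012, 5, 10)),
                  make_event(day=date(2011, 3, 2))]
        assert earliest_code_match(events, {"B1"}) == date(2011, 3, 2)

    def test_no_match_is_none(self):
        assert earliest_code_match([make_event(code="ZZ")], {"B1"}) is None

    def test_matches_filter_then_min_oracle(self):
        rng = random.Random(11)
        codes = ["B1", "B2", "N1", "ZZ"]
        for _ in range(500):
            events = [make_event(day=date(2010, 1, 1) + timedelta(days=rng.randint(0, 3000)),
                                 code=rng.choice(codes))
                      for _ in range(rng.randint(0, 6))]
            subset = {"B1", "N1"}
            expected = min((e.event_date for e in events if e.code in subset),
                           default=None)
            assert earliest_code_match(events, subset) == expected


class TestQualifyingAdmission:
    def test_secondary_position_qualifies(self):
        s = spell(diagnoses=((1, "I500"), (2, "J841")))
        assert has_qualifying_admission([s]) == s.admission_date

    def test_position_three_needs_top3_rule(self):
        s = spell(diagnoses=((1, "I500"), (2, "J449"), (3, "J841")))
        assert has_qualifying_admission([s], rule=PositionRule.PRIMARY_OR_SECONDARY) is None
        assert has_qualifying_admission([s], rule=PositionRule.TOP3) == s.admission_date

    def test_empty_spell_list(self):
        assert has_qualifying_admission([]) is None

    def test_window_restricts_admissions(self):
        s = spell(admission=date(2013, 5, 1))
        inside = FollowUpWindow(date(2013, 1, 1), date(2014, 1, 1))
        outside = FollowUpWindow(date(2014, 1, 1), date(2015, 1, 1))
        assert has_qualifying_admission([s], window=inside) == s.admission_date
        assert has_qualifying_admission([s], window=outside) is None

    def test_earliest_admission_wins(self):
        late = spell(admission=date(2014, 1, 1))
        early = spell(admission=date(2012, 1, 1))
        assert has_qualifying_admission([late, early]) == date(2012, 1, 1)

    def test_any_episode_counts(self):
        s = HospitalSpell("P1", date(2013, 5, 1), date(2013, 5, 9),
                          (Episode(1, ((1, "I500"),)),
                           Episode(2, ((1, "A419"), (2, "J848")))))
        assert has_qualifying_admission([s]) == s.admission_date


class TestDeathCertificate:
    def test_underlying_matches_both_modes(self):
        death = DeathRecord("P1", date(2015, 1, 1), "J841")
        assert death_has_ipf(death, mode=DeathCauseMode.ANYWHERE)
        assert death_has_ipf(death, mode=DeathCauseMode.UNDERLYING_ONLY)

    def test_contributory_only_fails_underlying_mode(self):
        death = DeathRecord("P1", date(2015, 1, 1), "I219", ("J849",))
        assert death_has_ipf(death, mode=DeathCauseMode.ANYWHERE)
        assert not death_has_ipf(death, mode=DeathCauseMode.UNDERLYING_ONLY)

    def test_no_ipf_code_fails_both(self):
        death = DeathRecord("P1", date(2015, 1, 1), "I219", ("J189",))
        assert not death_has_ipf(death, mode=DeathCauseMode.ANYWHERE)
        assert not death_has_ipf(death, mode=DeathCauseMode.UNDERLYING_ONLY)


class TestHrctAndExclusions:
    def test_ct_thorax_at_any_time(self):
        # even after death: imaging evidence has no date restriction
        assert has_hrct_evidence(
            [ImagingEvent("P1", date(2020, 1, 1), Modality.CT, BodyRegion.THORAX)])

    def test_xray_thorax_is_not_ct(self):
        assert not has_hrct_evidence(
            [ImagingEvent("P1", date(2013, 1, 1), Modality.XRAY, BodyRegion.THORAX)])

    def test_empty_imaging(self):
        assert not has_hrct_evidence([])

    def test_exclusion_any_match(self):
        excl = default_exclusion_codelist()
        hit = ClinicalEvent("P1", date(2010, 1, 1), "40003", "sarcoidosis")
        assert has_other_ild_cause([hit], excl)
        assert not has_other_ild_cause([], excl)
        miss = ClinicalEvent("P1", date(2010, 1, 1), "10001", "ipf")
        assert not has_other_ild_cause([miss], excl)


def _patient(events=(), spells=(), imaging=(), death=None,
             death_date=None):
    codelist = default_ipf_codelist()
    registry = make_registry_row(death=death_date)
    return link_cohort([registry], events, spells,
                       [death] if death else [], imaging,
                       codelist=codelist,
                       exclusion_codelist=default_exclusion_codelist())[0]


class TestApplyAlgorithm:
    def test_presets_match_published_design(self):
        da = ALGORITHM_PRESETS
        assert da["DA1"].aurum_codeset == "broad" and not da["DA1"].require_hrct
        assert da["DA2"].exclude_other_ild and da["DA2"].require_hrct
        assert da["DA3"].aurum_codeset == "narrow"
        assert da["DA4"].aurum_codeset == "narrow" and da["DA4"].require_hrct
        assert da["DA5"].aurum_codeset == "none" and da["DA5"].require_hospitalisation
        assert da["DA6"].require_hrct and da["DA6"].require_hospitalisation
        assert da["DA7"].aurum_codeset == "broad" and da["DA7"].require_hospitalisation
        assert da["DA8"].aurum_codeset == "narrow" and da["DA8"].require_hospitalisation
        for d in da.values():
            assert d.position_rule is PositionRule.PRIMARY_OR_SECONDARY

    def test_broad_code_only_passes_da1_not_da7(self):
        p = _patient(events=[make_event(code="20001")],
                     death_date=date(2015, 6, 30))
        assert apply_algorithm(ALGORITHM_PRESETS["DA1"], p, CONFIG)
        assert not apply_algorithm(ALGORITHM_PRESETS["DA7"], p, CONFIG)

    def test_narrow_plus_admission_passes_da8(self):
        p = _patient(events=[make_event(code="10001")],
                     spells=[spell()], death_date=date(2015, 6, 30))
        assert apply_algorithm(ALGORITHM_PRESETS["DA8"], p, CONFIG)

    def test_exclusion_code_blocks_da2(self):
        p = _patient(events=[make_event(code="20001"),
                             ClinicalEvent("P1", date(2009, 1, 1), "40001", "ssc")],
                     imaging=[ImagingEvent("P1", date(2013, 1, 1),
                                           Modality.CT, BodyRegion.THORAX)],
                     death_date=date(2015, 6, 30))
        assert apply_algorithm(ALGORITHM_PRESETS["DA1"], p, CONFIG)
        assert not apply_algorithm(ALGORITHM_PRESETS["DA2"], p, CONFIG)

    def test_rejects_algorithm_without_criteria(self):
        with pytest.raises(ConfigurationError):
            AlgorithmDefinition("empty", aurum_codeset="none",
                                require_hospitalisation=False)

    def test_purity_order_independence(self):
        p1 = _patient(events=[make_event(code="20001")],
                      death_date=date(2015, 6, 30))
        first = apply_algorithm(ALGORITHM_PRESETS["DA1"], p1, CONFIG)
        assert first == apply_algorithm(ALGORITHM_PRESETS["DA1"], p1, CONFIG)


@pytest.fixture(scope="module")
def generated():
    cohort = generate(GeneratorConfig(n_patients=4000, seed=99)).link()
    return {da_id: validate(da, cohort).n_found
            for da_id, da in ALGORITHM_PRESETS.items()}


class TestCountMonotonicity:
    """Adding conjuncts or narrowing a code set never grows a cohort."""

    @pytest.mark.parametrize("smaller, larger", [
        ("DA3", "DA1"), ("DA4", "DA2"), ("DA2", "DA1"),
        ("DA8", "DA7"), ("DA7", "DA1"), ("DA6", "DA5"), ("DA7", "DA5"),
    ])
    def test_pairwise(self, generated, smaller, larger):
        assert generated[smaller] <= generated[larger]


def test_position_rule_relaxation_never_removes_patients():
    cohort = generate(GeneratorConfig(n_patients=3000, seed=5,
                                      p_position3_only=0.3)).link()
    rules = [PositionRule.PRIMARY_OR_SECONDARY, PositionRule.TOP3,
             PositionRule.ANY]
    qualifying = []
    for rule in rules:
        qualifying.append({
            p.patient_id for p in cohort
            if has_qualifying_admission(p.spells, rule=rule,
                                        window=p.window(CONFIG, False))})
    assert qualifying[0] <= qualifying[1] <= qualifying[2]
    assert qualifying[0] != qualifying[1]  # generator created position-3-only
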