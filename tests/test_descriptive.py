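"""Coding trends, cohort profiles, and non-concordant death causes."""

from datetime import date, timedelta

import pytest

from ipflink.casefinding import link_cohort
from ipflink.core import ClinicalEvent, DeathRecord
from ipflink.descriptive import (
    code_usage_by_year,
    cohort_profile,
    noncordant_death_causes,
)
from ipflink.synthetic import (
    GeneratorConfig,
    default_ipf_codelist,
    generate,
)

from conftest import make_event, make_registry_row

CODELIST = default_ipf_codelist()


class TestCodeUsageByYear:
    def test_counts_by_year_and_code(self):
        events = ([make_event(day=date(2010, 1, 1 + i), code="20001")
                   for i in range(5)]
                  + [make_event(day=date(2011, 2, 1 + i), code="20002")
                     for i in range(3)])
        table = code_usage_by_year(events, CODELIST, (2008, 2018))
        rows = {(r.year, r.code): r.event_count
                for r in table.frame.itertuples()}
        assert rows == {(2010, "20001"): 5, (2011, "20002"): 3}

    def test_total_events_conserved_and_shares_sum_to_one(self):
        cohort = generate(GeneratorConfig(n_patients=3000, seed=21))
        table = code_usage_by_year(cohort.events, CODELIST, (2008, 2018))
        matching = [e for e in cohort.events
                    if e.code in CODELIST.broad
                    and 2008 <= e.event_date.year <= 2018]
        assert table.frame["event_count"].sum() == len(matching)
        shares = table.shares().groupby("year")["share"].sum()
        assert (shares - 1.0).abs().max() < 1e-12

    def test_empty_stream_gives_empty_table(self):
        table = code_usage_by_year([], CODELIST, (2008, 2018))
        assert table.frame.empty

    def test_empty_year_range_rejected(self):
        with pytest.raises(ValueError):
            code_usage_by_year([], CODELIST, (2018, 2008))

    def test_rejected_codes_never_counted(self):
        events = [make_event(code="30001")]  # rated "no"
        table = code_usage_by_year(events, CODELIST, (2008, 2018))
        assert table.frame.empty


SMOKING = {"S_NEV": "never", "S_EX": "ex", "S_CUR": "current"}


def _cohort(rows):
    registry, events, deaths = [], [], []
    for pid, birth, diag_day, death_day, extra_events in rows:
        registry.append(make_registry_row(pid=pid, birth=birth, death=death_day))
        events.append(make_event(pid=pid, day=diag_day, code="20001"))
        events.extend(extra_events)
        if death_day:
            deaths.append(DeathRecord(pid, death_day, "I219"))
    return link_cohort(registry, events, deaths=deaths, codelist=CODELIST)


class TestCohortProfile:
    def test_median_survival(self):
        diag = date(2010, 1, 1)
        rows = [(f"P{i}", date(1940, 1, 1), diag,
                 diag + timedelta(days=round(365.25 * y)), [])
                for i, y in enumerate([1, 2, 3])]
        profile = cohort_profile(_cohort(rows))
        assert profile.median_survival_years == pytest.approx(2.0, abs=0.01)
        assert profile.n == 3

    def test_smoking_closest_record_wins(self):
        diag = date(2010, 6, 1)
        extra = [ClinicalEvent("P0", diag - timedelta(days=10), "S_NEV", ""),
                 ClinicalEvent("P0", diag - timedelta(days=2), "S_CUR", "")]
        rows = [("P0", date(1940, 1, 1), diag, date(2012, 1, 1), extra)]
        profile = cohort_profile(_cohort(rows), smoking_codes=SMOKING)
        assert profile.pct_ever_current_smoker == 100.0

    def test_smoking_unknown_excluded_from_denominator(self):
        diag = date(2010, 6, 1)
        rows = [("P0", date(1940, 1, 1), diag, date(2012, 1, 1),
                 [ClinicalEvent("P0", diag - timedelta(days=5), "S_NEV", "")]),
                ("P1", date(1941, 1, 1), diag, date(2013, 1, 1), [])]
        profile = cohort_profile(_cohort(rows), smoking_codes=SMOKING)
        assert profile.n_smoking_known == 1
        assert profile.pct_ever_current_smoker == 0.0

    def test_comorbidity_on_index_day_not_counted(self):
        diag = date(2010, 6, 1)
        rows = [("P0", date(1940, 1, 1), diag, date(2012, 1, 1),
                 [ClinicalEvent("P0", diag, "CM1", "")]),
                ("P1", date(1941, 1, 1), diag, date(2013, 1, 1),
                 [ClinicalEvent("P1", diag - timedelta(days=1), "CM1", "")])]
        profile = cohort_profile(_cohort(rows),
                                 comorbidity_codelists={"copd": {"CM1"}})
        assert profile.comorbidity_pct["copd"] == pytest.approx(50.0)

    def test_age_and_male_share(self):
        diag = date(2010, 6, 1)
        rows = [("P0", date(1940, 6, 2), diag, date(2012, 1, 1), []),
                ("P1", date(1940, 5, 31), diag, date(2012, 1, 1), [])]
        profile = cohort_profile(_cohort(rows))
        # birthday the day after index: still 69; the day before: already 70
        assert profile.median_age == 69.5
        assert profile.pct_65_plus == 100.0
        assert profile.pct_male == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_profile([])

    def test_order_invariant(self):
        cohort = generate(GeneratorConfig(n_patients=500, seed=31)).link()
        cohort = [p for p in cohort if p.earliest_broad is not None]
        forward = cohort_profile(cohort)
        backward = cohort_profile(list(reversed(cohort)))
        assert forward == backward


class TestNoncordantDeathCauses:
    def test_ranking_with_lexicographic_ties(self):
        registry, events, deaths = [], [], []
        causes = ["J189", "J189", "J189", "C349", "C349", "A419", "B999"]
        for i, cause in enumerate(causes):
            pid = f"P{i}"
            registry.append(make_registry_row(pid=pid, death=date(2015, 6, 30)))
            events.append(make_event(pid=pid, code="20001"))
            deaths.append(DeathRecord(pid, date(2015, 6, 30), cause))
        cohort = link_cohort(registry, events, deaths=deaths, codelist=CODELIST)
        ranked = noncordant_death_causes(cohort, "aurum")
        assert ranked == [("J189", 3), ("C349", 2), ("A419", 1), ("B999", 1)]

    def test_full_concordance_gives_empty_list(self):
        registry = [make_registry_row(pid="P0", death=date(2015, 6, 30))]
        events = [make_event(pid="P0", code="20001")]
        deaths = [DeathRecord("P0", date(2015, 6, 30), "J841")]
        cohort = link_cohort(registry, events, deaths=deaths, codelist=CODELIST)
        assert noncordant_death_causes(cohort, "aurum") == []

    def test_counts_match_brute_force_on_generator_output(self):
        cohort = generate(GeneratorConfig(n_patients=2000, seed=41)).link()
        ranked = dict(noncordant_death_causes(cohort, "hes"))
        assert sum(ranked.values()) > 0
        # brute force: hospital-flagged deceased without any J84 cause
        from ipflink.validation import source_membership

        hes = source_membership(cohort).hes
        expected: dict[str, int] = {}
        for p in cohort:
            if (p.patient_id in hes and p.death is not None
                    and not any(c.startswith("J84") for c in p.death.all_causes())):
                expected[p.death.underlying_cause] = \
                    expected.get(p.death.underlying_cause, 0) + 1
        assert ranked == expected

    def test_noncordant_plus_concordant_equals_flagged(self, fixture_cohort):
        ranked = noncordant_death_causes(fixture_cohort, "aurum")
        from ipflink.validation import source_membership

        membership = source_membership(fixture_cohort)
        concordant = len(membership.aurum & membership.ons)
        assert sum(n for _, n in ranked) + concordant == len(membership.aurum)
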