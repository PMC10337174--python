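# Methods

## The validation design

The package models a record-linkage validation study of IPF recording. Three
concurrent sources can each assert that a patient has IPF: primary-care
clinical codes, IPF-coded hospital admissions, and the death certificate.
Because no practical reference diagnosis exists for a disease managed in
secondary care, the death registration is used as the gold standard — a
patient with J84.1/J84.8/J84.9 anywhere on the certificate is taken to truly
have had IPF — and every validation quantity is therefore computed over
patients who died inside the study window. This is an imperfect standard
(patients who die *with* undiagnosed IPF, or of something else entirely, are
invisible to it); the underlying-cause sensitivity analysis quantifies one
direction of that imperfection.

## Eligibility and follow-up

Usable follow-up runs from the latest of study start (default 2008-01-01),
the diagnosis date (the earliest broad primary-care code, when one exists),
registration start and the 18th birthday, to the earliest of study end
(default 2018-12-31), death, last data collection and transfer-out. A window
exists when it covers at least one calendar day (start-day inclusive, the
minimal reading of "1 day of usable follow-up"). Eligibility additionally
requires adulthood at study start and at diagnosis. Two conventions the
source rules leave open: 29 February birthdays roll to 1 March in non-leap
years, and patients present only in hospital/death data take their first
qualifying admission as index date.

## Case definitions

* **Primary care.** A rated codelist yields a narrow subset ("yes"-rated,
  strongly indicative) and a broad subset ("yes" or "maybe"); "no"-rated
  codes never match. Codes are opaque identifiers — no ontology traversal —
  because the design matches flat clinician-rated lists.
* **Hospital.** A qualifying admission carries an IPF ICD-10 code at an
  allowed diagnostic position (default: 1–2, i.e. primary or secondary
  diagnosis; the sensitivity analysis relaxes this to 1–3) in any episode of
  the spell, with the admission date inside follow-up. ICD-10 matching is
  prefix-based after dot-stripping, so national 4th/5th-character
  subdivisions (J84.10) still match a listed 3-character.1 code; an
  `exact=True` flag disables this.
* **Imaging.** Any thoracic CT, at any time: the imaging dataset does not
  distinguish high-resolution CT, and no date restriction is applied (the
  imaging feed starts later than the study window; this is a documented
  limitation, not a bug).
* **Exclusions.** Any record, at any date, of a known non-IPF ILD cause
  (connective tissue disease, sarcoidosis, exposures, drug toxicity).

The eight preset algorithms combine these: DA1/DA3 are bare broad/narrow
code sets; DA2/DA4 add CT plus the ILD exclusion; DA5/DA6 are
hospital-based (alone, plus CT); DA7/DA8 conjoin broad/narrow codes with a
hospitalisation. For DA7/DA8 the admission must fall in the same follow-up
window as for DA5 — the source design is silent, and symmetry is adopted.

## Statistics

PPV and sensitivity are binomial proportions with Wilson score intervals
(bounds pinned to 0/1 exactly at x = 0 and x = n). The score interval was
chosen because the study this models does not name its CI method and Wilson
behaves sensibly at the extreme proportions the narrow algorithms produce;
printed CI bounds are consequently not reproduction targets, only point
estimates. The certificate-case denominator is shared across algorithms.
Percentages are reported to one decimal, rounded half away from zero, via
the shortest-decimal representation so that true half-cases round up.

Concordance partitions three deceased membership sets into seven exclusive
regions. Primary-care membership tolerates a code up to 60 days after death
(late data entry around death registration); that grace window applies only
here, never to follow-up. `derive_pairwise_from_marginals` inverts the
partition from printed marginals by inclusion–exclusion and rejects any
marginal set implying a negative region.

## The synthetic cohort

**Generator.** Each patient draws a latent IPF label, then conditionally:
broad primary-care coding (sensitivity ~0.7 for true cases, false-positive
coding rate 0.15), a narrow code for one in five coded patients, an
IPF-coded admission (0.6 true / 0.05 false), a certificate IPF code for 85%
of true cases (underlying cause for 62% of those), plus independent CT,
exclusion-code and position-3-only flags. Non-IPF patients never receive
certificate IPF codes; that convention makes the broad-code PPV available in
closed form (`expected_ppv`), which the recovery tests exploit: empirical
PPV at n = 50,000 must sit within 3 Monte-Carlo standard errors of the
analytic value for at least 19 of 20 random configurations. Code identity is
drawn from per-year multinomial weights that shift mass from historic terms
(cryptogenic fibrosing alveolitis, diffuse pulmonary fibrosis) to the modern
IPF-specific and generic pulmonary-fibrosis codes over 2008–2018, emulating
observed coding drift. Default rates were chosen once to give a deceased,
IPF-enriched population whose broad-code PPV lands near the mid-60s percent
seen in practice. What the generator does **not** emulate: comorbidity
correlation structure, repeated registrations, multi-spell admission
histories, certificate false positives (available by relabelling), or
realistic death-rate age structure — so passing tests demonstrate internal
consistency of the pipeline, not fidelity to any real population.

**Fixture.** The deterministic fixture inverts the published marginal counts
into the seven exclusive regions (2,201 / 2,879 / 2,835 / 1,184 / 1,809 /
2,347 / 4,304 patients; total 17,559) and then assigns narrow-code, CT and
underlying-cause flags by a fixed waterfall, filling the most-constrained
intersection first (e.g. the hospital-confirmed narrow block in the triple
region), so that each algorithm's found/confirmed pair equals the printed
counts exactly. Any allocation satisfying the marginals would do — every
target depends only on marginal counts — determinism is for test stability,
not uniqueness. 3,243 extra patients carry IPF strictly at diagnostic
position 3 (and no other IPF record), growing the hospital cohort to 13,957
under the relaxed rule; their certificate overlap is not constrained by any
printed count and is not targeted. Fixture dates are schematic (identical
mid-study deaths) because no targeted quantity depends on dates; date logic
is exercised by the generator and unit tests instead.

## Known inconsistencies in the modelled counts

The published table prints PPVs of 64.3% and 62.0% for DA1/DA5 where the
printed counts give 6,113/9,498 = 64.4% and 6,651/10,714 = 62.1%; the
printed DA1/DA5 sensitivities (53.5%, 57.0%) disagree with the counts
(54.1%, 58.9%). The package reports the count-derived values; acceptance
checks allow the 0.1-point rounding slack and skip the two inconsistent
sensitivities. The fixture's population total follows the running text
(17,559), not the conflicting table header (17,557).

## Problem sizes

The fixture pipeline (20,802 patients) fits in about two seconds; recovery
tests use 50,000-patient generator draws; property suites use 1,000–6,000
random patients per invariant. All test data are generated at run time;
nothing is stored.
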