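"""Cohort construction, status resolution and coverage accounting."""

import random
from datetime import date

import pytest

from smokestat import (
    CohortSpec,
    Patient,
    StructuredSmokingEntry,
    annotate_corpus,
    build_cohort,
    cohort_frame,
    coverage_by_source,
    coverage_by_year,
    resolve_all,
    resolve_patient_status,
)
from smokestat.patient_pipeline import care_months, months_between
from smokestat.rule_engine import ClinicalDocument, SmokingAnnotation

WINDOW = (date(2008, 1, 1), date(2011, 12, 31))


def patient(pid="p1", age=40.0, referral=date(2009, 6, 1), months=24, **kw):
    end = None
    if months is not None:
        y, m = divmod(referral.month - 1 + months, 12)
        end = date(referral.year + y, m + 1, referral.day)
    defaults = dict(
        patient_id=pid, age_at_referral=age, sex="male", marital="single",
        deprivation_tertile="middle", diagnosis="schizophrenia",
        referral_date=referral, care_end_date=end,
    )
    defaults.update(kw)
    return Patient(**defaults)


def make_doc(doc_id, pid, when, text):
    return ClinicalDocument(doc_id, pid, when, "progress_note", text)


def ann(doc_id, status):
    return SmokingAnnotation(doc_id, 0, 5, "smoke", status, f"{status}:test")


# ---------------------------------------------------------------------------
# months arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "start, end, months",
    [
        (date(2008, 1, 15), date(2009, 1, 15), 12),
        (date(2008, 1, 15), date(2009, 1, 14), 11),
        (date(2008, 1, 31), date(2008, 2, 28), 0),
        (date(2008, 2, 1), date(2008, 3, 1), 1),
    ],
)
def test_calendar_month_arithmetic(start, end, months):
    assert months_between(start, end) == months


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def test_age_over_15_is_exclusive():
    spec = CohortSpec(referral_window=WINDOW)
    assert build_cohort([patient(age=15.0)], spec) == []
    assert len(build_cohort([patient(age=16.0)], spec)) == 1


def test_care_duration_threshold():
    spec12 = CohortSpec(referral_window=WINDOW, min_care_months=12)
    spec_none = CohortSpec(referral_window=WINDOW, min_care_months=None)
    short = patient(months=11)
    assert build_cohort([short], spec12) == []
    assert build_cohort([short], spec_none) == [short]
    assert build_cohort([patient(months=12)], spec12) != []
    # an open episode satisfies any duration requirement
    assert build_cohort([patient(months=None)], spec12) != []
    assert care_months(patient(months=None)) is None


def test_referral_window_filter_and_idempotence():
    spec = CohortSpec(referral_window=WINDOW)
    inside = patient("in", referral=date(2010, 5, 1))
    before = patient("early", referral=date(2007, 12, 31))
    after = patient("late", referral=date(2012, 1, 1))
    cohort = build_cohort([inside, before, after], spec)
    assert [p.patient_id for p in cohort] == ["in"]
    assert build_cohort(cohort, spec) == cohort


def test_hand_enumerated_register_membership():
    """20 patients with known attributes against all three filters."""
    spec = CohortSpec(referral_window=WINDOW, min_age_exclusive=15, min_care_months=12)
    pts, expected = [], []
    for i in range(20):
        age = 14 + i  # 14..33: the first two fail the age filter
        months = 6 + i  # 6..25: months < 12 fail the care filter
        referral = date(2007 + i % 6, 3, 1)  # 2007 and 2012 out of window
        pid = f"h{i:02d}"
        pts.append(patient(pid, age=age, referral=referral, months=months))
        if age > 15 and months >= 12 and WINDOW[0] <= referral <= WINDOW[1]:
            expected.append(pid)
    assert [p.patient_id for p in build_cohort(pts, spec)] == expected
    assert expected  # the fixture must keep someone


# ---------------------------------------------------------------------------
# Status resolution
# ---------------------------------------------------------------------------

def test_earliest_record_wins_across_sources():
    p = patient(referral=date(2009, 6, 1))
    d = make_doc("d1", "p1", date(2009, 6, 4), "xxxxx")  # day 3 after referral
    structured = [StructuredSmokingEntry("p1", date(2009, 6, 11), "current")]
    res = resolve_patient_status([ann("d1", "never")], {"d1": d}, structured, p)
    assert (res.status, res.source) == ("never", "text")


def test_records_before_referral_are_discarded():
    p = patient(referral=date(2009, 6, 1))
    d = make_doc("d1", "p1", date(2009, 5, 20), "xxxxx")
    structured = [StructuredSmokingEntry("p1", date(2009, 1, 2), "current")]
    assert resolve_patient_status([ann("d1", "never")], {"d1": d}, structured, p) is None


def test_same_date_structured_beats_text(fixtures):
    f = fixtures["same-date-conflict"]
    anns = annotate_corpus(f.documents)
    res = resolve_all(f.documents, anns, f.structured, [f.patient])
    status = res[f.patient.patient_id]
    assert status.status == f.expected["resolved_status"]
    assert status.source == f.expected["resolved_source"]


def test_same_date_text_tie_prefers_affirmative(fixtures):
    f = fixtures["text-tie"]
    anns = annotate_corpus(f.documents)
    res = resolve_all(f.documents, anns, f.structured, [f.patient])
    status = res[f.patient.patient_id]
    assert status.status == f.expected["resolved_status"]
    assert status.source == f.expected["resolved_source"]


def test_tie_break_is_configurable(fixtures):
    f = fixtures["same-date-conflict"]
    anns = annotate_corpus(f.documents)
    res = resolve_all(f.documents, anns, f.structured, [f.patient],
                      source_priority=("text", "structured"))
    assert res[f.patient.patient_id].source == "text"


def test_resolution_is_order_invariant(register, annotations):
    cohort = build_cohort(register.patients, CohortSpec(referral_window=WINDOW))
    base = resolve_all(register.documents, annotations, register.structured, cohort)
    rng = random.Random(0)
    docs, anns, structured, members = (
        list(register.documents), list(annotations),
        list(register.structured), list(cohort),
    )
    for seq in (docs, anns, structured, members):
        rng.shuffle(seq)
    shuffled = resolve_all(docs, anns, structured, members)
    assert shuffled == base


def test_one_status_per_patient(register, annotations):
    cohort = build_cohort(register.patients, CohortSpec(referral_window=WINDOW))
    resolved = resolve_all(register.documents, annotations, register.structured, cohort)
    assert len(resolved) <= len(cohort)
    assert set(resolved) <= {p.patient_id for p in cohort}
    for pid, status in resolved.items():
        assert status.patient_id == pid


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def test_structured_only_never_exceeds_combined(register, annotations):
    cohort = build_cohort(register.patients, CohortSpec(referral_window=WINDOW))
    resolved = resolve_all(register.documents, annotations, register.structured, cohort)
    cov = coverage_by_source(cohort, resolved, register.structured).set_index("source")
    assert (
        cov.loc["structured_only", "n_with_status"]
        <= cov.loc["structured_plus_text", "n_with_status"]
    )


def test_full_structured_coverage_reads_100_percent():
    pts = [patient(f"p{i}", referral=date(2009, 1, 1)) for i in range(10)]
    structured = [StructuredSmokingEntry(p.patient_id, date(2009, 1, 5), "current") for p in pts]
    resolved = resolve_all([], [], structured, pts)
    cov = coverage_by_source(pts, resolved, structured)
    assert (cov["percent"] == 100.0).all()


def test_empty_cohort_coverage_is_an_error():
    with pytest.raises(ValueError):
        coverage_by_source([], {}, [])


def test_constant_coverage_has_no_trend():
    pts, structured = [], []
    for year in (2008, 2009, 2010):
        for i in range(10):
            pid = f"{year}-{i}"
            pts.append(patient(pid, referral=date(year, 2, 1)))
            if i < 5:  # 50% coverage every year
                structured.append(StructuredSmokingEntry(pid, date(year, 2, 2), "past"))
    resolved = resolve_all([], [], structured, pts)
    df = coverage_by_year(pts, resolved, structured, [2008, 2009, 2010])
    assert df.attrs["trend_p_all_sources"] == pytest.approx(1.0)
    assert (df["all_sources_pct"] == 50.0).all()


def test_rising_coverage_detected_as_trend():
    pts, structured = [], []
    rates = {2008: 0.4, 2009: 0.5, 2010: 0.6}
    for year, rate in rates.items():
        for i in range(400):
            pid = f"{year}-{i}"
            pts.append(patient(pid, referral=date(year, 2, 1)))
            if i < rate * 400:
                structured.append(StructuredSmokingEntry(pid, date(year, 2, 2), "past"))
    resolved = resolve_all([], [], structured, pts)
    df = coverage_by_year(pts, resolved, structured, [2008, 2009, 2010])
    assert df.attrs["trend_p_all_sources"] < 0.001


def test_year_without_patients_is_omitted():
    pts = [patient("a", referral=date(2008, 2, 1)), patient("b", referral=date(2010, 2, 1))]
    df = coverage_by_year(pts, {}, [], [2008, 2009, 2010])
    assert list(df["year"]) == [2008, 2010]


# ---------------------------------------------------------------------------
# End-to-end ground-truth recovery
# ---------------------------------------------------------------------------

def test_explicit_notes_without_missingness_recover_truth():
    from smokestat import SimulationConfig, generate_register

    cfg = SimulationConfig(
        n_patients=300, seed=11, missing_coefficients=None,
        p_mention=1.0, out_of_lexicon_rate=0.0, ambiguous_rate=0.0,
    )
    reg = generate_register(cfg)
    anns = annotate_corpus(reg.documents)
    cohort = build_cohort(reg.patients, CohortSpec(referral_window=WINDOW))
    resolved = resolve_all(reg.documents, anns, reg.structured, cohort)
    assert set(resolved) == {p.patient_id for p in cohort}  # 100% coverage
    for pid, status in resolved.items():
        assert status.status == reg.truth.true_status[pid]
    frame = cohort_frame(cohort, resolved)
    assert not frame["missing"].any()
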