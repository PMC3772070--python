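"""Patient-level smoking-status resolution and cohort construction.

Text-derived annotations (dated by their source document) are pooled with
clinician-entered structured-field entries; the earliest record on or after
the referral date defines the patient's status.  Cohorts are built from a
referral window, a minimum age at referral, and (optionally) a minimum
duration of active care measured in calendar months.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .rule_engine import STATUSES, ClinicalDocument, SmokingAnnotation

logger = logging.getLogger("smokestat")

SEXES = ("male", "female")
MARITAL = ("single", "cohabiting", "separated_widowed", "unknown")
DEPRIVATION = ("least", "middle", "most", "unknown")
DIAGNOSES = ("schizophrenia", "schizoaffective", "bipolar", "other")

SOURCE_STRUCTURED = "structured"
SOURCE_TEXT = "text"

#: tie-break when a structured entry and a text annotation share a date:
#: the deliberate clinician-entered field is the stronger evidence.
DEFAULT_SOURCE_PRIORITY = (SOURCE_STRUCTURED, SOURCE_TEXT)
#: tie-break between same-day text annotations with different statuses:
#: affirmative mentions are the higher-precision signal.
DEFAULT_STATUS_PRIORITY = ("current", "past", "never")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    age_at_referral: float
    sex: str
    marital: str
    deprivation_tertile: str
    diagnosis: str
    referral_date: Date
    care_end_date: Optional[Date] = None  # None = episode still open

    def __post_init__(self) -> None:
        if self.age_at_referral <= 0:
            raise ValueError("age_at_referral must be positive")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.marital not in MARITAL:
            raise ValueError(f"unknown marital status {self.marital!r}")
        if self.deprivation_tertile not in DEPRIVATION:
            raise ValueError(f"unknown deprivation tertile {self.deprivation_tertile!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.care_end_date is not None and self.care_end_date < self.referral_date:
            raise ValueError("care_end_date precedes referral_date")


@dataclass(frozen=True)
class StructuredSmokingEntry:
    patient_id: str
    date: Date
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class PatientSmokingStatus:
    """The resolved per-patient status: first record on/after referral."""

    patient_id: str
    status: str
    date: Date
    source: str


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion rules: referral window, minimum age (exclusive) and, when
    set, a minimum number of calendar months of active care."""

    referral_window: tuple[Date, Date]
    min_age_exclusive: float = 15.0
    min_care_months: Optional[int] = 12

    def __post_init__(self) -> None:
        if self.referral_window[0] > self.referral_window[1]:
            raise ValueError("referral window start is after its end")


def months_between(start: Date, end: Date) -> int:
    """Whole calendar months from start to end (day-of-month aware)."""
    if end < start:
        return -months_between(end, start)
    months = (end.year - start.year) * 12 + (end.month - start.month)
    if end.day < start.day:
        months -= 1
    return months


def care_months(patient: Patient) -> Optional[int]:
    """Completed months of active care; None for an open episode."""
    if patient.care_end_date is None:
        return None
    return months_between(patient.referral_date, patient.care_end_date)


def build_cohort(patients: Iterable[Patient], spec: CohortSpec) -> list[Patient]:
    """Apply the referral-window, age and care-duration filters.

    Open care episodes satisfy any care-duration requirement.  Records with
    malformed dates are rejected with a logged diagnostic rather than
    aborting the run.
    """
    lo, hi = spec.referral_window
    out: list[Patient] = []
    for p in patients:
        try:
            if not (lo <= p.referral_date <= hi):
                continue
            if p.age_at_referral <= spec.min_age_exclusive:
                continue
            if spec.min_care_months is not None:
                months = care_months(p)
                if months is not None and months < spec.min_care_months:
                    continue
        except TypeError as exc:  # malformed / non-date field
            logger.warning("rejecting patient %s: %s", p.patient_id, exc)
            continue
        out.append(p)
    return out


def resolve_patient_status(
    annotations: Sequence[SmokingAnnotation],
    documents: Mapping[str, ClinicalDocument],
    structured: Sequence[StructuredSmokingEntry],
    patient: Patient,
    source_priority: Sequence[str] = DEFAULT_SOURCE_PRIORITY,
    status_priority: Sequence[str] = DEFAULT_STATUS_PRIORITY,
) -> Optional[PatientSmokingStatus]:
    """Resolve one patient's smoking status from both record sources.

    Dated records from the structured field and from text annotations (each
    dated by its source document) are pooled; records before the referral
    date are discarded; the earliest surviving record wins.  Same-date ties
    fall first to the configured source priority, then to the status
    priority.  Returns None when nothing survives — the "missing smoking
    information" state.
    """
    records: list[tuple[Date, int, int, str, str]] = []
    src_rank = {s: i for i, s in enumerate(source_priority)}
    st_rank = {s: i for i, s in enumerate(status_priority)}
    for entry in structured:
        if entry.patient_id != patient.patient_id:
            raise ValueError("structured entry belongs to another patient")
        records.append(
            (entry.date, src_rank[SOURCE_STRUCTURED], st_rank[entry.status],
             entry.status, SOURCE_STRUCTURED)
        )
    for ann in annotations:
        doc = documents[ann.doc_id]
        if doc.patient_id != patient.patient_id:
            raise ValueError("annotation belongs to another patient")
        records.append(
            (doc.date, src_rank[SOURCE_TEXT], st_rank[ann.status],
             ann.status, SOURCE_TEXT)
        )
    records = [r for r in records if r[0] >= patient.referral_date]
    if not records:
        return None
    date, _, _, status, source = min(records)
    return PatientSmokingStatus(
        patient_id=patient.patient_id, status=status, date=date, source=source
    )


def resolve_all(
    documents: Sequence[ClinicalDocument],
    annotations: Sequence[SmokingAnnotation],
    structured: Sequence[StructuredSmokingEntry],
    cohort: Sequence[Patient],
    **tie_breaks,
) -> dict[str, PatientSmokingStatus]:
    """Resolve every cohort patient; patients with no record are absent from
    the result (they are the missing-information group)."""
    docs_by_id = {d.doc_id: d for d in documents}
    anns_by_patient: dict[str, list[SmokingAnnotation]] = {}
    for ann in annotations:
        pid = docs_by_id[ann.doc_id].patient_id
        anns_by_patient.setdefault(pid, []).append(ann)
    struct_by_patient: dict[str, list[StructuredSmokingEntry]] = {}
    for entry in structured:
        struct_by_patient.setdefault(entry.patient_id, []).append(entry)

    out: dict[str, PatientSmokingStatus] = {}
    for patient in cohort:
        resolved = resolve_patient_status(
            anns_by_patient.get(patient.patient_id, []),
            docs_by_id,
            struct_by_patient.get(patient.patient_id, []),
            patient,
            **tie_breaks,
        )
        if resolved is not None:
            out[patient.patient_id] = resolved
    return out


AGE_BANDS = ("15-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+")


def age_band(age: float) -> str:
    """Ten-year age band used in the descriptive tables."""
    for band in AGE_BANDS[:-1]:
        hi = int(band.split("-")[1])
        if age <= hi:
            return band
    return "75+"


def cohort_frame(
    cohort: Sequence[Patient], resolved: Mapping[str, PatientSmokingStatus]
) -> pd.DataFrame:
    """One row per cohort patient: demographics, resolved smoking status
    (NaN when missing), and derived analysis columns.

    ``current`` is 1/0 among patients with a known status; ``missing`` flags
    patients with no smoking record.  Deprivation is also scored 0/1/2 for
    trend tests and ordinal regression (NaN when unknown).
    """
    dep_score = {"least": 0, "middle": 1, "most": 2}
    rows = []
    for p in cohort:
        status = resolved.get(p.patient_id)
        rows.append(
            {
                "patient_id": p.patient_id,
                "age": p.age_at_referral,
                "age_band": age_band(p.age_at_referral),
                "age_65_plus": int(p.age_at_referral >= 65),
                "sex": p.sex,
                "marital": p.marital,
                "deprivation": p.deprivation_tertile,
                "deprivation_score": dep_score.get(p.deprivation_tertile),
                "diagnosis": p.diagnosis,
                "referral_year": p.referral_date.year,
                "status": status.status if status else None,
                "source": status.source if status else None,
                "missing": status is None,
                "current": (status.status == "current") if status else None,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["age_band"] = pd.Categorical(df["age_band"], categories=list(AGE_BANDS), ordered=True)
        df["sex"] = pd.Categorical(df["sex"], categories=list(SEXES))
        df["marital"] = pd.Categorical(df["marital"], categories=list(MARITAL))
        df["deprivation"] = pd.Categorical(
            df["deprivation"], categories=list(DEPRIVATION), ordered=True
        )
        df["diagnosis"] = pd.Categorical(df["diagnosis"], categories=list(DIAGNOSES))
    return df


# ---------------------------------------------------------------------------
# Coverage summaries
# ---------------------------------------------------------------------------

def _structured_only(
    structured: Sequence[StructuredSmokingEntry], cohort: Sequence[Patient]
) -> set[str]:
    """Patients ascertainable from the structured field alone (an entry on
    or after referral)."""
    referral = {p.patient_id: p.referral_date for p in cohort}
    return {
        e.patient_id
        for e in structured
        if e.patient_id in referral and e.date >= referral[e.patient_id]
    }


def coverage_by_source(
    cohort: Sequence[Patient],
    resolved: Mapping[str, PatientSmokingStatus],
    structured: Sequence[StructuredSmokingEntry],
) -> pd.DataFrame:
    """Counts and percentages of cohort patients with any smoking status,
    by information source: structured field only, and structured plus
    text-derived annotations."""
    if not cohort:
        raise ValueError("coverage percentages are undefined for an empty cohort")
    n = len(cohort)
    ids = {p.patient_id for p in cohort}
    n_structured = len(_structured_only(structured, cohort))
    n_combined = len(set(resolved) & ids)
    df = pd.DataFrame(
        {
            "source": ["structured_only", "structured_plus_text"],
            "n_with_status": [n_structured, n_combined],
            "cohort_n": [n, n],
        }
    )
    df["percent"] = 100.0 * df["n_with_status"] / df["cohort_n"]
    return df


def coverage_by_year(
    cohort: Sequence[Patient],
    resolved: Mapping[str, PatientSmokingStatus],
    structured: Sequence[StructuredSmokingEntry],
    years: Sequence[int],
) -> pd.DataFrame:
    """Per-referral-year coverage under each source regime, with a
    Cochran–Armitage linear-trend p-value per regime (requires >= 3 years)."""
    from .epi_stats import ContingencyTable, cochran_armitage

    struct_ids = _structured_only(structured, cohort)
    rows = []
    for year in years:
        members = [p for p in cohort if p.referral_date.year == year]
        if not members:
            logger.warning("coverage_by_year: no patients referred in %d; row omitted", year)
            continue
        ids = {p.patient_id for p in members}
        n = len(members)
        k_struct = len(ids & struct_ids)
        k_all = len(ids & set(resolved))
        rows.append(
            {
                "year": year,
                "n": n,
                "structured_only_n": k_struct,
                "structured_only_pct": 100.0 * k_struct / n,
                "all_sources_n": k_all,
                "all_sources_pct": 100.0 * k_all / n,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 3:
        for regime in ("structured_only", "all_sources"):
            table = ContingencyTable(
                row_labels=[str(y) for y in df["year"]],
                col_labels=["with_status", "without_status"],
                counts=[
                    [int(k), int(n - k)]
                    for k, n in zip(df[f"{regime}_n"], df["n"])
                ],
                ordinal=True,
            )
            _, p = cochran_armitage(table)
            df.attrs[f"trend_p_{regime}"] = p
    return df
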