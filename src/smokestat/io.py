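"""File round-trips: line-delimited corpora and annotations, delimited
tables, and rule-set configuration documents.

Corpora and annotation streams are JSON-lines (one record per line, UTF-8);
tables are comma-delimited with a header row and ISO-8601 dates.  All
writers and readers are inverses of each other.
"""

from __future__ import annotations

import json
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .evaluation import GoldAnnotation
from .patient_pipeline import Patient, PatientSmokingStatus, StructuredSmokingEntry
from .rule_engine import ClinicalDocument, RuleSet, SmokingAnnotation

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------

def write_corpus(docs: Iterable[ClinicalDocument], path: PathLike) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps({
                "doc_id": d.doc_id, "patient_id": d.patient_id,
                "date": d.date.isoformat(), "doc_type": d.doc_type, "text": d.text,
            }, ensure_ascii=False) + "\n")
            n += 1
    return n


def read_corpus(path: PathLike) -> list[ClinicalDocument]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(ClinicalDocument(
                doc_id=rec["doc_id"], patient_id=rec["patient_id"],
                date=Date.fromisoformat(rec["date"]),
                doc_type=rec["doc_type"], text=rec["text"],
            ))
    return out


def read_corpus_dir(directory: PathLike, metadata: PathLike) -> list[ClinicalDocument]:
    """Read a directory of plain-text documents with a sidecar metadata table
    (columns: doc_id, patient_id, date, doc_type, filename)."""
    directory = Path(directory)
    meta = pd.read_csv(metadata, dtype=str)
    out = []
    for rec in meta.to_dict("records"):
        text = (directory / rec["filename"]).read_text(encoding="utf-8")
        out.append(ClinicalDocument(
            doc_id=rec["doc_id"], patient_id=rec["patient_id"],
            date=Date.fromisoformat(rec["date"]), doc_type=rec["doc_type"], text=text,
        ))
    return out


# ---------------------------------------------------------------------------
# Annotations (predicted and gold share one schema)
# ---------------------------------------------------------------------------

def write_annotations(
    annotations: Iterable[Union[SmokingAnnotation, GoldAnnotation]], path: PathLike
) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            rec = {"doc_id": a.doc_id, "start": a.start, "end": a.end,
                   "status": a.status}
            if isinstance(a, SmokingAnnotation):
                rec["matched_text"] = a.matched_text
                rec["rule_id"] = a.rule_id
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            n += 1
    return n


def read_annotations(path: PathLike) -> list[SmokingAnnotation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(SmokingAnnotation(
                doc_id=rec["doc_id"], start=rec["start"], end=rec["end"],
                matched_text=rec.get("matched_text", ""),
                status=rec["status"], rule_id=rec.get("rule_id", ""),
            ))
    return out


def read_gold_annotations(path: PathLike) -> list[GoldAnnotation]:
    return [
        GoldAnnotation(a.doc_id, a.start, a.end, a.status)
        for a in read_annotations(path)
    ]


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_patients(patients: Sequence[Patient], path: PathLike) -> int:
    rows = [{
        "patient_id": p.patient_id, "age_at_referral": p.age_at_referral,
        "sex": p.sex, "marital": p.marital,
        "deprivation_tertile": p.deprivation_tertile, "diagnosis": p.diagnosis,
        "referral_date": p.referral_date.isoformat(),
        "care_end_date": p.care_end_date.isoformat() if p.care_end_date else "",
    } for p in patients]
    pd.DataFrame(rows).to_csv(path, index=False)
    return len(rows)


def read_patients(path: PathLike) -> list[Patient]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Patient(
            patient_id=r["patient_id"],
            age_at_referral=float(r["age_at_referral"]),
            sex=r["sex"], marital=r["marital"],
            deprivation_tertile=r["deprivation_tertile"], diagnosis=r["diagnosis"],
            referral_date=Date.fromisoformat(r["referral_date"]),
            care_end_date=Date.fromisoformat(r["care_end_date"]) if r["care_end_date"] else None,
        )
        for r in df.to_dict("records")
    ]


def write_structured(entries: Sequence[StructuredSmokingEntry], path: PathLike) -> int:
    pd.DataFrame([{
        "patient_id": e.patient_id, "date": e.date.isoformat(), "status": e.status,
    } for e in entries]).to_csv(path, index=False)
    return len(entries)


def read_structured(path: PathLike) -> list[StructuredSmokingEntry]:
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        return []
    return [
        StructuredSmokingEntry(r["patient_id"], Date.fromisoformat(r["date"]), r["status"])
        for r in df.to_dict("records")
    ]


def write_resolved(
    resolved: Sequence[PatientSmokingStatus], path: PathLike
) -> int:
    pd.DataFrame([{
        "patient_id": r.patient_id, "status": r.status,
        "date": r.date.isoformat(), "source": r.source,
    } for r in resolved]).to_csv(path, index=False)
    return len(resolved)


def read_resolved(path: PathLike) -> list[PatientSmokingStatus]:
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        return []
    return [
        PatientSmokingStatus(r["patient_id"], r["status"],
                             Date.fromisoformat(r["date"]), r["source"])
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# RuleSet configuration
# ---------------------------------------------------------------------------

_RULESET_FIELDS = (
    "tobacco_terms", "tobacco_objects", "non_tobacco_terms", "negation_cues",
    "past_cues", "current_cues", "third_party_cues", "scope", "max_tokens",
    "abstain_on_conflict",
)


def write_ruleset(rules: RuleSet, path: PathLike) -> None:
    doc = {name: getattr(rules, name) for name in _RULESET_FIELDS}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def read_ruleset(path: PathLike) -> RuleSet:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    unknown = set(doc) - set(_RULESET_FIELDS)
    if unknown:
        raise ValueError(f"unknown rule-set keys: {sorted(unknown)}")
    return RuleSet(**doc)
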