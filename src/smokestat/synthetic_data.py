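"""Seeded synthetic mental-health case registers.

Generates patients, structured smoking-status entries, and free-text
clinical notes with gold-standard mention annotations, so the extraction
rules, the patient pipeline and the statistics can all be exercised without
patient data.  The generator emulates the statistical structure the
analysis assumes:

* demographics drawn from the margins of a secondary-care severe-mental-
  illness cohort (age bands, sex, marital status, deprivation tertiles,
  ICD-10 diagnosis groups);
* a logistic smoking model in those covariates with user-set coefficients;
* a documentation model (documents per patient, per-document mention
  probability, a phrasing mix that includes negations, past-tense mentions,
  non-tobacco distractors, deliberately out-of-lexicon phrasings and
  ambiguous sentences);
* a demographically patterned missingness mechanism: for a "missing"
  patient no record — structured or textual — states smoking status.

Notes are assembled from a template bank; each smoking phrase carries
exactly one gold annotation, distractors carry none.  Identical configs
(including the seed) produce byte-identical registers.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, asdict
from datetime import date as Date, timedelta
from typing import Optional, Sequence

import numpy as np

from .evaluation import GoldAnnotation
from .patient_pipeline import (
    Patient,
    PatientSmokingStatus,
    StructuredSmokingEntry,
)
from .rule_engine import ClinicalDocument, CURRENT, PAST, NEVER, DOC_TYPES


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_AGE_BAND_RANGES = {
    "15-24": (16, 24), "25-34": (25, 34), "35-44": (35, 44),
    "45-54": (45, 54), "55-64": (55, 64), "65-74": (65, 74), "75+": (75, 90),
}

#: default demographic margins: proportions observed in a 12-month-care
#: secondary mental-health cohort (see docs/methods.md).
_DEF_AGE = {"15-24": 0.234, "25-34": 0.276, "35-44": 0.204, "45-54": 0.115,
            "55-64": 0.059, "65-74": 0.055, "75+": 0.057}
_DEF_SEX = {"male": 0.516, "female": 0.484}
_DEF_MARITAL = {"single": 0.655, "cohabiting": 0.174,
                "separated_widowed": 0.138, "unknown": 0.033}
_DEF_DEPRIVATION = {"least": 0.304, "middle": 0.323, "most": 0.299, "unknown": 0.074}
_DEF_DIAGNOSIS = {"schizophrenia": 0.430, "schizoaffective": 0.040,
                  "bipolar": 0.247, "other": 0.283}

#: log-odds of current smoking; names match the design columns emitted by
#: epi_stats._encode_terms so fits can be compared to these directly.
_DEF_SMOKING_COEF = {
    "intercept": 0.90,
    "age_65_plus": float(np.log(0.23)),
    "sex[female]": float(np.log(0.62)),
    "marital[cohabiting]": float(np.log(0.53)),
    "marital[separated_widowed]": 0.0,
    "deprivation_score": float(np.log(1.26)),
    "diagnosis[schizoaffective]": float(np.log(1.66)),
    "diagnosis[bipolar]": float(np.log(0.77)),
    "diagnosis[other]": float(np.log(0.58)),
}

#: log-odds that a patient's record never states smoking status: higher in
#: women and bipolar disorder, lower with rising area deprivation.
_DEF_MISSING_COEF = {
    "intercept": -1.0,
    "sex[female]": 0.47,
    "diagnosis[bipolar]": 0.73,
    "deprivation_score": -0.22,
}


@dataclass
class SimulationConfig:
    """All knobs of the register generator; every probability validated."""

    n_patients: int = 2000
    seed: int = 0
    referral_window: tuple[Date, Date] = (Date(2008, 1, 1), Date(2011, 12, 31))
    age_band_probs: dict = field(default_factory=lambda: dict(_DEF_AGE))
    sex_probs: dict = field(default_factory=lambda: dict(_DEF_SEX))
    marital_probs: dict = field(default_factory=lambda: dict(_DEF_MARITAL))
    deprivation_probs: dict = field(default_factory=lambda: dict(_DEF_DEPRIVATION))
    diagnosis_probs: dict = field(default_factory=lambda: dict(_DEF_DIAGNOSIS))
    smoking_coefficients: dict = field(default_factory=lambda: dict(_DEF_SMOKING_COEF))
    past_fraction: float = 0.35  # P(past | not current); remainder never
    frac_long_care: float = 0.28  # P(care episode >= 12 months)
    docs_per_patient_mean: float = 5.0  # Poisson, floored at 1 document
    p_mention: float = 0.6  # per document, given an ascertainable patient
    p_distractor: float = 0.15  # non-tobacco smoking sentence per document
    out_of_lexicon_rate: float = 0.15  # mention phrased outside the lexicons
    ambiguous_rate: float = 0.10  # mention with conflicting cues
    p_structured: float = 0.18  # structured entry, given ascertainable
    missing_coefficients: Optional[dict] = field(
        default_factory=lambda: dict(_DEF_MISSING_COEF)
    )  # None switches the missingness mechanism off

    def __post_init__(self) -> None:
        for name in ("past_fraction", "frac_long_care", "p_mention",
                     "p_distractor", "out_of_lexicon_rate", "ambiguous_rate",
                     "p_structured"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.out_of_lexicon_rate + self.ambiguous_rate > 1.0:
            raise ValueError("phrasing-class rates exceed 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name in ("age_band_probs", "sex_probs", "marital_probs",
                     "deprivation_probs", "diagnosis_probs"):
            probs = getattr(self, name)
            vals = np.array(list(probs.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a probability distribution")


@dataclass
class GroundTruth:
    """What the generator knows: per-patient truth and gold annotations."""

    true_status: dict[str, str]
    ascertainable: dict[str, bool]
    gold: list[GoldAnnotation]
    gold_classes: list[str]  # phrasing class per gold annotation

    def gold_of_class(self, cls: str) -> list[GoldAnnotation]:
        return [g for g, c in zip(self.gold, self.gold_classes) if c == cls]


@dataclass
class Register:
    patients: list[Patient]
    documents: list[ClinicalDocument]
    structured: list[StructuredSmokingEntry]
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Template bank
# ---------------------------------------------------------------------------
# (before, gold phrase, after); the gold annotation spans the phrase, which
# always contains the lexical anchor the rules fire on (or deliberately does
# not, for the out-of-lexicon class).

_TEMPLATES = {
    ("standard", CURRENT): [
        ("He is a ", "heavy smoker", ", approx 20 per day."),
        ("", "Smokes 10 cigarettes a day", " despite advice."),
        ("She is a ", "current smoker", " and declined the cessation clinic."),
        ("", "Still smoking heavily", ", around a pack a day."),
    ],
    ("standard", PAST): [
        ("He is an ", "ex-smoker", ", quit two years ago."),
        ("She ", "stopped smoking", " in 2009."),
        ("Patient ", "used to smoke", " but gave up last year."),
        ("", "Former smoker", " of many years."),
    ],
    ("standard", NEVER): [
        ("She has ", "never smoked", "."),
        ("Patient is a ", "non-smoker", "."),
        ("He ", "denies smoking", " or alcohol use."),
        ("", "No history of tobacco", " use documented."),
    ],
    ("out_of_lexicon", CURRENT): [
        ("Has a ", "20 a day habit", " by own account."),
        ("", "Lights up first thing", " every morning."),
    ],
    ("out_of_lexicon", PAST): [
        ("", "Packed in the fags", " five years back."),
    ],
    ("out_of_lexicon", NEVER): [
        ("", "Has not touched a fag", " in his life."),
    ],
    ("ambiguous", CURRENT): [
        ("", "Ex-smoker but still smokes", " at weekends."),
    ],
    ("ambiguous", PAST): [
        ("", "Still smokes per old note but quit since", "."),
    ],
}

_DISTRACTORS = [
    "Smokes cannabis most evenings.",
    "Uses crack cocaine intermittently.",
    "Reports heavy weed use.",
    "Rolled a joint at the weekend.",
]

_FILLERS = [
    "Seen at home by the care coordinator.",
    "Attended the outpatient clinic today.",
    "Sleep remains poor.",
    "Mood settled on medication.",
    "Care plan discussed and agreed.",
    "No concerns raised at review.",
    "Medication adherence is good.",
    "Lives alone in supported accommodation.",
]


def _add_months(d: Date, months: int) -> Date:
    y, m0 = divmod(d.month - 1 + months, 12)
    year, month = d.year + y, m0 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return Date(year, month, day)


def _linear_predictor(coef: dict, feats: dict[str, np.ndarray]) -> np.ndarray:
    lp = np.full(len(next(iter(feats.values()))), coef.get("intercept", 0.0))
    for name, values in feats.items():
        lp += coef.get(name, 0.0) * values
    return lp


def _sample_cat(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    labels = list(probs.keys())
    return rng.choice(labels, size=n, p=list(probs.values()))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_patients(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[Patient], dict[str, str], dict[str, bool]]:
    """Sample patients with true smoking statuses and ascertainability flags.

    Returned separately from note generation so parameter-recovery studies
    can run at large n without assembling any text.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return [], {}, {}

    bands = _sample_cat(rng, config.age_band_probs, n)
    lo_age = np.array([_AGE_BAND_RANGES[b][0] for b in bands])
    hi_age = np.array([_AGE_BAND_RANGES[b][1] for b in bands])
    ages = rng.integers(lo_age, hi_age + 1)
    sexes = _sample_cat(rng, config.sex_probs, n)
    maritals = _sample_cat(rng, config.marital_probs, n)
    deprivations = _sample_cat(rng, config.deprivation_probs, n)
    diagnoses = _sample_cat(rng, config.diagnosis_probs, n)

    lo, hi = config.referral_window
    window_days = (hi - lo).days
    referral_offsets = rng.integers(0, window_days + 1, size=n)

    long_care = rng.random(n) < config.frac_long_care
    months = np.where(long_care, rng.integers(12, 49, size=n), rng.integers(1, 12, size=n))
    extra_days = rng.integers(0, 28, size=n)

    dep_score = {"least": 0.0, "middle": 1.0, "most": 2.0, "unknown": 1.0}
    feats = {
        "age_65_plus": (ages >= 65).astype(float),
        "sex[female]": (sexes == "female").astype(float),
        "marital[cohabiting]": (maritals == "cohabiting").astype(float),
        "marital[separated_widowed]": (maritals == "separated_widowed").astype(float),
        "deprivation_score": np.array([dep_score[d] for d in deprivations]),
        "diagnosis[schizoaffective]": (diagnoses == "schizoaffective").astype(float),
        "diagnosis[bipolar]": (diagnoses == "bipolar").astype(float),
        "diagnosis[other]": (diagnoses == "other").astype(float),
    }
    p_current = 1.0 / (1.0 + np.exp(-_linear_predictor(config.smoking_coefficients, feats)))
    is_current = rng.random(n) < p_current
    is_past = rng.random(n) < config.past_fraction

    if config.missing_coefficients is None:
        missing = np.zeros(n, dtype=bool)
    else:
        p_missing = 1.0 / (
            1.0 + np.exp(-_linear_predictor(config.missing_coefficients, feats))
        )
        missing = rng.random(n) < p_missing

    width = len(str(max(n - 1, 1)))
    patients, true_status, ascertainable = [], {}, {}
    for i in range(n):
        pid = f"p{i:0{width}d}"
        referral = lo + timedelta(days=int(referral_offsets[i]))
        care_end = _add_months(referral, int(months[i])) + timedelta(days=int(extra_days[i]))
        patients.append(
            Patient(
                patient_id=pid,
                age_at_referral=float(ages[i]),
                sex=str(sexes[i]),
                marital=str(maritals[i]),
                deprivation_tertile=str(deprivations[i]),
                diagnosis=str(diagnoses[i]),
                referral_date=referral,
                care_end_date=care_end,
            )
        )
        true_status[pid] = (
            CURRENT if is_current[i] else (PAST if is_past[i] else NEVER)
        )
        ascertainable[pid] = not bool(missing[i])
    return patients, true_status, ascertainable


def _render_note(
    rng: np.random.Generator,
    doc_id: str,
    status: Optional[str],
    mention: bool,
    config: SimulationConfig,
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Assemble one note; returns (text, gold spans as (start, end, status,
    phrasing class))."""
    n_filler = int(rng.integers(1, 4))
    sentences: list[tuple[str, Optional[tuple]]] = [
        (str(rng.choice(_FILLERS)), None) for _ in range(n_filler)
    ]
    if mention and status is not None:
        u = rng.random()
        if u < config.out_of_lexicon_rate:
            cls = "out_of_lexicon"
        elif u < config.out_of_lexicon_rate + config.ambiguous_rate and status != NEVER:
            cls = "ambiguous"
        else:
            cls = "standard"
        options = _TEMPLATES[(cls, status)]
        before, phrase, after = options[int(rng.integers(0, len(options)))]
        sentences.insert(
            int(rng.integers(0, len(sentences) + 1)),
            (before + phrase + after, (len(before), len(before) + len(phrase), status, cls)),
        )
    if rng.random() < config.p_distractor:
        sentences.insert(
            int(rng.integers(0, len(sentences) + 1)),
            (str(rng.choice(_DISTRACTORS)), None),
        )
    text_parts: list[str] = []
    gold: list[tuple[int, int, str, str]] = []
    offset = 0
    for sentence, mark in sentences:
        if mark is not None:
            s, e, status_, cls = mark
            gold.append((offset + s, offset + e, status_, cls))
        text_parts.append(sentence)
        offset += len(sentence) + 1  # single-space joined
    return " ".join(text_parts), gold


def generate_register(config: SimulationConfig) -> Register:
    """Generate a full synthetic register: patients, structured entries,
    documents and ground truth.  Reproducible for a fixed config."""
    rng = np.random.default_rng(config.seed)
    patients, true_status, ascertainable = generate_patients(config, rng)

    documents: list[ClinicalDocument] = []
    structured: list[StructuredSmokingEntry] = []
    gold: list[GoldAnnotation] = []
    gold_classes: list[str] = []

    for patient in patients:
        pid = patient.patient_id
        status = true_status[pid]
        observable = ascertainable[pid]
        if observable and rng.random() < config.p_structured:
            structured.append(
                StructuredSmokingEntry(
                    patient_id=pid,
                    date=patient.referral_date + timedelta(days=int(rng.integers(0, 31))),
                    status=status,
                )
            )
        n_docs = max(1, int(rng.poisson(config.docs_per_patient_mean)))
        care_days = (patient.care_end_date - patient.referral_date).days
        for j in range(n_docs):
            doc_id = f"{pid}-d{j}"
            doc_date = patient.referral_date + timedelta(
                days=int(rng.integers(0, care_days + 1))
            )
            mention = observable and rng.random() < config.p_mention
            text, spans = _render_note(rng, doc_id, status, mention, config)
            documents.append(
                ClinicalDocument(
                    doc_id=doc_id,
                    patient_id=pid,
                    date=doc_date,
                    doc_type=str(rng.choice(DOC_TYPES)),
                    text=text,
                )
            )
            for s, e, status_, cls in spans:
                gold.append(GoldAnnotation(doc_id=doc_id, start=s, end=e, status=status_))
                gold_classes.append(cls)

    return Register(
        patients=patients,
        documents=documents,
        structured=structured,
        truth=GroundTruth(
            true_status=true_status,
            ascertainable=ascertainable,
            gold=gold,
            gold_classes=gold_classes,
        ),
        config=config,
    )


# ---------------------------------------------------------------------------
# Hand-traceable fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A tiny deterministic corpus with its expected outputs."""

    name: str
    documents: list[ClinicalDocument]
    gold: list[GoldAnnotation]
    structured: list[StructuredSmokingEntry]
    patient: Optional[Patient]
    expected: dict


def _doc(doc_id: str, text: str, pid: str = "px", day: int = 1) -> ClinicalDocument:
    return ClinicalDocument(
        doc_id=doc_id, patient_id=pid, date=Date(2009, 1, day),
        doc_type="progress_note", text=text,
    )


def _gold_in(doc: ClinicalDocument, phrase: str, status: str) -> GoldAnnotation:
    start = doc.text.index(phrase)
    return GoldAnnotation(doc.doc_id, start, start + len(phrase), status)


def make_fixture_suite() -> dict[str, Fixture]:
    """Small deterministic corpora covering the hand-traced rule, evaluation
    and tie-break cases, with their expected outputs alongside."""
    px = Patient(
        patient_id="px", age_at_referral=40, sex="male", marital="single",
        deprivation_tertile="middle", diagnosis="schizophrenia",
        referral_date=Date(2009, 1, 1), care_end_date=Date(2010, 6, 1),
    )
    fixtures: dict[str, Fixture] = {}

    d = _doc("neg1", "She has never smoked.")
    fixtures["negation"] = Fixture(
        "negation", [d], [_gold_in(d, "never smoked", NEVER)], [], px,
        {"n_annotations": 1, "statuses": [NEVER]},
    )

    d = _doc("can1", "Smokes cannabis daily. Uses crack cocaine.")
    fixtures["cannabis-only"] = Fixture(
        "cannabis-only", [d], [], [], px, {"n_annotations": 0, "statuses": []},
    )

    d = _doc(
        "mix1",
        "Reported as a heavy smoker at admission. "
        "Later note says he has never smoked. "
        "Smokes cannabis occasionally.",
    )
    fixtures["mixed"] = Fixture(
        "mixed", [d],
        [_gold_in(d, "heavy smoker", CURRENT), _gold_in(d, "never smoked", NEVER)],
        [], px, {"n_annotations": 2, "statuses": [CURRENT, NEVER]},
    )

    d = _doc("conf1", "Smoking status unclear; family smokes.")
    fixtures["conflict"] = Fixture(
        "conflict", [d], [], [], px, {"n_annotations": 0, "statuses": []},
    )

    d = _doc("amb1", "Ex-smoker but still smokes at weekends.")
    fixtures["ambiguous"] = Fixture(
        "ambiguous", [d], [_gold_in(d, "Ex-smoker but still smokes", CURRENT)],
        [], px,
        {"n_annotations": 0, "statuses": [],
         "no_abstain_statuses": [PAST]},  # precedence never > past > current
    )

    # structured (past) and text (current) records on the same day: the
    # structured field wins the tie.
    d = _doc("tie1", "He is a current smoker.", day=10)
    fixtures["same-date-conflict"] = Fixture(
        "same-date-conflict", [d], [_gold_in(d, "current smoker", CURRENT)],
        [StructuredSmokingEntry("px", Date(2009, 1, 10), PAST)], px,
        {"resolved_status": PAST, "resolved_source": "structured"},
    )

    # two text annotations on the same day with different statuses: the
    # affirmative (current) mention takes precedence.
    d1 = _doc("tt1", "He is a current smoker.", day=12)
    d2 = _doc("tt2", "Patient is a non-smoker.", day=12)
    fixtures["text-tie"] = Fixture(
        "text-tie", [d1, d2],
        [_gold_in(d1, "current smoker", CURRENT), _gold_in(d2, "non-smoker", NEVER)],
        [], px, {"resolved_status": CURRENT, "resolved_source": "text"},
    )

    d = _doc(
        "abbr1",
        "Seen by Dr. Smith today. He smokes e.g. roll-ups. Plan agreed.",
    )
    fixtures["abbreviations"] = Fixture(
        "abbreviations", [d], [_gold_in(d, "smokes e.g. roll-ups", CURRENT)],
        [], px, {"n_sentences": 3},
    )

    return fixtures
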