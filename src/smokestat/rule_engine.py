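"""Rule-based detection and classification of tobacco-smoking mentions in
clinical free text.

The engine performs shallow parsing: sentences are segmented, lexicon
matches anchor candidate mentions, and sentence-bounded cue words classify
each mention as *current*, *past* or *never* smoking.  Mentions of smoked
substances other than tobacco (cannabis, crack cocaine, ...) are
suppressed, and the engine abstains whenever cues conflict or no cue
resolves a mention: precision is deliberately prioritised over recall,
because smoking status tends to be re-stated across a patient's record and
missed mentions are recoverable from later documents.

Offsets are 0-based, half-open character offsets into the original
(unnormalised) document text; matching is case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date as Date
from typing import Iterable, Optional, Sequence

CURRENT = "current"
PAST = "past"
NEVER = "never"
STATUSES = (CURRENT, PAST, NEVER)

DOC_TYPES = ("assessment", "progress_note", "correspondence")

#: status precedence used when abstention-on-conflict is disabled; negation
#: is the strongest signal in clinical text, past-tense cues the next.
CONFLICT_PRECEDENCE = (NEVER, PAST, CURRENT)


@dataclass(frozen=True)
class ClinicalDocument:
    """One free-text record tied to a patient and a date."""

    doc_id: str
    patient_id: str
    date: Date
    doc_type: str
    text: str

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            raise ValueError(f"unknown doc_type {self.doc_type!r}")


@dataclass(frozen=True)
class SmokingAnnotation:
    """A classified smoking mention: span, status and the rule that fired."""

    doc_id: str
    start: int
    end: int
    matched_text: str
    status: str
    rule_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("annotation span must satisfy 0 <= start < end")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


# ---------------------------------------------------------------------------
# RuleSet: configurable lexicons
# ---------------------------------------------------------------------------

_DEFAULT_TOBACCO_TERMS = [
    "smoke", "smokes", "smoked", "smoking", "smoker", "smokers",
    "cigarette", "cigarettes", "cig", "cigs", "tobacco", "nicotine",
    "roll-up", "roll-ups", "rollup", "rollups",
]

#: explicit tobacco objects: nouns that name the substance itself.  They are
#: immune to non-tobacco suppression and preferred as annotation anchors.
_DEFAULT_TOBACCO_OBJECTS = [
    "cigarette", "cigarettes", "cig", "cigs", "tobacco", "nicotine",
    "roll-up", "roll-ups", "rollup", "rollups",
]

_DEFAULT_NON_TOBACCO_TERMS = [
    "cannabis", "marijuana", "weed", "skunk", "cocaine", "crack",
    "joint", "spliff", "heroin",
]

_DEFAULT_NEGATION_CUES = [
    "never", "denies", "denied", "does not", "doesn't", "non-",
    "no history of", "no evidence of", "not a",
]

_DEFAULT_PAST_CUES = [
    "ex-", "former", "formerly", "quit", "stopped", "used to",
    "gave up", "in the past",
]

_DEFAULT_CURRENT_CUES = [
    "current", "currently", "smokes", "per day", "a day", "/day",
    "heavy smoker", "pack a day", "still",
]

#: mentions attributed to someone other than the patient force abstention.
_DEFAULT_THIRD_PARTY_CUES = [
    "family", "wife", "husband", "partner", "mother", "father",
    "brother", "sister", "flatmate", "friend",
]


def _pattern_to_regex(entry: str) -> str:
    """Turn a lexicon entry into a case-insensitive regex fragment.

    Internal whitespace matches any run of whitespace; word boundaries are
    applied only where the entry starts/ends with a word character, so that
    prefix cues like ``non-`` and symbol cues like ``/day`` behave.
    """
    body = r"\s+".join(re.escape(tok) for tok in entry.split())
    pre = r"(?<!\w)" if entry[0].isalnum() else ""
    suf = r"(?!\w)" if entry[-1].isalnum() else ""
    return pre + body + suf


def _compile(entries: Sequence[str]) -> list[tuple[str, re.Pattern]]:
    return [(e, re.compile(_pattern_to_regex(e), re.IGNORECASE)) for e in entries]


@dataclass
class RuleSet:
    """Configurable lexicons and scope parameters for the extraction rules.

    ``max_tokens`` bounds the token distance between a cue and the tobacco
    term it scopes; scope never crosses a sentence boundary.  With
    ``abstain_on_conflict`` (the default) a mention scoped by cues of more
    than one class yields no annotation; disabling it resolves conflicts by
    the fixed precedence never > past > current.
    """

    tobacco_terms: list[str] = field(default_factory=lambda: list(_DEFAULT_TOBACCO_TERMS))
    tobacco_objects: list[str] = field(default_factory=lambda: list(_DEFAULT_TOBACCO_OBJECTS))
    non_tobacco_terms: list[str] = field(default_factory=lambda: list(_DEFAULT_NON_TOBACCO_TERMS))
    negation_cues: list[str] = field(default_factory=lambda: list(_DEFAULT_NEGATION_CUES))
    past_cues: list[str] = field(default_factory=lambda: list(_DEFAULT_PAST_CUES))
    current_cues: list[str] = field(default_factory=lambda: list(_DEFAULT_CURRENT_CUES))
    third_party_cues: list[str] = field(default_factory=lambda: list(_DEFAULT_THIRD_PARTY_CUES))
    scope: str = "sentence"
    max_tokens: int = 5
    abstain_on_conflict: bool = True

    def __post_init__(self) -> None:
        for name in ("tobacco_terms", "negation_cues", "past_cues", "current_cues"):
            if not getattr(self, name):
                raise ValueError(f"RuleSet.{name} must be non-empty")
        overlap = set(t.lower() for t in self.tobacco_terms) & set(
            t.lower() for t in self.non_tobacco_terms
        )
        if overlap:
            raise ValueError(f"tobacco and non-tobacco lexicons overlap: {sorted(overlap)}")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")
        self._recompile()

    def _recompile(self) -> None:
        self._tobacco = _compile(self.tobacco_terms)
        self._objects = {t.lower() for t in self.tobacco_objects}
        self._non_tobacco = _compile(self.non_tobacco_terms)
        self._cues = {
            NEVER: _compile(self.negation_cues),
            PAST: _compile(self.past_cues),
            CURRENT: _compile(self.current_cues),
        }
        self._third_party = _compile(self.third_party_cues)

    def without_tobacco_term(self, term: str) -> "RuleSet":
        """A copy of this rule set with one tobacco pattern removed."""
        terms = [t for t in self.tobacco_terms if t != term]
        objects = [t for t in self.tobacco_objects if t != term]
        return replace(self, tobacco_terms=terms, tobacco_objects=objects)


def default_ruleset(**overrides) -> RuleSet:
    """The shipped default rule set (a reconstruction; every lexicon is
    configurable because no canonical keyword inventory exists)."""
    return RuleSet(**overrides)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "cf", "vs", "approx", "dr", "mr", "mrs", "ms",
    "prof", "st", "no",
}

_BOUNDARY = re.compile(r"[.!?;]+(?=\s|$)|\n+")


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans (0-based, half-open character offsets).

    Spans are ordered, non-overlapping, and together cover every
    non-whitespace character.  Common abbreviations ("e.g.", "Dr.") do not
    trigger a split.
    """
    if not text or text.isspace():
        return []
    breaks = [0]
    for m in _BOUNDARY.finditer(text):
        if "\n" not in m.group(0):
            # the token immediately before the terminator
            head = text[: m.start()]
            tail = re.split(r"\s", head)[-1].lower().rstrip(".")
            if tail in _ABBREVIATIONS:
                continue
        breaks.append(m.end())
    breaks.append(len(text))
    spans: list[tuple[int, int]] = []
    for lo, hi in zip(breaks, breaks[1:]):
        chunk = text[lo:hi]
        stripped = chunk.strip()
        if not stripped:
            continue
        start = lo + (len(chunk) - len(chunk.lstrip()))
        spans.append((start, start + len(stripped)))
    return spans


def _token_spans(text: str, lo: int, hi: int) -> list[tuple[int, int]]:
    return [(m.start() + lo, m.end() + lo) for m in re.finditer(r"\S+", text[lo:hi])]


def _token_distance(a: tuple[int, int], b: tuple[int, int],
                    tokens: Sequence[tuple[int, int]]) -> int:
    """Number of tokens lying strictly between two character spans
    (0 when the spans touch or overlap)."""
    lo, hi = (a, b) if a[0] <= b[0] else (b, a)
    if hi[0] < lo[1]:
        return 0
    return sum(1 for s, e in tokens if s >= lo[1] and e <= hi[0])


# ---------------------------------------------------------------------------
# Candidate detection
# ---------------------------------------------------------------------------

def find_candidate_mentions(
    text: str, sentence: tuple[int, int], rules: RuleSet
) -> list[tuple[int, int]]:
    """Locate tobacco-term spans in one sentence, suppressing mentions whose
    smoking verb is modified by a non-tobacco substance.

    A generic smoking term ("smokes", "smoker") is suppressed when a
    non-tobacco term sits within ``max_tokens`` and no explicit tobacco
    object sits at least as close: "smokes cannabis" is not a tobacco
    mention, but "smokes cigarettes and cannabis" is.  Nearby candidates are
    then collapsed into one mention anchored on the tobacco object when one
    is present (otherwise the leftmost term).
    """
    lo, hi = sentence
    tokens = _token_spans(text, lo, hi)

    matches: list[tuple[tuple[int, int], bool]] = []  # (span, is_object)
    for entry, pat in rules._tobacco:
        for m in pat.finditer(text, lo, hi):
            matches.append(((m.start(), m.end()), entry.lower() in rules._objects))
    if not matches:
        return []
    # longest-leftmost wins among overlapping lexicon matches
    matches.sort(key=lambda t: (t[0][0], -(t[0][1] - t[0][0])))
    kept: list[tuple[tuple[int, int], bool]] = []
    for span, is_obj in matches:
        if kept and span[0] < kept[-1][0][1]:
            continue
        kept.append((span, is_obj))

    non_tobacco = [
        (m.start(), m.end())
        for _, pat in rules._non_tobacco
        for m in pat.finditer(text, lo, hi)
    ]

    def nearest(span, others):
        ds = [_token_distance(span, o, tokens) for o in others]
        return min(ds) if ds else None

    object_spans = [s for s, is_obj in kept if is_obj]
    survivors: list[tuple[tuple[int, int], bool]] = []
    for span, is_obj in kept:
        if not is_obj:
            d_drug = nearest(span, non_tobacco)
            if d_drug is not None and d_drug <= rules.max_tokens:
                d_obj = nearest(span, object_spans)
                if d_obj is None or d_obj > d_drug:
                    continue  # the smoked substance is not tobacco
        survivors.append((span, is_obj))
    if not survivors:
        return []

    # collapse runs of nearby candidates into one mention each
    groups: list[list[tuple[tuple[int, int], bool]]] = [[survivors[0]]]
    for item in survivors[1:]:
        if _token_distance(groups[-1][-1][0], item[0], tokens) <= rules.max_tokens:
            groups[-1].append(item)
        else:
            groups.append([item])
    anchors = []
    for group in groups:
        objs = [s for s, is_obj in group if is_obj]
        anchors.append(objs[0] if objs else group[0][0])
    return anchors


# ---------------------------------------------------------------------------
# Mention classification
# ---------------------------------------------------------------------------

def classify_mention(
    text: str,
    candidate: tuple[int, int],
    sentence: tuple[int, int],
    rules: RuleSet,
    doc_id: str = "",
) -> Optional[SmokingAnnotation]:
    """Classify one candidate mention, or abstain.

    Cues scope the candidate when they lie in the same sentence within
    ``max_tokens`` tokens.  A single scoping cue class decides the status;
    a third-party attribution cue, conflicting cue classes (under the
    default abstaining behaviour), or the absence of any cue all yield
    abstention (``None``) — missed mentions are preferred to wrong ones.
    """
    lo, hi = sentence
    tokens = _token_spans(text, lo, hi)

    def scoping(compiled):
        out = []
        for entry, pat in compiled:
            for m in pat.finditer(text, lo, hi):
                span = (m.start(), m.end())
                d = _token_distance(span, candidate, tokens)
                if d <= rules.max_tokens:
                    out.append((d, entry, span))
        return sorted(out)

    if scoping(rules._third_party):
        return None

    by_class = {status: scoping(rules._cues[status]) for status in STATUSES}
    # a "current" cue that is the candidate token itself (e.g. "smokes") is
    # no evidence of current smoking when a negation or past cue also
    # scopes: "never smokes" negates the verb, it does not assert it.
    others = bool(by_class[NEVER] or by_class[PAST])
    if others:
        overlap_free = [
            c for c in by_class[CURRENT]
            if not (c[2][0] < candidate[1] and candidate[0] < c[2][1])
        ]
        by_class[CURRENT] = overlap_free

    present = [s for s in STATUSES if by_class[s]]
    if not present:
        return None
    if len(present) > 1:
        if rules.abstain_on_conflict:
            return None
        status = next(s for s in CONFLICT_PRECEDENCE if s in present)
    else:
        status = present[0]
    _, cue, _ = by_class[status][0]
    return SmokingAnnotation(
        doc_id=doc_id,
        start=candidate[0],
        end=candidate[1],
        matched_text=text[candidate[0]: candidate[1]],
        status=status,
        rule_id=f"{status}:{cue}",
    )


def annotate_document(doc: ClinicalDocument, rules: RuleSet) -> list[SmokingAnnotation]:
    """All smoking annotations for one document, ordered by start offset."""
    out: list[SmokingAnnotation] = []
    for sentence in segment_sentences(doc.text):
        for candidate in find_candidate_mentions(doc.text, sentence, rules):
            ann = classify_mention(doc.text, candidate, sentence, rules, doc_id=doc.doc_id)
            if ann is not None:
                out.append(ann)
    out.sort(key=lambda a: a.start)
    return out


def annotate_corpus(
    docs: Iterable[ClinicalDocument], rules: Optional[RuleSet] = None
) -> list[SmokingAnnotation]:
    """Annotate a corpus of documents with one rule set."""
    rules = rules or default_ruleset()
    out: list[SmokingAnnotation] = []
    for doc in docs:
        out.extend(annotate_document(doc, rules))
    return out
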