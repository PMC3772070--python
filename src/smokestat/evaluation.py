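"""Annotation-level evaluation: precision and recall against a gold standard.

Predicted and gold annotations are matched one-to-one per document; a pair
matches when the spans satisfy the matching criterion (character overlap by
default, exact spans optionally) AND the statuses agree.  A predicted
annotation with the right span but the wrong status therefore counts as
both a false positive and a false negative.  The error report lists every
fp/fn with its sentence context to drive iterative rule refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .rule_engine import STATUSES, ClinicalDocument, SmokingAnnotation, segment_sentences


@dataclass(frozen=True)
class GoldAnnotation:
    """A manually assigned smoking mention used as reference."""

    doc_id: str
    start: int
    end: int
    status: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("gold span must satisfy 0 <= start < end")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    matched: list[tuple[SmokingAnnotation, GoldAnnotation]]
    false_positives: list[SmokingAnnotation]
    false_negatives: list[GoldAnnotation]
    per_class: dict = field(default_factory=dict)
    per_rule_fp: dict = field(default_factory=dict)

    @property
    def precision(self) -> Optional[float]:
        """tp/(tp+fp); None (undefined) when nothing was predicted."""
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> Optional[float]:
        """tp/(tp+fn); None (undefined) when the gold set is empty."""
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None


def _spans_match(pred, gold, matching: str) -> bool:
    if matching == "exact":
        return pred.start == gold.start and pred.end == gold.end
    if matching == "overlap":
        return pred.start < gold.end and gold.start < pred.end
    raise ValueError(f"unknown matching mode {matching!r}")


def match_annotations(
    predicted: Sequence[SmokingAnnotation],
    gold: Sequence[GoldAnnotation],
    matching: str = "overlap",
    known_doc_ids: Optional[set[str]] = None,
) -> tuple[list[tuple[SmokingAnnotation, GoldAnnotation]],
           list[SmokingAnnotation], list[GoldAnnotation]]:
    """One-to-one matching of predicted to gold annotations.

    Greedy by leftmost-longest predicted span within each document; among
    eligible gold partners the leftmost-longest is taken, so the matching
    is deterministic and independent of input order.
    Returns (matched pairs, unmatched predicted, unmatched gold).
    """
    if known_doc_ids is not None:
        for ann in list(predicted) + list(gold):
            if ann.doc_id not in known_doc_ids:
                raise ValueError(f"annotation references unknown doc_id {ann.doc_id!r}")

    order = lambda a: (a.doc_id, a.start, -(a.end - a.start), a.status)
    preds = sorted(predicted, key=order)
    golds = sorted(gold, key=order)
    unmatched_gold = list(golds)
    pairs: list[tuple[SmokingAnnotation, GoldAnnotation]] = []
    unmatched_pred: list[SmokingAnnotation] = []
    for p in preds:
        partner = next(
            (g for g in unmatched_gold
             if g.doc_id == p.doc_id and g.status == p.status and _spans_match(p, g, matching)),
            None,
        )
        if partner is None:
            unmatched_pred.append(p)
        else:
            unmatched_gold.remove(partner)
            pairs.append((p, partner))
    return pairs, unmatched_pred, unmatched_gold


def score(
    predicted: Sequence[SmokingAnnotation],
    gold: Sequence[GoldAnnotation],
    matching: str = "overlap",
    known_doc_ids: Optional[set[str]] = None,
) -> EvalResult:
    """Annotation-level precision (positive predictive value) and recall
    (sensitivity), with per-class and per-rule breakdowns."""
    pairs, fps, fns = match_annotations(predicted, gold, matching, known_doc_ids)
    per_class = {}
    for status in STATUSES:
        tp_c = sum(1 for _, g in pairs if g.status == status)
        fp_c = sum(1 for a in fps if a.status == status)
        fn_c = sum(1 for g in fns if g.status == status)
        per_class[status] = {
            "tp": tp_c,
            "fp": fp_c,
            "fn": fn_c,
            "precision": tp_c / (tp_c + fp_c) if tp_c + fp_c else None,
            "recall": tp_c / (tp_c + fn_c) if tp_c + fn_c else None,
        }
    per_rule_fp: dict[str, int] = {}
    for a in fps:
        per_rule_fp[a.rule_id] = per_rule_fp.get(a.rule_id, 0) + 1
    return EvalResult(
        tp=len(pairs),
        fp=len(fps),
        fn=len(fns),
        matched=pairs,
        false_positives=fps,
        false_negatives=fns,
        per_class=per_class,
        per_rule_fp=per_rule_fp,
    )


def _context(doc: ClinicalDocument, start: int, end: int) -> str:
    for lo, hi in segment_sentences(doc.text):
        if lo <= start < hi:
            return doc.text[lo:hi]
    return doc.text[max(0, start - 40): end + 40]


def error_report(
    result: EvalResult, corpus: Mapping[str, ClinicalDocument]
) -> str:
    """Human-readable listing of every false positive and false negative
    with document id, span, the matched/missed text and its sentence."""
    lines: list[str] = []
    for a in result.false_positives:
        doc = corpus[a.doc_id]
        lines.append(
            f"FP  doc={a.doc_id} [{a.start},{a.end}) status={a.status} "
            f"rule={a.rule_id} text={a.matched_text!r} | {_context(doc, a.start, a.end)!r}"
        )
    for g in result.false_negatives:
        doc = corpus[g.doc_id]
        lines.append(
            f"FN  doc={g.doc_id} [{g.start},{g.end}) status={g.status} "
            f"text={doc.text[g.start:g.end]!r} | {_context(doc, g.start, g.end)!r}"
        )
    return "\n".join(lines)
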