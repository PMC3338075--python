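"""Mention-level evaluation: exact/partial matching and precision/recall/F.

Predicted mentions are scored against gold annotations one entity type at a
time (person, for the expert pipeline).  Exact mode requires identical
character spans; partial mode credits any character overlap under greedy
one-to-one matching.  Percentages are rounded half-up to one decimal, the
convention used for reported tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fn: int
    fp: int
    mode: str = "exact"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")


def _round1(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def prf(counts: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall and F-measure (percent, one decimal, half-up).

    P = 100·TP/(TP+FP), R = 100·TP/(TP+FN) and F is their harmonic mean,
    computed exactly as F = 200·TP/(2·TP+FN+FP) before rounding.  A zero
    denominator yields 0.0 for that quantity.
    """
    tp, fn, fp = counts.tp, counts.fn, counts.fp
    p = Decimal(100 * tp) / (tp + fp) if tp + fp else Decimal(0)
    r = Decimal(100 * tp) / (tp + fn) if tp + fn else Decimal(0)
    f = Decimal(200 * tp) / (2 * tp + fn + fp) if 2 * tp + fn + fp else Decimal(0)
    return _round1(p), _round1(r), _round1(f)


def ratio_percent(numerator: int, denominator: int) -> float:
    """100·numerator/denominator, rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return _round1(Decimal(100 * numerator) / denominator)


def _span_key(m) -> tuple:
    return (m.doc_id, m.char_start, m.char_end)


def _select(mentions: Iterable, entity_type: str | None) -> list:
    out = [
        m for m in mentions
        if entity_type is None or getattr(m, "type", entity_type) == entity_type
    ]
    return sorted(out, key=_span_key)


def _overlap(a, b) -> int:
    if a.doc_id != b.doc_id:
        return 0
    return max(0, min(a.char_end, b.char_end) - max(a.char_start, b.char_start))


def match_mentions(
    predicted: Sequence,
    gold: Sequence,
    mode: str = "exact",
    entity_type: str | None = "person",
    min_overlap: float = 0.0,
) -> EvalCounts:
    """Score predicted against gold mentions in ``exact`` or ``partial`` mode.

    Mentions need ``doc_id``, ``char_start``, ``char_end`` (and ``type`` when
    ``entity_type`` restricts the comparison).  Partial mode matches greedily
    one-to-one in document order; a pair qualifies when its character overlap
    exceeds ``min_overlap`` as a fraction of the shorter span (0.0 = any
    overlap).  Overlapping gold annotations are an input error.
    """
    if mode not in ("exact", "partial"):
        raise ValueError(f"unknown mode {mode!r}")
    pred = _select(predicted, entity_type)
    gold_m = _select(gold, entity_type)
    for a, b in zip(gold_m, gold_m[1:]):
        if a.doc_id == b.doc_id and b.char_start < a.char_end:
            raise ValueError(
                f"overlapping gold annotations in {a.doc_id} at {b.char_start}"
            )
    if mode == "exact":
        from collections import Counter

        pc, gc = Counter(map(_span_key, pred)), Counter(map(_span_key, gold_m))
        tp = sum(min(pc[k], gc[k]) for k in pc)
    else:
        matched = [False] * len(gold_m)
        tp = 0
        for p in pred:
            for j, g in enumerate(gold_m):
                if matched[j]:
                    continue
                ov = _overlap(p, g)
                shorter = min(p.char_end - p.char_start, g.char_end - g.char_start)
                if ov > 0 and (min_overlap <= 0.0 or ov / shorter >= min_overlap):
                    matched[j] = True
                    tp += 1
                    break
    return EvalCounts(tp=tp, fn=len(gold_m) - tp, fp=len(pred) - tp, mode=mode)
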