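"""Reducing person mentions to subject-expert mentions.

Three rules, applied in order, each shrinking the mention set:

1. drop person mentions that are part of an organization name in the same
   document (span containment, or surface equal to a token of an
   organization mention — the "visited Mayo" confusion);
2. keep a mention only if some scholarly keyword ("Dr", "PhD",
   "University", ...) occurs within 100 characters in either direction;
3. keep a mention only if the person has at least 10 publications according
   to a publication-count provider (a static first/last-name table by
   default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .ner_crf import Mention

logger = logging.getLogger(__name__)


class FilterConfigError(ValueError):
    pass


#: Scholarly-context keywords (33 unique strings; matched case-insensitively
#: on token boundaries, multiword entries as phrases).
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "Dr", "MD", "PhD", "M.D", "Prof", "Dr.", "M.D.", "Ph.D.", "Prof.",
    "Program Director", "Professor", "Journal", "Colleague", "Colleagues",
    "Researcher", "Faculty", "Doctor", "Doctors", "Publish", "Published",
    "University", "Hospital", "Hospitals", "Research", "Lab", "Laboratory",
    "School", "Engineering", "Sciences", "Institute", "Institutes",
    "Clinic", "College",
)


def compile_keywords(keywords: Sequence[str] = DEFAULT_KEYWORDS) -> re.Pattern:
    """One alternation regex, longest-first, bounded so that e.g. the
    keyword "Dr" never matches inside "drive"."""
    if not keywords:
        raise FilterConfigError("keyword list is empty")
    parts = [
        re.escape(kw).replace(r"\ ", r"\s+")
        for kw in sorted(set(keywords), key=lambda k: (-len(k), k))
    ]
    return re.compile(
        r"(?<![A-Za-z0-9])(?:" + "|".join(parts) + r")(?![A-Za-z0-9])",
        re.IGNORECASE,
    )


def load_keywords(path: str | Path) -> tuple[str, ...]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return tuple(ln.strip() for ln in lines if ln.strip())


@dataclass(frozen=True)
class ExpertMention:
    """A person mention that survived the filters, with its evidence."""

    mention: Mention
    keyword: str | None = None
    keyword_gap: int | None = None
    publication_count: int | None = None
    provider_failed: bool = False

    @property
    def doc_id(self) -> str:
        return self.mention.doc_id

    @property
    def char_start(self) -> int:
        return self.mention.char_start

    @property
    def char_end(self) -> int:
        return self.mention.char_end

    @property
    def text(self) -> str:
        return self.mention.text


# ---------------------------------------------------------------------------
# Rule 1: organization-nested person names
# ---------------------------------------------------------------------------


def remove_org_nested_persons(
    mentions: Sequence[Mention], doc=None
) -> list[Mention]:
    """Drop person mentions that are part of an organization name.

    A person mention is removed if its span is contained in an organization
    mention's span, or its case-folded surface equals a whitespace token of
    any organization mention's surface in the same document.  Non-person
    mentions pass through untouched.
    """
    orgs = [m for m in mentions if m.type == "organization"]
    org_tokens = {w.casefold() for m in orgs for w in m.text.split()}
    out: list[Mention] = []
    for m in mentions:
        if m.type == "person":
            contained = any(
                o.char_start <= m.char_start and m.char_end <= o.char_end
                for o in orgs
            )
            if contained or m.text.casefold() in org_tokens:
                continue
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# Rule 2: keyword proximity
# ---------------------------------------------------------------------------


def _gap(m_start: int, m_end: int, k_start: int, k_end: int) -> int:
    if k_end <= m_start:
        return m_start - k_end
    if m_end <= k_start:
        return k_start - m_end
    return 0  # overlap


def keyword_proximity_filter(
    mentions: Sequence[Mention],
    doc_text: str,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    window: int = 100,
) -> list[ExpertMention]:
    """Keep person mentions within ``window`` characters of a keyword.

    The gap is measured between the nearest boundaries of the mention span
    and the keyword span (0 on overlap) and the window is inclusive: a gap
    of exactly ``window`` retains the mention.
    """
    if window <= 0:
        raise FilterConfigError("window must be positive")
    pattern = compile_keywords(keywords)
    spans = [(m.start(), m.end(), m.group(0)) for m in pattern.finditer(doc_text)]
    out: list[ExpertMention] = []
    for m in mentions:
        best: tuple[int, str] | None = None
        for ks, ke, kw in spans:
            g = _gap(m.char_start, m.char_end, ks, ke)
            if best is None or g < best[0]:
                best = (g, kw)
        if best is not None and best[0] <= window:
            out.append(ExpertMention(m, keyword=best[1], keyword_gap=best[0]))
    return out


# ---------------------------------------------------------------------------
# Rule 3: publication counts
# ---------------------------------------------------------------------------


def split_person_name(surface: str) -> tuple[str, str]:
    """(first, last) from a mention surface.

    Multi-token surfaces use the first and last whitespace tokens; a
    single-token surface looks up as ``(token, "")``.
    """
    parts = surface.split()
    if len(parts) == 1:
        return parts[0], ""
    return parts[0], parts[-1]


class StaticPublicationCounts:
    """Publication-count lookup backed by a (first, last, count) table.

    Lookups are case-insensitive; a first name that is a bare initial
    ("J" or "J.") matches, PubMed-style, any table row with the same last
    name whose first name starts with that letter (the maximum count wins,
    deterministically).  Names absent from the table count 0.
    """

    def __init__(self, rows: Iterable[tuple[str, str, int]]):
        self._exact: dict[tuple[str, str], int] = {}
        self._by_last: dict[str, list[tuple[str, int]]] = {}
        for first, last, count in rows:
            key = (first.casefold(), last.casefold())
            self._exact[key] = max(int(count), self._exact.get(key, 0))
            self._by_last.setdefault(key[1], []).append((key[0], int(count)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StaticPublicationCounts":
        rows = []
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            if ln.strip():
                first, last, count = ln.split("\t")
                rows.append((first, last, int(count)))
        return cls(rows)

    def __call__(self, first: str, last: str) -> int:
        f = first.casefold().rstrip(".")
        l = last.casefold()
        hit = self._exact.get((f + "." if first.endswith(".") else f, l))
        if hit is None:
            hit = self._exact.get((f, l))
        if hit is not None:
            return hit
        if len(f) == 1:  # initial-only first name
            cands = [c for name, c in self._by_last.get(l, []) if name.startswith(f)]
            if cands:
                return max(cands)
        return 0


def publication_count_filter(
    mentions: Sequence[ExpertMention],
    provider: Callable[[str, str], int],
    min_count: int = 10,
) -> list[ExpertMention]:
    """Keep mentions whose person has at least ``min_count`` publications.

    A provider failure retains the mention fail-open, flagged and logged.
    """
    out: list[ExpertMention] = []
    for em in mentions:
        first, last = split_person_name(em.text)
        try:
            count = provider(first, last)
        except Exception:
            logger.warning(
                "publication lookup failed for %r; retaining mention", em.text,
            )
            out.append(replace(em, provider_failed=True))
            continue
        if count >= min_count:
            out.append(replace(em, publication_count=count))
    return out


# ---------------------------------------------------------------------------
# Composition and reporting
# ---------------------------------------------------------------------------


def filter_experts(
    mentions: Sequence[Mention],
    doc_text: str,
    provider: Callable[[str, str], int],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    window: int = 100,
    min_count: int = 10,
) -> list[ExpertMention]:
    """Apply the three rules in order for one document's mentions."""
    step1 = remove_org_nested_persons(mentions)
    persons = [m for m in step1 if m.type == "person"]
    step2 = keyword_proximity_filter(persons, doc_text, keywords, window)
    return publication_count_filter(step2, provider, min_count)


def filtered_fraction(count_without_filter: int, count_with_filter: int) -> float:
    """Percentage of mentions removed by the filter, to one decimal."""
    if count_without_filter <= 0:
        raise ValueError("count without filter must be positive")
    if not 0 <= count_with_filter <= count_without_filter:
        raise ValueError("filtered count must lie in [0, unfiltered count]")
    frac = (
        Decimal(100 * (count_without_filter - count_with_filter))
        / count_without_filter
    )
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
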