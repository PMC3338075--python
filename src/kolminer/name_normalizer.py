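"""Clustering expert mentions into unique individuals.

Mentions of the same person vary lexically ("John Doe" vs "J. Doe" —
synonymy) while distinct people can share a name string (two John Does at
different institutions — polysemy).  The normalizer resolves both with a
name-similarity score combined with organization/location context from the
same article: mentions are blocked by last name and single-link merged when
the name score clears a threshold and, where context is required, the two
mentions share an organization or location token.

Generic institution-type words (University, Clinic, ...) are excluded from
the shared-token test, otherwise any two universities would count as shared
context and polysemous names could never be split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import edlib

#: Honorifics/degrees stripped before name comparison.
_PREFIX_TOKENS = {
    "dr", "dr.", "prof", "prof.", "professor", "doctor",
    "mr", "mr.", "mrs", "mrs.", "ms", "ms.",
}
_SUFFIX_TOKENS = {"jr", "jr.", "sr", "sr.", "md", "m.d.", "phd", "ph.d.", "ii", "iii"}

#: Generic words carrying no identity evidence in org/location strings.
_CONTEXT_STOPWORDS = {
    "university", "institute", "institutes", "clinic", "hospital",
    "hospitals", "college", "school", "center", "centre", "laboratory",
    "lab", "research", "medical", "national", "department", "of", "the",
    "for", "and", "at", "in",
}


def parse_person_name(name: str) -> tuple[list[str], str]:
    """Split a surface name into (first/middle tokens, last token),
    dropping honorific prefixes and degree suffixes."""
    tokens = name.split()
    while tokens and tokens[0].casefold() in _PREFIX_TOKENS:
        tokens = tokens[1:]
    while tokens and tokens[-1].casefold().strip(",") in _SUFFIX_TOKENS:
        tokens = tokens[:-1]
    if not tokens:
        return [], ""
    return tokens[:-1], tokens[-1]


def _normalized_edit_distance(a: str, b: str) -> float:
    if not a and not b:
        return 0.0
    m = max(len(a), len(b))
    if not a or not b:
        return 1.0
    return edlib.align(a, b)["editDistance"] / m


def _first_token(tokens: list[str]) -> str:
    return tokens[0].casefold().rstrip(".") if tokens else ""


def name_similarity(a: str, b: str) -> float:
    """Similarity in [0, 1] between two person-name surfaces.

    The last names must agree within normalized edit distance 0.2 (else the
    score is 0).  The last-name edit similarity is then scaled by first-name
    compatibility: identical first names 1.0, an initial matching the other
    name's first letter 0.9, a missing first name 0.9, two full-but-different
    first names 0.
    """
    fa, la = parse_person_name(a)
    fb, lb = parse_person_name(b)
    if not la or not lb:
        return 0.0
    nd = _normalized_edit_distance(la.casefold(), lb.casefold())
    if nd > 0.2 + 1e-12:
        return 0.0
    last_sim = 1.0 - nd
    f1, f2 = _first_token(fa), _first_token(fb)
    if not f1 or not f2:
        comp = 0.9
    elif f1 == f2:
        comp = 1.0
    elif len(f1) == 1 or len(f2) == 1:
        short, full = (f1, f2) if len(f1) == 1 else (f2, f1)
        comp = 0.9 if full.startswith(short) else 0.0
    else:
        comp = 0.0
    return last_sim * comp


@dataclass(frozen=True)
class MentionRecord:
    """An expert mention plus the article context used as evidence."""

    doc_id: str
    char_start: int
    name: str
    orgs: tuple[str, ...] = ()
    locs: tuple[str, ...] = ()
    mention: object = None


@dataclass
class CanonicalPerson:
    person_id: str
    canonical_name: str
    aliases: tuple[str, ...]
    members: list[MentionRecord]

    @property
    def mention_count(self) -> int:
        return len(self.members)

    @property
    def doc_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m.doc_id for m in self.members}))


def _context_tokens(strings: Iterable[str]) -> frozenset[str]:
    return frozenset(
        w for s in strings for w in s.casefold().split()
        if w not in _CONTEXT_STOPWORDS and len(w) > 1
    )


def _is_ambiguous(name: str) -> bool:
    first, last = parse_person_name(name)
    return not first or len(_first_token(first)) <= 1


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_mentions(
    records: Sequence[MentionRecord],
    theta_name: float = 0.85,
    require_context: bool | Literal["auto"] = "auto",
) -> list[CanonicalPerson]:
    """Single-link clustering of mention records into unique individuals.

    Records are sorted by (doc_id, offset), blocked by case-folded last name
    (blocks whose keys agree within normalized edit distance 0.2 are fused),
    and two records merge when ``name_similarity >= theta_name`` and the
    context requirement is met.  ``require_context=True`` demands a shared
    organization or location token for every merge; ``False`` never demands
    it; ``"auto"`` waives it only for exact full-name matches (both first
    names present and spelled out).

    The output clusters partition the input; lowering ``theta_name`` never
    increases the cluster count.
    """
    order = sorted(range(len(records)), key=lambda i: (records[i].doc_id,
                                                       records[i].char_start,
                                                       records[i].name))
    recs = [records[i] for i in order]
    n = len(recs)
    keys = [parse_person_name(r.name)[1].casefold() for r in recs]
    distinct = sorted(set(keys))
    key_uf = _UnionFind(len(distinct))
    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            if _normalized_edit_distance(distinct[i], distinct[j]) <= 0.2 + 1e-12:
                key_uf.union(i, j)
    key_root = {k: key_uf.find(i) for i, k in enumerate(distinct)}
    blocks: dict[int, list[int]] = {}
    for i, k in enumerate(keys):
        blocks.setdefault(key_root[k], []).append(i)

    # context = the *associated* organization/location: the nearest of each
    # type in the article (using every org/loc in the article would let any
    # shared background mention bridge two different people)
    ctx = [
        (_context_tokens(r.orgs[:1]), _context_tokens(r.locs[:1])) for r in recs
    ]
    parsed = [parse_person_name(r.name) for r in recs]

    def exact_full_match(i: int, j: int) -> bool:
        (fi, li), (fj, lj) = parsed[i], parsed[j]
        if li.casefold() != lj.casefold():
            return False
        a, b = _first_token(fi), _first_token(fj)
        return bool(a) and a == b and len(a) > 1

    uf = _UnionFind(n)
    for members in blocks.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if name_similarity(recs[i].name, recs[j].name) < theta_name:
                    continue
                if require_context is True:
                    need = True
                elif require_context is False:
                    need = False
                else:  # auto
                    need = not exact_full_match(i, j)
                if need:
                    shared = (ctx[i][0] & ctx[j][0]) or (ctx[i][1] & ctx[j][1])
                    if not shared:
                        continue
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    persons: list[CanonicalPerson] = []
    for k, root in enumerate(sorted(groups)):
        members = [recs[i] for i in groups[root]]
        surfaces = sorted({m.name for m in members})
        canonical = max(surfaces, key=lambda s: (len(s), [-ord(c) for c in s]))
        persons.append(
            CanonicalPerson(
                person_id=f"P{k:05d}",
                canonical_name=canonical,
                aliases=tuple(surfaces),
                members=members,
            )
        )
    return persons


def build_records(
    expert_mentions: Sequence,
    doc_mentions: dict[str, Sequence],
    documents: dict[str, object] | None = None,
) -> list[MentionRecord]:
    """Attach organization/location context to expert mentions.

    ``doc_mentions`` maps doc_id to all typed mentions of that document.
    When ``documents`` (doc_id -> tokenized ``Document``) is supplied,
    context is restricted to mentions in the same sentence — the
    attribution sentence of a news article is what carries a person's
    affiliation — falling back to the whole article when the sentence has
    none.  Context lists are ordered nearest-first by character distance.
    """
    sentence_spans: dict[str, list[tuple[int, int]]] = {}
    if documents:
        for doc_id, doc in documents.items():
            sentence_spans[doc_id] = [
                (s.tokens[0].char_start, s.tokens[-1].char_end)
                for s in doc.sentences if s.tokens
            ]

    records = []
    for em in expert_mentions:
        others = doc_mentions.get(em.doc_id, [])
        bounds = None
        for lo, hi in sentence_spans.get(em.doc_id, ()):
            if lo <= em.char_start and em.char_end <= hi:
                bounds = (lo, hi)
                break

        def nearest(etype: str) -> tuple[str, ...]:
            cands = [m for m in others if m.type == etype]
            if bounds is not None:
                within = [m for m in cands
                          if bounds[0] <= m.char_start and m.char_end <= bounds[1]]
                if within:
                    cands = within
            cands.sort(key=lambda m: (abs(m.char_start - em.char_start), m.char_start))
            return tuple(m.text for m in cands)

        records.append(
            MentionRecord(
                doc_id=em.doc_id,
                char_start=em.char_start,
                name=em.text,
                orgs=nearest("organization"),
                locs=nearest("location"),
                mention=em,
            )
        )
    return records
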