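"""Deterministic synthetic news corpora with full ground truth.

The generator emulates the statistical structure the expert-discovery
pipeline assumes in real health news, without requiring any download:

* templated news sentences embedding gold-annotated Person, Organization
  and Location names drawn from bundled synthetic lexicons;
* subject experts placed within 100 characters of a scholarly keyword and
  given publication counts >= 10; non-experts either placed beyond the
  keyword window (behind long keyword-free filler) or given counts < 10;
* organization-nested name traps ("Maylor Clinic" ... "I visited Maylor"),
  polysemous identical names attached to different organizations, and
  initial-vs-full synonym forms ("J. Doe" / "John Doe");
* planted community structure for the co-mention network (articles draw
  their persons from blocks, with a small cross-block probability);
* a matching publication-count table, CoNLL training split, lexicon files
  and a per-mention ground truth (true person id, expert flag, true
  co-mention edges).

Everything is driven by one ``random.Random(seed)``; a fixed seed yields
byte-identical output files.  Before returning, the generator verifies
offset fidelity and that the three filter rules alone reproduce the planted
expert flags exactly (separability); violations raise ``GeneratorError``
rather than emitting an inconsistent corpus.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import expert_filter
from .corpus_io import Document, LabeledSentence, Token, tokenize, write_conll
from .ner_crf import Lexicons, RulePosTagger


class GeneratorError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Bundled synthetic name pools (invented, license-free; the pools are
# mutually disjoint so person, organization and location surfaces never
# collide by accident — only the trap heads are designed to collide).
# ---------------------------------------------------------------------------

FIRST_NAMES = (
    "Alara", "Bennet", "Carys", "Doran", "Elio", "Farrah", "Gideon", "Hale",
    "Imara", "Jorun", "Kiva", "Lysandra", "Marek", "Nadia", "Orin", "Petra",
    "Quill", "Rosalind", "Soren", "Talia", "Ulric", "Vera", "Wendel",
    "Xenia", "Yusra", "Zane", "Amity", "Bram", "Celia", "Dexter", "Elowen",
    "Fintan", "Greta", "Hollis", "Ines", "Jasper", "Keturah", "Lionel",
    "Maeve", "Nestor", "Odile", "Pascal", "Quinta", "Rufus", "Sybil",
    "Tobias", "Una", "Vance",
)

LAST_NAMES = (
    "Abernathy", "Blackwood", "Calloway", "Draven", "Ellsworth",
    "Fairbanks", "Galloway", "Hargrove", "Ivers", "Jardine", "Kessler",
    "Lockhart", "Merriweather", "Northgate", "Oakes", "Pemberton",
    "Quimby", "Ravenscroft", "Sablewood", "Thackeray", "Underhill",
    "Veltman", "Whitlock", "Yarrow", "Zellner", "Ashcombe", "Birchall",
    "Crowther", "Dunmore", "Eastgate", "Farnsworth", "Gresham",
    "Holloway", "Ironwood", "Jessop", "Kirkby", "Lanyon", "Mortlake",
    "Netherby", "Ormsby", "Pickersgill", "Quarles", "Redfern", "Stanhope",
    "Tredwell", "Umber", "Vexley", "Wolcott", "Yates", "Zorn", "Applewhite",
    "Brackenridge", "Coldwell", "Dunleavy", "Everhart", "Fenmore",
    "Grimsby", "Hartwell", "Inchbald", "Joyner", "Kentwell", "Loxley",
    "Marchbanks", "Norwell",
)

ORG_HEADS = (
    "Varenth", "Kellowan", "Mirebrook", "Tallowmere", "Quindell",
    "Selworth", "Duncliffe", "Everbright", "Norfell", "Pellham",
    "Wrenfield", "Caldermoor", "Brightholm", "Stonefen", "Ashvale",
    "Glenmorrow", "Harrowgate", "Fennimore",
)
ORG_TYPES = ("University", "Institute", "Medical School", "Clinic",
             "College", "Research Hospital")

TRAP_HEADS = ("Maylor", "Carden", "Bexley", "Thorwald")

LOCATIONS = (
    "Brimlake", "Coldport", "Dunmere", "Eastvale", "Farrowgate",
    "Glimmerton", "Hartsfall", "Ilverton", "Juneport", "Kestrelmoor",
    "Larkspur", "Midvale", "Norrbay", "Oakhollow", "Pinecrest",
    "Quarrytown", "Ridgemont", "Silverbeck", "Tarnwick", "Umberlyn",
    "Westhollow", "Yellowfield",
)

TOPICS = (
    "obesity", "childhood obesity", "nutrition habits", "metabolic health",
    "diet trends", "sleep patterns", "food policy", "exercise routines",
)

# Sentence templates.  Expert templates place the name within 100 characters
# of at least one scholarly keyword ("Dr.", "researcher", the
# institution-type word of the organization, ...); filler and far templates
# contain no keyword token at all.

_OPENING_FILLERS = (
    "The morning streets of {loc} filled slowly with commuters and delivery vans.",
    "A cool wind moved through {loc} as the week began.",
    "Market stalls lined the harbor of {loc} before sunrise.",
)
_LONG_FILLERS = (
    "The town market opened early as vendors arranged crates of apples, pears,"
    " and late-season berries along the old waterfront promenade.",
    "Families strolled past the fountain while street musicians tuned their"
    " instruments and bakers set out trays of warm bread for the crowd.",
    "Rowers glided across the bay at dawn, trailed by gulls, while joggers"
    " wound along the shoreline path toward the lighthouse and back again.",
)
_CLOSING_FILLERS = (
    "The afternoon ended quietly as ferries crossed the calm gray water.",
    "By evening the streets had emptied and the harbor lights came on.",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus."""

    seed: int = 42
    n_articles: int = 120
    n_persons: int = 60
    expert_fraction: float = 0.6
    lowpub_fraction: float = 0.2    # keyword context but < 10 publications
    polysemy_pairs: int = 2         # identical full names, different orgs
    initial_form_rate: float = 0.3  # "J. Doe" synonym forms
    org_trap_rate: float = 0.12     # articles with an org-nested name trap
    n_blocks: int = 3
    between_prob: float = 0.08      # cross-block co-mention probability
    persons_per_article: tuple[float, ...] = (0.3, 0.4, 0.2, 0.1)
    n_train_sentences: int = 260

    def validate(self) -> None:
        probs = (self.expert_fraction, self.lowpub_fraction,
                 self.initial_form_rate, self.org_trap_rate,
                 self.between_prob, *self.persons_per_article)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise GeneratorError("probabilities must lie in [0, 1]")
        if self.expert_fraction + self.lowpub_fraction > 1.0 + 1e-9:
            raise GeneratorError("expert and low-publication fractions exceed 1")
        if self.n_blocks < 1 or self.n_articles < 1 or self.n_persons < 1:
            raise GeneratorError("block, article and person counts must be positive")
        if self.n_persons + self.polysemy_pairs > len(LAST_NAMES):
            raise GeneratorError("not enough last names in the bundled pool")
        if self.expert_fraction > 0 and not expert_filter.DEFAULT_KEYWORDS:
            raise GeneratorError("experts require a non-empty keyword list")


@dataclass(frozen=True)
class PersonRecord:
    pid: str
    first: str
    last: str
    org: str
    loc: str
    block: int
    pub_count: int
    expert: bool
    kind: str  # expert | lowpub | far

    @property
    def full_name(self) -> str:
        return f"{self.first} {self.last}"


@dataclass(frozen=True)
class GoldMention:
    doc_id: str
    type: str
    char_start: int
    char_end: int
    text: str
    person_id: str | None = None
    expert: bool = False


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    documents: list[Document]
    gold_mentions: list[GoldMention]
    persons: dict[str, PersonRecord]
    true_edges: set[frozenset]
    train_sentences: list[LabeledSentence]
    lexicons: Lexicons
    pub_counts: dict[tuple[str, str], int]

    @property
    def pub_provider(self) -> expert_filter.StaticPublicationCounts:
        return expert_filter.StaticPublicationCounts(
            (f, l, c) for (f, l), c in sorted(self.pub_counts.items())
        )

    def gold_for_doc(self, doc_id: str) -> list[GoldMention]:
        return [m for m in self.gold_mentions if m.doc_id == doc_id]

    def true_mention_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.gold_mentions:
            if m.person_id is not None and m.expert:
                counts[m.person_id] = counts.get(m.person_id, 0) + 1
        return counts

    def emit(self, outdir: str | Path) -> None:
        """Write corpus.jsonl, gold.tsv, train.conll, lexicons/, pubs.tsv,
        truth.json — all plain text, byte-identical for a fixed seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .corpus_io import write_corpus_jsonl

        write_corpus_jsonl(self.documents, outdir / "corpus.jsonl")
        with open(outdir / "gold.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("doc_id\ttype\tchar_start\tchar_end\ttext\tperson_id\texpert\n")
            for m in self.gold_mentions:
                fh.write(
                    f"{m.doc_id}\t{m.type}\t{m.char_start}\t{m.char_end}\t"
                    f"{m.text}\t{m.person_id or ''}\t{int(m.expert)}\n"
                )
        write_conll(self.train_sentences, outdir / "train.conll")
        lexdir = outdir / "lexicons"
        lexdir.mkdir(exist_ok=True)
        for fname, values in (
            ("first_names.txt", FIRST_NAMES),
            ("last_names.txt", LAST_NAMES),
            ("org_names.txt", _org_lexicon_tokens()),
            ("loc_names.txt", LOCATIONS),
        ):
            (lexdir / fname).write_text(
                "\n".join(sorted(values)) + "\n", encoding="utf-8"
            )
        with open(outdir / "pubs.tsv", "w", encoding="utf-8", newline="\n") as fh:
            for (first, last), count in sorted(self.pub_counts.items()):
                fh.write(f"{first}\t{last}\t{count}\n")
        truth = {
            "config": asdict(self.config),
            "persons": {pid: asdict(p) for pid, p in sorted(self.persons.items())},
            "edges": sorted(sorted(e) for e in self.true_edges),
        }
        (outdir / "truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )


def _org_lexicon_tokens() -> tuple[str, ...]:
    tokens = set(ORG_HEADS) | set(TRAP_HEADS)
    for t in ORG_TYPES:
        tokens.update(t.split())
    return tuple(sorted(tokens))


# ---------------------------------------------------------------------------
# Article composition
# ---------------------------------------------------------------------------


class _Composer:
    """Accumulates sentence text and typed spans with document offsets."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.length = 0
        self.mentions: list[GoldMention] = []

    def add(self, pieces: Sequence[tuple]) -> None:
        """pieces: ("txt", s) or (type, surface, person_id, expert_flag)."""
        if self.parts:
            self.length += 1  # joining space
        chunk: list[str] = []
        pos = self.length
        for piece in pieces:
            if piece[0] == "txt":
                chunk.append(piece[1])
                pos += len(piece[1])
            else:
                etype, surface, pid, expert = piece
                self.mentions.append(
                    GoldMention(self.doc_id, etype, pos, pos + len(surface),
                                surface, pid, expert)
                )
                chunk.append(surface)
                pos += len(surface)
        sentence = "".join(chunk)
        self.parts.append(sentence)
        self.length += len(sentence)

    def text(self) -> str:
        return " ".join(self.parts)


def _opening_pieces(rng) -> list[tuple]:
    before, after = rng.choice(_OPENING_FILLERS).split("{loc}")
    return [("txt", before), ("location", rng.choice(LOCATIONS), None, False),
            ("txt", after)]


def _expert_sentence(rng, name_piece, org: str, loc: str) -> list[tuple]:
    topic = rng.choice(TOPICS)
    variant = rng.randrange(5)
    org_piece = ("organization", org, None, False)
    loc_piece = ("location", loc, None, False)
    if variant == 0:
        return [("txt", "Dr. "), name_piece,
                ("txt", ", a researcher at "), org_piece, ("txt", " in "),
                loc_piece, ("txt", f", said the findings on {topic} were encouraging.")]
    if variant == 1:
        return [("txt", "Prof. "), name_piece, ("txt", " of "), org_piece,
                ("txt", f" argued that {topic} deserves more attention in "),
                loc_piece, ("txt", ".")]
    if variant == 2:
        return [name_piece, ("txt", ", a professor at "), org_piece,
                ("txt", f", published a study on {topic} with colleagues in "),
                loc_piece, ("txt", ".")]
    if variant == 3:
        return [("txt", "According to Dr. "), name_piece,
                ("txt", ", the team at "), org_piece, ("txt", " in "),
                loc_piece, ("txt", f" has tracked {topic} for a decade.")]
    return [("txt", "Faculty at "), org_piece, ("txt", " led by "),
            name_piece, ("txt", f" reported new findings on {topic} in "),
            loc_piece, ("txt", ".")]


def _far_sentence(rng, name_piece, loc: str) -> list[tuple]:
    loc_piece = ("location", loc, None, False)
    variant = rng.randrange(3)
    if variant == 0:
        return [("txt", "Neighbors say "), name_piece, ("txt", " from "),
                loc_piece,
                ("txt", " spends weekends tending a small orchard near the river.")]
    if variant == 1:
        return [name_piece, ("txt", ", a retired ferry operator in "),
                loc_piece, ("txt", ", watched the harvest parade with family.")]
    return [("txt", "Longtime resident "), name_piece, ("txt", " of "),
            loc_piece, ("txt", " won the pie contest at the autumn fair.")]


def _name_piece(rng, person: PersonRecord, initial_form_rate: float) -> tuple:
    if rng.random() < initial_form_rate:
        surface = f"{person.first[0]}. {person.last}"
    else:
        surface = person.full_name
    return ("person", surface, person.pid, person.expert)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _make_persons(rng: random.Random, cfg: GeneratorConfig) -> list[PersonRecord]:
    lasts = rng.sample(LAST_NAMES, cfg.n_persons)
    n_expert = round(cfg.n_persons * cfg.expert_fraction)
    n_lowpub = round(cfg.n_persons * cfg.lowpub_fraction)
    kinds = (["expert"] * n_expert + ["lowpub"] * n_lowpub
             + ["far"] * (cfg.n_persons - n_expert - n_lowpub))
    rng.shuffle(kinds)
    block_orgs = {
        b: [f"{head} {ORG_TYPES[i % len(ORG_TYPES)]}"
            for i, head in enumerate(ORG_HEADS) if i % cfg.n_blocks == b]
        for b in range(cfg.n_blocks)
    }
    persons: list[PersonRecord] = []
    for i, (last, kind) in enumerate(zip(lasts, kinds)):
        block = i % cfg.n_blocks
        count = {
            "expert": rng.randint(10, 200),
            "lowpub": rng.randint(0, 9),
            "far": rng.randint(0, 30),
        }[kind]
        persons.append(PersonRecord(
            pid=f"T{i:04d}",
            first=rng.choice(FIRST_NAMES),
            last=last,
            org=rng.choice(block_orgs[block]),
            loc=rng.choice(LOCATIONS),
            block=block,
            pub_count=count,
            expert=kind == "expert",
            kind=kind,
        ))
    # polysemy twins: same full name, different block and organization
    experts = [p for p in persons if p.expert]
    spare_lasts = [l for l in LAST_NAMES if l not in set(lasts)]
    for j in range(min(cfg.polysemy_pairs, len(experts), len(spare_lasts))):
        src = experts[j]
        block = (src.block + 1) % cfg.n_blocks
        persons.append(PersonRecord(
            pid=f"T{cfg.n_persons + j:04d}",
            first=src.first,
            last=src.last,
            org=rng.choice(block_orgs[block]),
            loc=rng.choice([l for l in LOCATIONS if l != src.loc]),
            block=block,
            pub_count=src.pub_count,
            expert=True,
            kind="expert",
        ))
    return persons


def _verify(corpus: "SyntheticCorpus") -> None:
    by_doc = {d.doc_id: d for d in corpus.documents}
    for m in corpus.gold_mentions:
        if by_doc[m.doc_id].text[m.char_start:m.char_end] != m.text:
            raise GeneratorError(f"offset infidelity at {m}")
    provider = corpus.pub_provider
    for doc in corpus.documents:
        gold = corpus.gold_for_doc(doc.doc_id)
        from .ner_crf import Mention

        mentions = [
            Mention(m.doc_id, m.type, m.char_start, m.char_end, m.text)
            for m in gold
        ]
        survivors = expert_filter.filter_experts(mentions, doc.text, provider)
        got = {(s.char_start, s.char_end) for s in survivors}
        want = {(m.char_start, m.char_end) for m in gold
                if m.type == "person" and m.expert}
        if got != want:
            raise GeneratorError(
                f"filter separability violated in {doc.doc_id}: "
                f"extra={sorted(got - want)} missing={sorted(want - got)}"
            )


def _train_split(rng: random.Random,
                 cfg: GeneratorConfig) -> list[LabeledSentence]:
    tagger = RulePosTagger()
    sentences: list[LabeledSentence] = []
    for _ in range(cfg.n_train_sentences):
        comp = _Composer("train")
        r = rng.random()
        first = rng.choice(FIRST_NAMES)
        last = rng.choice(LAST_NAMES)
        surface = (f"{first[0]}. {last}" if rng.random() < cfg.initial_form_rate
                   else f"{first} {last}")
        piece = ("person", surface, None, False)
        org = f"{rng.choice(ORG_HEADS)} {rng.choice(ORG_TYPES)}"
        loc = rng.choice(LOCATIONS)
        if r < 0.55:
            comp.add(_expert_sentence(rng, piece, org, loc))
        elif r < 0.70:
            comp.add(_far_sentence(rng, piece, loc))
        elif r < 0.80:
            head = rng.choice(TRAP_HEADS)
            trap_org = f"{head} {rng.choice(('Clinic', 'Institute'))}"
            if rng.random() < 0.5:
                comp.add([("organization", trap_org, None, False),
                          ("txt", f" is widely known across "),
                          ("location", loc, None, False),
                          ("txt", f" for its work on {rng.choice(TOPICS)}.")])
            else:
                comp.add([("txt", "So, I visited "),
                          ("person", head, None, False),
                          ("txt", f" to know more about {rng.choice(TOPICS)}.")])
        elif r < 0.90:
            comp.add(_opening_pieces(rng))
        else:
            comp.add([("txt", rng.choice(_LONG_FILLERS))])
        text = comp.text()
        doc = tokenize(text, doc_id="train")
        toks = doc.sentences[0].tokens if doc.sentences else []
        labels = []
        for tok in toks:
            label = "O"
            for m in comp.mentions:
                if tok.char_start >= m.char_start and tok.char_end <= m.char_end:
                    label = {"person": "Iperson", "organization": "Iorg",
                             "location": "Iloc"}[m.type]
                    break
            labels.append(label)
        tags = tagger.tag(toks)
        words = [t.text for t in toks]
        pos = 0
        rebuilt = []
        for w, tg in zip(words, tags):
            rebuilt.append(Token(w, pos, pos + len(w), pos=tg))
            pos += len(w) + 1
        sentences.append(LabeledSentence(rebuilt, labels))
    return sentences


def generate_corpus(config: GeneratorConfig | None = None) -> SyntheticCorpus:
    """Generate articles, ground truth, a training split, lexicons and a
    publication table.  Deterministic in ``config.seed``."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = random.Random(cfg.seed)
    persons = _make_persons(rng, cfg)
    by_block: dict[int, list[PersonRecord]] = {}
    for p in persons:
        by_block.setdefault(p.block, []).append(p)

    documents: list[Document] = []
    gold: list[GoldMention] = []
    edges: set[frozenset] = set()

    for a in range(cfg.n_articles):
        doc_id = f"news{a:04d}"
        comp = _Composer(doc_id)
        block = rng.randrange(cfg.n_blocks)
        pool = by_block[block]
        k = rng.choices(range(1, len(cfg.persons_per_article) + 1),
                        weights=cfg.persons_per_article)[0]
        chosen = rng.sample(pool, min(k, len(pool)))
        if rng.random() < cfg.between_prob and cfg.n_blocks > 1:
            other = rng.choice([b for b in range(cfg.n_blocks) if b != block])
            extra = rng.choice(by_block[other])
            if extra not in chosen:
                chosen.append(extra)

        comp.add(_opening_pieces(rng))
        far_people: list[PersonRecord] = []
        for p in chosen:
            if p.kind == "far":
                far_people.append(p)
                continue
            piece = _name_piece(rng, p, cfg.initial_form_rate)
            comp.add(_expert_sentence(rng, piece, p.org, p.loc))
        if rng.random() < cfg.org_trap_rate:
            head = rng.choice(TRAP_HEADS)
            trap_org = f"{head} {rng.choice(('Clinic', 'Institute'))}"
            comp.add([("organization", trap_org, None, False),
                      ("txt", " is widely known across "),
                      ("location", rng.choice(LOCATIONS), None, False),
                      ("txt", f" for its work on {rng.choice(TOPICS)}.")])
            comp.add([("txt", "So, I visited "),
                      ("person", head, None, False),
                      ("txt", f" to know more about {rng.choice(TOPICS)}.")])
        if far_people:
            comp.add([("txt", rng.choice(_LONG_FILLERS))])
            for p in far_people:
                piece = _name_piece(rng, p, cfg.initial_form_rate)
                comp.add(_far_sentence(rng, piece, p.loc))
        comp.add([("txt", rng.choice(_CLOSING_FILLERS))])

        documents.append(tokenize(comp.text(), doc_id=doc_id))
        gold.extend(comp.mentions)
        article_experts = sorted(p.pid for p in chosen if p.expert)
        for i, u in enumerate(article_experts):
            for v in article_experts[i + 1:]:
                edges.add(frozenset((u, v)))

    pub_counts: dict[tuple[str, str], int] = {}
    for p in persons:
        pub_counts[(p.first, p.last)] = p.pub_count

    lexicons = Lexicons.from_iterables(
        FIRST_NAMES, LAST_NAMES, _org_lexicon_tokens(), LOCATIONS
    )
    corpus = SyntheticCorpus(
        config=cfg,
        documents=documents,
        gold_mentions=gold,
        persons={p.pid: p for p in persons},
        true_edges=edges,
        train_sentences=_train_split(rng, cfg),
        lexicons=lexicons,
        pub_counts=pub_counts,
    )
    _verify(corpus)
    return corpus


# ---------------------------------------------------------------------------
# Pipeline scoring against ground truth
# ---------------------------------------------------------------------------


def _pairs(groups: Sequence[Sequence]) -> set[frozenset]:
    out: set[frozenset] = set()
    for g in groups:
        g = list(g)
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                out.add(frozenset((g[i], g[j])))
    return out


def score_pipeline(
    truth: SyntheticCorpus,
    predicted_mentions=None,
    expert_mentions=None,
    clusters=None,
    graph=None,
    centrality=None,
) -> dict:
    """Per-stage quality report against the generator's ground truth.

    Provide whichever stage outputs are available: typed ``Mention`` lists
    for NER, surviving expert mentions for the filter, ``CanonicalPerson``
    clusters for normalization, the co-mention graph and the centrality
    table.  Clustering is scored pairwise (label-invariant); graph edges by
    Jaccard similarity after mapping each cluster to its majority true
    person; ranks by Spearman correlation between computed mention counts
    and planted prominence.
    """
    from .eval_metrics import match_mentions, prf

    report: dict = {}
    gold_person = [m for m in truth.gold_mentions if m.type == "person"]
    span_to_pid = {
        (m.doc_id, m.char_start, m.char_end): m.person_id for m in gold_person
    }

    if predicted_mentions is not None:
        counts = match_mentions(predicted_mentions, gold_person, mode="exact")
        p, r, f = prf(counts)
        report["ner"] = {"precision": p, "recall": r, "f": f,
                         "counts": (counts.tp, counts.fn, counts.fp)}

    if expert_mentions is not None:
        got = {(m.doc_id, m.char_start, m.char_end) for m in expert_mentions}
        want = {(m.doc_id, m.char_start, m.char_end)
                for m in gold_person if m.expert}
        tp = len(got & want)
        from .eval_metrics import EvalCounts

        p, r, f = prf(EvalCounts(tp, len(want) - tp, len(got) - tp))
        report["filter"] = {"precision": p, "recall": r, "f": f}

    cluster_to_pid: dict[int, str] = {}
    if clusters is not None:
        member_pids: list[list[str]] = []
        for ci, cluster in enumerate(clusters):
            pids = []
            for rec in cluster.members:
                pid = span_to_pid.get(
                    (rec.doc_id, rec.char_start,
                     rec.char_start + len(rec.name))
                )
                if pid is not None:
                    pids.append(pid)
            member_pids.append(pids)
            if pids:
                cluster_to_pid[ci] = max(sorted(set(pids)), key=pids.count)
        # pairwise scores over the mention universe with known true identity
        true_groups: dict[str, list] = {}
        for ci, pids in enumerate(member_pids):
            for k, pid in enumerate(pids):
                true_groups.setdefault(pid, []).append((ci, k))
        pred_pairs = _pairs([[(ci, k) for k in range(len(pids))]
                             for ci, pids in enumerate(member_pids)])
        true_pairs = _pairs(list(true_groups.values()))
        tp = len(pred_pairs & true_pairs)
        precision = tp / len(pred_pairs) if pred_pairs else 1.0
        recall = tp / len(true_pairs) if true_pairs else 1.0
        report["clustering"] = {"pair_precision": precision,
                                "pair_recall": recall}

    if graph is not None and clusters is not None:
        id_map = {clusters[ci].person_id: pid
                  for ci, pid in cluster_to_pid.items()}
        pred_edges = {
            frozenset((id_map[u], id_map[v]))
            for u, v in graph.edges
            if u in id_map and v in id_map and id_map[u] != id_map[v]
        }
        union = pred_edges | truth.true_edges
        inter = pred_edges & truth.true_edges
        report["graph"] = {
            "edge_jaccard": len(inter) / len(union) if union else 1.0,
            "n_pred_edges": len(pred_edges),
            "n_true_edges": len(truth.true_edges),
        }

    if centrality is not None and clusters is not None:
        from scipy.stats import spearmanr

        id_map = {clusters[ci].person_id: pid
                  for ci, pid in cluster_to_pid.items()}
        truth_counts = truth.true_mention_counts()
        xs, ys = [], []
        for pid_cluster, row in centrality.iterrows():
            tpid = id_map.get(pid_cluster)
            if tpid is not None and tpid in truth_counts:
                xs.append(truth_counts[tpid])
                ys.append(row["mentions"])
        if len(xs) >= 3:
            rho = float(spearmanr(xs, ys).statistic)
            report["rank_correlation"] = {"mentions_spearman": rho}
    return report
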