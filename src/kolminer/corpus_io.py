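"""Reading news articles and labeled training corpora.

Raw inputs are HTML or plain-text news articles; training data follows the
CoNLL-2003 four-column layout (token, POS, chunk, NE tag).  Entity labels use
the four-label IO scheme ``Iperson / Iorg / Iloc / O``: a token is either
inside a typed entity or outside any entity.  All character offsets are
0-based, half-open into the owning document's text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import lxml.html

IO_LABELS: tuple[str, ...] = ("Iperson", "Iorg", "Iloc", "O")

#: IO label -> mention type name
ENTITY_TYPES = {"Iperson": "person", "Iorg": "organization", "Iloc": "location"}

_CONLL_TO_IO = {"PER": "Iperson", "ORG": "Iorg", "LOC": "Iloc", "MISC": "O"}
_IO_TO_CONLL = {"Iperson": "I-PER", "Iorg": "I-ORG", "Iloc": "I-LOC", "O": "O"}


class ConllFormatError(ValueError):
    """Raised when a CoNLL file does not follow the four-column layout."""


@dataclass(frozen=True)
class Token:
    text: str
    char_start: int
    char_end: int
    pos: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(f"bad token span [{self.char_start}, {self.char_end})")


@dataclass
class Sentence:
    doc_id: str
    index: int
    tokens: list[Token]
    section: str | None = None


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    source_uri: str | None = None


@dataclass
class LabeledSentence:
    """A training sentence: tokens plus one IO label per token."""

    tokens: list[Token]
    labels: list[str]
    section: str | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError("labels length must equal tokens length")
        bad = set(self.labels) - set(IO_LABELS)
        if bad:
            raise ValueError(f"labels outside the IO label set: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Boilerplate removal
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"<\s*[A-Za-z!/]")
_WS_RE = re.compile(r"[ \t\r\f\v]+")

_DROP_TAGS = {
    "script", "style", "noscript", "nav", "header", "footer",
    "aside", "form", "iframe", "svg", "button", "select", "option",
}
_LEAF_TAGS = {
    "p", "li", "h1", "h2", "h3", "h4", "h5", "h6", "td", "th",
    "blockquote", "pre", "dd", "dt", "figcaption", "caption", "summary",
}


def _collapse(text: str) -> str:
    return _WS_RE.sub(" ", text.replace("\n", " ")).strip()


def _leaf_blocks(el) -> list:
    if not isinstance(el.tag, str):
        return []
    if el.tag in _LEAF_TAGS:
        return [el]
    found: list = []
    for child in el:
        found.extend(_leaf_blocks(child))
    if found:
        return found
    return [el]


def strip_boilerplate(html: str, max_link_density: float = 0.4) -> str:
    """Convert an HTML news page to plain article text.

    Tag-stripping plus a per-block link-density heuristic: each leaf text
    block (paragraph, heading, list item, ...) is kept only if the fraction
    of its characters that sit inside ``<a>`` elements is at most
    ``max_link_density``.  Link-dense sidebars and navigation lists are
    dropped; the article body survives.  Paragraph breaks become newlines.
    Plain-text input (no markup) is returned unchanged, which makes the
    function idempotent on its own output.
    """
    if not html or not html.strip():
        return ""
    if not _TAG_RE.search(html):
        return html.strip()
    try:
        tree = lxml.html.fromstring(html)
    except lxml.etree.ParserError:
        return ""
    for el in list(tree.iter()):
        if isinstance(el.tag, str) and el.tag in _DROP_TAGS:
            parent = el.getparent()
            if parent is not None:
                el.drop_tree()
    kept: list[str] = []
    for block in _leaf_blocks(tree):
        text = _collapse(" ".join(block.itertext()))
        if not text:
            continue
        link_chars = sum(
            len(_collapse(" ".join(a.itertext()))) for a in block.iter("a")
        )
        if link_chars / len(text) > max_link_density:
            continue
        kept.append(text)
    return "\n".join(kept)


# ---------------------------------------------------------------------------
# Tokenization and sentence splitting
# ---------------------------------------------------------------------------

# Abbreviations kept as single tokens and protected from sentence breaks.
# The honorifics/degrees used by the expert keyword filter ("Dr.", "M.D.",
# "Ph.D.", "Prof.") are the load-bearing entries.
ABBREVIATIONS: tuple[str, ...] = (
    "Ph.D.", "M.D.", "D.Sc.", "Dr.", "Prof.", "Mr.", "Mrs.", "Ms.",
    "St.", "Jr.", "Sr.", "vs.", "etc.", "e.g.", "i.e.", "U.S.", "U.K.",
)

_TOKEN_RE = re.compile(
    "|".join(
        [re.escape(a) for a in ABBREVIATIONS]
        + [
            r"[A-Z]\.",                       # personal initials: "J."
            r"[A-Za-z]+(?:['’-][A-Za-z]+)*",
            r"\d+(?:[.,]\d+)*",
            r"\S",
        ]
    )
)

_TERMINALS = {".", "!", "?"}
_CLOSERS = {'"', "'", "”", "’", ")", "]"}


def tokenize(text: str, doc_id: str = "doc") -> Document:
    """Tokenize plain text into a :class:`Document` with offset-true tokens.

    Sentences are split after terminal punctuation tokens (``. ! ?``);
    abbreviations such as "Dr." keep their period inside the token and so
    never trigger a break.  Empty text yields a document with no sentences.
    """
    doc = Document(doc_id=doc_id, text=text)
    raw = [
        Token(m.group(0), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]
    sentences: list[list[Token]] = []
    current: list[Token] = []
    i = 0
    while i < len(raw):
        tok = raw[i]
        current.append(tok)
        if tok.text in _TERMINALS:
            # absorb trailing quotes / brackets into the sentence
            while i + 1 < len(raw) and raw[i + 1].text in _CLOSERS:
                i += 1
                current.append(raw[i])
            sentences.append(current)
            current = []
        i += 1
    if current:
        sentences.append(current)
    doc.sentences = [
        Sentence(doc_id=doc_id, index=k, tokens=toks)
        for k, toks in enumerate(sentences)
    ]
    return doc


# ---------------------------------------------------------------------------
# CoNLL-2003 reading / writing
# ---------------------------------------------------------------------------


def _space_joined_tokens(words: Sequence[str], tags: Sequence[str | None]) -> list[Token]:
    tokens, pos = [], 0
    for word, tag in zip(words, tags):
        tokens.append(Token(word, pos, pos + len(word), pos=tag))
        pos += len(word) + 1
    return tokens


def read_conll(path: str | Path) -> list[LabeledSentence]:
    """Read a CoNLL-2003 column file into IO-labeled sentences.

    IOB named-entity tags collapse onto the four-label IO scheme:
    ``B-PER/I-PER -> Iperson``, ``B-ORG/I-ORG -> Iorg``,
    ``B-LOC/I-LOC -> Iloc`` and everything else (``O``, MISC) ``-> O``.
    Token offsets are synthesized by single-space joining within each
    sentence.  A row with the wrong column count raises
    :class:`ConllFormatError` naming the line.
    """
    sentences: list[LabeledSentence] = []
    words: list[str] = []
    tags: list[str | None] = []
    labels: list[str] = []

    def flush() -> None:
        if words:
            sentences.append(
                LabeledSentence(_space_joined_tokens(words, tags), list(labels))
            )
            words.clear(), tags.clear(), labels.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split()
            if cols[0] == "-DOCSTART-":
                flush()
                continue
            if len(cols) != 4:
                raise ConllFormatError(
                    f"line {lineno}: expected 4 columns, got {len(cols)}"
                )
            word, pos_tag, _chunk, ne = cols
            if ne == "O":
                label = "O"
            else:
                try:
                    prefix, etype = ne.split("-", 1)
                except ValueError:
                    raise ConllFormatError(f"line {lineno}: bad NE tag {ne!r}")
                if prefix not in ("B", "I") or etype not in _CONLL_TO_IO:
                    raise ConllFormatError(f"line {lineno}: bad NE tag {ne!r}")
                label = _CONLL_TO_IO[etype]
            words.append(word)
            tags.append(None if pos_tag == "-X-" else pos_tag)
            labels.append(label)
    flush()
    return sentences


def write_conll(sentences: Iterable[LabeledSentence], path: str | Path) -> None:
    """Write IO-labeled sentences in CoNLL-2003 column layout.

    ``read_conll(write_conll(x)) == x`` holds for sentences whose token
    offsets are single-space joined (as produced by ``read_conll`` and the
    synthetic corpus generator).  Absent POS tags are stored as ``-X-``; the
    chunk column is a constant placeholder.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sent in sentences:
            for tok, label in zip(sent.tokens, sent.labels):
                if label not in IO_LABELS:
                    raise ValueError(f"label outside the IO label set: {label!r}")
                fh.write(
                    f"{tok.text} {tok.pos or '-X-'} -X- {_IO_TO_CONLL[label]}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Corpus ingest
# ---------------------------------------------------------------------------


def read_corpus_dir(path: str | Path, fmt: str = "txt") -> list[Document]:
    """Read a directory of ``.txt`` or ``.html`` articles into documents."""
    path = Path(path)
    ext = {"txt": ".txt", "html": ".html"}[fmt]
    docs = []
    for fp in sorted(path.glob(f"*{ext}")):
        raw = fp.read_text(encoding="utf-8")
        text = strip_boilerplate(raw) if fmt == "html" else raw
        doc = tokenize(text, doc_id=fp.stem)
        doc.source_uri = str(fp)
        docs.append(doc)
    return docs


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    """Write one ``{"doc_id": ..., "text": ...}`` JSON object per line."""
    import json

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for doc in docs:
            fh.write(json.dumps({"doc_id": doc.doc_id, "text": doc.text},
                                sort_keys=True) + "\n")


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    import json

    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                docs.append(tokenize(rec["text"], doc_id=rec["doc_id"]))
    return docs
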