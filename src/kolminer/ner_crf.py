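"""First-order linear-chain CRF for Person/Organization/Location extraction.

The tagger assigns one of four IO labels (``Iperson``, ``Iorg``, ``Iloc``,
``O``) to every token.  The score of a label sequence y for a sentence with
per-token feature sets x is

    score(y) = sum_t [ W[y_t] · x_t  +  T[y_{t-1}, y_t] ]

with state weights W (label × feature) and transition weights T
(label × label).  Training minimizes the L2-penalized negative conditional
log-likelihood with the partition function from the forward recursion in log
space; decoding is Viterbi with ties broken by the fixed label order.  The
IO scheme keeps the label set minimal (decoding is O(T·L²) per sentence) at
the known cost that abutting same-type entities merge into one mention.

Feature families (all binary, string-named):

* lexical — lowercased token, rule-lemma, prefixes/suffixes (lengths 2–4),
  character n-grams, shape patterns (initial capital, all caps, digits,
  periods, hyphens);
* syntactic — part-of-speech tag (from training columns, or a pluggable
  tagger at run time);
* pragmatic — section label of the sentence;
* semantic — dictionary membership (person first/last, organization,
  location lexicons) and distributional-thesaurus neighbors (names of the
  top-k paradigmatically similar terms).

Every family is also emitted for context tokens at offsets −2..+2, tagged
with the offset; positions beyond the sentence contribute only an explicit
boundary marker.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse

from .corpus_io import (
    ENTITY_TYPES,
    IO_LABELS,
    Document,
    LabeledSentence,
    Sentence,
    Token,
)

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


class NumericalError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Lexicons and the distributional thesaurus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lexicons:
    """Case-folded name dictionaries used as semantic features."""

    first_names: frozenset[str]
    last_names: frozenset[str]
    org_names: frozenset[str]
    loc_names: frozenset[str]

    @classmethod
    def from_iterables(cls, first, last, org, loc) -> "Lexicons":
        fold = lambda it: frozenset(s.casefold() for s in it)
        return cls(fold(first), fold(last), fold(org), fold(loc))

    @classmethod
    def load(cls, directory: str | Path) -> "Lexicons":
        directory = Path(directory)

        def read(name: str) -> list[str]:
            fp = directory / name
            if not fp.exists():
                return []
            return [ln.strip() for ln in fp.read_text(encoding="utf-8").splitlines()
                    if ln.strip()]

        return cls.from_iterables(
            read("first_names.txt"), read("last_names.txt"),
            read("org_names.txt"), read("loc_names.txt"),
        )


@dataclass
class DistributionalThesaurus:
    """term -> nearest paradigmatic neighbors (cosine over context counts)."""

    neighbors: dict[str, tuple[tuple[str, float], ...]]
    window: int

    def get(self, term: str) -> tuple[tuple[str, float], ...]:
        return self.neighbors.get(term.casefold(), ())


def build_thesaurus(
    sentences: Sequence[Sequence[str]],
    window: int = 2,
    top_k: int = 5,
    min_count: int = 2,
) -> DistributionalThesaurus:
    """Build a thesaurus of distributionally similar terms.

    Terms occurring at least ``min_count`` times get context-cooccurrence
    vectors (symmetric window of ``window`` positions) and are mapped to
    their ``top_k`` cosine-nearest other terms.  Two terms that occur in
    identical contexts have similarity 1.0; terms with disjoint contexts 0.0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    from collections import Counter

    counts: Counter[str] = Counter()
    folded = [[t.casefold() for t in sent] for sent in sentences]
    for sent in folded:
        counts.update(sent)
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        logger.warning("corpus below frequency floor; thesaurus is empty")
        return DistributionalThesaurus({}, window)
    dims = sorted(counts)
    dim_ix = {t: i for i, t in enumerate(dims)}
    voc_ix = {t: i for i, t in enumerate(vocab)}
    mat = np.zeros((len(vocab), len(dims)))
    for sent in folded:
        for i, term in enumerate(sent):
            row = voc_ix.get(term)
            if row is None:
                continue
            lo, hi = max(0, i - window), min(len(sent), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    mat[row, dim_ix[sent[j]]] += 1.0
    norms = np.linalg.norm(mat, axis=1)
    norms[norms == 0] = 1.0
    unit = mat / norms[:, None]
    sims = unit @ unit.T
    neighbors: dict[str, tuple[tuple[str, float], ...]] = {}
    for i, term in enumerate(vocab):
        order = sorted(
            (j for j in range(len(vocab)) if j != i),
            key=lambda j: (-sims[i, j], vocab[j]),
        )[:top_k]
        neighbors[term] = tuple((vocab[j], float(sims[i, j])) for j in order)
    return DistributionalThesaurus(neighbors, window)


# ---------------------------------------------------------------------------
# Rule-based POS tagging and lemmatization (run-time stand-ins for the
# training-corpus POS column)
# ---------------------------------------------------------------------------

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "of": "IN", "in": "IN", "at": "IN", "on": "IN", "for": "IN",
    "with": "IN", "from": "IN", "to": "TO", "by": "IN", "near": "IN",
    "and": "CC", "or": "CC", "but": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
    "said": "VBD", "says": "VBZ", "told": "VBD", "has": "VBZ",
    "have": "VBP", "had": "VBD", "be": "VB",
    "he": "PRP", "she": "PRP", "it": "PRP", "they": "PRP", "i": "PRP",
    "his": "PRP$", "her": "PRP$", "their": "PRP$",
}


class RulePosTagger:
    """Tiny deterministic rule tagger for run-time part-of-speech features."""

    def tag(self, tokens: Sequence[Token]) -> list[str]:
        tags = []
        for tok in tokens:
            t = tok.text
            low = t.casefold()
            if not t[0].isalnum() and len(t) <= 2:
                tags.append(t if t in ".,:;" else "SYM")
            elif low in _CLOSED_CLASS:
                tags.append(_CLOSED_CLASS[low])
            elif t[0].isdigit():
                tags.append("CD")
            elif t[0].isupper():
                tags.append("NNP")
            elif low.endswith("ing"):
                tags.append("VBG")
            elif low.endswith("ed"):
                tags.append("VBD")
            elif low.endswith("ly"):
                tags.append("RB")
            elif low.endswith("s") and len(low) > 3:
                tags.append("NNS")
            else:
                tags.append("NN")
        return tags


def rule_lemma(word: str) -> str:
    """Small rule lemmatizer: strips common inflection suffixes."""
    w = word.casefold()
    for suffix, repl, floor in (("ies", "y", 4), ("sses", "ss", 5),
                                ("ing", "", 5), ("ed", "", 4), ("s", "", 4)):
        if w.endswith(suffix) and len(w) >= floor:
            return w[: len(w) - len(suffix)] + repl
    return w


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


@dataclass
class FeatureConfig:
    dictionary: bool = True
    distributional: bool = True
    section: bool = True
    pos: bool = True
    lexical: bool = True
    window: int = 2
    affix_lengths: tuple[int, ...] = (2, 3, 4)
    ngram_lengths: tuple[int, ...] = (2, 3)
    thesaurus_k: int = 5

    def __post_init__(self) -> None:
        if not (self.dictionary or self.distributional or self.section
                or self.pos or self.lexical):
            raise ValueError("at least one feature family must be enabled")


_DIGIT_RE = re.compile(r"\d")


def _base_features(
    tok: Token,
    section: str | None,
    lexicons: Lexicons | None,
    thesaurus: DistributionalThesaurus | None,
    cfg: FeatureConfig,
) -> list[str]:
    t = tok.text
    low = t.casefold()
    feats: list[str] = []
    if cfg.lexical:
        feats.append(f"w={low}")
        feats.append(f"lem={rule_lemma(t)}")
        for n in cfg.affix_lengths:
            if len(low) >= n:
                feats.append(f"pre{n}={low[:n]}")
                feats.append(f"suf{n}={low[-n:]}")
        for n in cfg.ngram_lengths:
            for i in range(len(low) - n + 1):
                feats.append(f"ng{n}={low[i:i + n]}")
        if t[0].isupper():
            feats.append("pat=init-cap")
        if len(t) > 1 and t.isupper():
            feats.append("pat=all-caps")
        if _DIGIT_RE.search(t):
            feats.append("pat=has-digit")
        if "." in t:
            feats.append("pat=has-period")
        if "-" in t:
            feats.append("pat=has-hyphen")
    if cfg.pos and tok.pos is not None:
        feats.append(f"pos={tok.pos}")
    if cfg.section:
        feats.append(f"sec={section or 'NONE'}")
    if cfg.dictionary and lexicons is not None:
        if low in lexicons.first_names:
            feats.append("dict=person-first")
        if low in lexicons.last_names:
            feats.append("dict=person-last")
        if low in lexicons.org_names:
            feats.append("dict=org")
        if low in lexicons.loc_names:
            feats.append("dict=loc")
    if cfg.distributional and thesaurus is not None:
        for nbr, _score in thesaurus.get(low)[: cfg.thesaurus_k]:
            feats.append(f"thes={nbr}")
    return feats


def extract_features(
    sentence: Sentence | LabeledSentence,
    lexicons: Lexicons | None = None,
    thesaurus: DistributionalThesaurus | None = None,
    config: FeatureConfig | None = None,
) -> list[list[str]]:
    """Per-token feature-name lists with a −w..+w context window.

    Context features are tagged with their offset (``w=smith@-1``);
    positions before the start or past the end of the sentence contribute a
    single boundary marker (``BOS@-1`` / ``EOS@+2``) and nothing else.
    """
    cfg = config or FeatureConfig()
    section = getattr(sentence, "section", None)
    base = [
        _base_features(tok, section, lexicons, thesaurus, cfg)
        for tok in sentence.tokens
    ]
    n = len(base)
    out: list[list[str]] = []
    for i in range(n):
        feats: list[str] = []
        for off in range(-cfg.window, cfg.window + 1):
            j = i + off
            if j < 0:
                feats.append(f"BOS@{off}")
            elif j >= n:
                feats.append(f"EOS@{off:+d}")
            else:
                feats.extend(f"{f}@{off:+d}" for f in base[j])
        out.append(feats)
    return out


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


@dataclass
class TrainingStats:
    n_labels: int
    n_sentences: int
    mean_sentence_length: float
    mean_active_features: float
    iterations: int
    final_objective: float
    objective_history: list[float] = field(default_factory=list)


@dataclass
class CrfModel:
    labels: tuple[str, ...]
    feature_index: dict[str, int]
    state_weights: np.ndarray      # (L, F)
    transition_weights: np.ndarray  # (L, L)
    config: FeatureConfig = field(default_factory=FeatureConfig)
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    def encode(self, token_features: Sequence[Sequence[str]]) -> list[np.ndarray]:
        """Map feature names to column indices; unseen names are ignored."""
        idx = self.feature_index
        return [
            np.array(sorted(idx[f] for f in feats if f in idx), dtype=np.intp)
            for feats in token_features
        ]

    def save(self, path: str | Path) -> None:
        """Versioned flat-file serialization; round-trips bit-exact."""
        payload = {
            "format": "kolminer-crf",
            "version": 1,
            "labels": list(self.labels),
            "features": [
                name for name, _ in sorted(self.feature_index.items(),
                                           key=lambda kv: kv[1])
            ],
            "state_weights": self.state_weights.tolist(),
            "transition_weights": self.transition_weights.tolist(),
            "config": asdict(self.config),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CrfModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "kolminer-crf" or payload.get("version") != 1:
            raise ValueError("not a kolminer CRF model file (version 1)")
        cfg = payload["config"]
        for key in ("affix_lengths", "ngram_lengths"):
            cfg[key] = tuple(cfg[key])
        return cls(
            labels=tuple(payload["labels"]),
            feature_index={n: i for i, n in enumerate(payload["features"])},
            state_weights=np.array(payload["state_weights"]),
            transition_weights=np.array(payload["transition_weights"]),
            config=FeatureConfig(**cfg),
            metadata=payload["metadata"],
        )


# ---------------------------------------------------------------------------
# Inference: log-space forward/backward and Viterbi
# ---------------------------------------------------------------------------


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis=axis)


def _logsumexp_vec(v: np.ndarray) -> float:
    m = float(v.max())
    return m + math.log(float(np.exp(v - m).sum()))


def _emissions(
    state: np.ndarray, feats: Sequence[np.ndarray]
) -> np.ndarray:
    T, L = len(feats), state.shape[0]
    S = np.zeros((T, L))
    for t, ix in enumerate(feats):
        if len(ix):
            S[t] = state[:, ix].sum(axis=1)
    return S


def forward_log_z(S: np.ndarray, T_w: np.ndarray) -> float:
    """log of the partition function via the forward recursion."""
    alpha = S[0].copy()
    for t in range(1, S.shape[0]):
        alpha = S[t] + _logsumexp(alpha[:, None] + T_w, axis=0)
    return _logsumexp_vec(alpha)


def _forward_backward(S: np.ndarray, T_w: np.ndarray):
    T, L = S.shape
    alpha = np.empty((T, L))
    beta = np.empty((T, L))
    alpha[0] = S[0]
    for t in range(1, T):
        alpha[t] = S[t] + _logsumexp(alpha[t - 1][:, None] + T_w, axis=0)
    beta[T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        beta[t] = _logsumexp(T_w + (S[t + 1] + beta[t + 1])[None, :], axis=1)
    log_z = _logsumexp_vec(alpha[-1])
    return alpha, beta, log_z


def crf_nll_grad(
    model: CrfModel,
    batch: Sequence[tuple[Sequence[Sequence[str]] | Sequence[np.ndarray], Sequence[int]]],
    l2_variance: float | None = None,
):
    """Penalized NLL and its gradient over a batch of labeled sentences.

    Each batch item is ``(token_features, label_ids)`` where
    ``token_features`` is either per-token feature-name lists or already
    encoded index arrays.  Returns ``(nll, (grad_state, grad_transition))``
    with the gradient as expected minus empirical feature counts from the
    forward–backward marginals.
    """
    W, T_w = model.state_weights, model.transition_weights
    L = len(model.labels)
    grad_W = np.zeros_like(W)
    grad_T = np.zeros_like(T_w)
    nll = 0.0
    for s_ix, (feats, labels) in enumerate(batch):
        enc = (
            list(feats)
            if feats and isinstance(feats[0], np.ndarray)
            else model.encode(feats)
        )
        y = np.asarray(labels, dtype=np.intp)
        S = _emissions(W, enc)
        alpha, beta, log_z = _forward_backward(S, T_w)
        if not math.isfinite(log_z):
            raise NumericalError(f"non-finite partition function at sentence {s_ix}")
        gold = float(S[np.arange(len(y)), y].sum() + T_w[y[:-1], y[1:]].sum())
        nll += log_z - gold
        marg = np.exp(alpha + beta - log_z)          # (T, L)
        delta = marg.copy()
        delta[np.arange(len(y)), y] -= 1.0
        for t, ix in enumerate(enc):
            if len(ix):
                grad_W[:, ix] += delta[t][:, None]
        for t in range(1, len(y)):
            pair = np.exp(
                alpha[t - 1][:, None] + T_w + (S[t] + beta[t])[None, :] - log_z
            )
            grad_T += pair
            grad_T[y[t - 1], y[t]] -= 1.0
    if l2_variance:
        nll += (np.sum(W * W) + np.sum(T_w * T_w)) / (2.0 * l2_variance)
        grad_W += W / l2_variance
        grad_T += T_w / l2_variance
    if not math.isfinite(nll):
        raise NumericalError("non-finite objective")
    return nll, (grad_W, grad_T)


def viterbi_decode(
    model: CrfModel,
    token_features: Sequence[Sequence[str]] | Sequence[np.ndarray],
    return_ops: bool = False,
):
    """Argmax label sequence; ties broken by the fixed label order.

    With ``return_ops=True`` also returns the number of (previous label ×
    next label) transition evaluations, which is (T−1)·L² — linear in
    sentence length, quadratic in label count.
    """
    enc = (
        list(token_features)
        if token_features and isinstance(token_features[0], np.ndarray)
        else model.encode(token_features)
    )
    W, T_w = model.state_weights, model.transition_weights
    L = W.shape[0]
    S = _emissions(W, enc)
    T = S.shape[0]
    ops = 0
    if T == 0:
        return ([], 0) if return_ops else []
    delta = S[0].copy()
    back = np.zeros((T, L), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + T_w          # (prev, next)
        ops += L * L
        back[t] = np.argmax(cand, axis=0)     # first max = smallest label index
        delta = S[t] + cand[back[t], np.arange(L)]
    best = int(np.argmax(delta))
    path = [best]
    for t in range(T - 1, 0, -1):
        best = int(back[t, best])
        path.append(best)
    path.reverse()
    labels = [model.labels[i] for i in path]
    return (labels, ops) if return_ops else labels


# ---------------------------------------------------------------------------
# Mention assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mention:
    doc_id: str
    type: str                       # person | organization | location
    char_start: int
    char_end: int
    text: str
    token_span: tuple[int, int] = (0, 0)   # half-open token indices


def labels_to_mentions(
    sentence: Sentence | LabeledSentence,
    labels: Sequence[str],
    doc_text: str | None = None,
    doc_id: str | None = None,
) -> list[Mention]:
    """Convert an IO label sequence to typed mentions.

    Each maximal run of one inside-label becomes a single mention spanning
    from the first to the last token of the run; adjacent runs of different
    types are separate mentions.
    """
    toks = sentence.tokens
    if len(labels) != len(toks):
        raise ValueError("labels length must equal tokens length")
    did = doc_id or getattr(sentence, "doc_id", "doc")
    mentions: list[Mention] = []
    i = 0
    while i < len(labels):
        lab = labels[i]
        if lab == "O":
            i += 1
            continue
        j = i
        while j + 1 < len(labels) and labels[j + 1] == lab:
            j += 1
        start, end = toks[i].char_start, toks[j].char_end
        text = (
            doc_text[start:end]
            if doc_text is not None
            else " ".join(t.text for t in toks[i:j + 1])
        )
        mentions.append(
            Mention(did, ENTITY_TYPES[lab], start, end, text, (i, j + 1))
        )
        i = j + 1
    return mentions


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_crf(
    corpus: Sequence[LabeledSentence],
    config: FeatureConfig | None = None,
    lexicons: Lexicons | None = None,
    thesaurus: DistributionalThesaurus | None = None,
    l2_variance: float = 10.0,
    max_iter: int = 200,
    gtol: float = 1e-4,
) -> tuple[CrfModel, TrainingStats]:
    """Train the chain CRF by L-BFGS on the L2-penalized NLL.

    Weights start at zero, the feature table is built from the training
    corpus in sorted order, and L-BFGS-B minimizes until the gradient-norm
    tolerance or ``max_iter`` — so training is deterministic for a fixed
    corpus and configuration.
    """
    if not corpus:
        raise TrainingError("training corpus is empty")
    cfg = config or FeatureConfig()
    label_ix = {lab: i for i, lab in enumerate(IO_LABELS)}
    L = len(IO_LABELS)

    all_feats: list[list[list[str]]] = [
        extract_features(sent, lexicons, thesaurus, cfg) for sent in corpus
    ]
    names = sorted({f for sent in all_feats for tok in sent for f in tok})
    feature_index = {n: i for i, n in enumerate(names)}
    F = len(names)

    encoded: list[tuple[list[np.ndarray], np.ndarray]] = []
    n_tokens = n_active = 0
    for sent, feats in zip(corpus, all_feats):
        enc = [
            np.array(sorted(feature_index[f] for f in tok), dtype=np.intp)
            for tok in feats
        ]
        y = np.array([label_ix[lab] for lab in sent.labels], dtype=np.intp)
        encoded.append((enc, y))
        n_tokens += len(y)
        n_active += sum(len(ix) for ix in enc)

    model = CrfModel(
        labels=IO_LABELS,
        feature_index=feature_index,
        state_weights=np.zeros((L, F)),
        transition_weights=np.zeros((L, L)),
        config=cfg,
    )

    history: list[float] = []
    last: dict = {}

    def objective(w: np.ndarray):
        model.state_weights = w[: L * F].reshape(L, F)
        model.transition_weights = w[L * F:].reshape(L, L)
        nll, (gW, gT) = crf_nll_grad(model, encoded, l2_variance=l2_variance)
        last["x"], last["f"] = w.tobytes(), nll
        return nll, np.concatenate([gW.ravel(), gT.ravel()])

    def callback(xk: np.ndarray) -> None:
        history.append(last["f"])

    result = scipy.optimize.minimize(
        objective,
        np.zeros(L * F + L * L),
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-10},
    )
    if not math.isfinite(result.fun):
        raise TrainingError(f"divergent objective: {result.message}")
    model.state_weights = result.x[: L * F].reshape(L, F)
    model.transition_weights = result.x[L * F:].reshape(L, L)
    model.metadata = {
        "l2_variance": l2_variance,
        "iterations": int(result.nit),
        "converged": bool(result.success),
        "final_objective": float(result.fun),
    }
    stats = TrainingStats(
        n_labels=L,
        n_sentences=len(corpus),
        mean_sentence_length=n_tokens / len(corpus),
        mean_active_features=n_active / max(n_tokens, 1),
        iterations=int(result.nit),
        final_objective=float(result.fun),
        objective_history=history,
    )
    logger.info(
        "trained CRF: N=%d sentences, F=%d features, %d iterations, NLL=%.3f",
        stats.n_sentences, F, stats.iterations, stats.final_objective,
    )
    return model, stats


def tag_document(
    doc: Document,
    model: CrfModel,
    lexicons: Lexicons | None = None,
    thesaurus: DistributionalThesaurus | None = None,
    tagger: RulePosTagger | None = None,
) -> list[Mention]:
    """Decode every sentence of a document into typed mentions."""
    tagger = tagger or RulePosTagger()
    mentions: list[Mention] = []
    for sent in doc.sentences:
        if model.config.pos and any(t.pos is None for t in sent.tokens):
            tags = tagger.tag(sent.tokens)
            sent = Sentence(
                sent.doc_id, sent.index,
                [Token(t.text, t.char_start, t.char_end, pos=tag)
                 for t, tag in zip(sent.tokens, tags)],
                section=sent.section,
            )
        feats = extract_features(sent, lexicons, thesaurus, model.config)
        labels = viterbi_decode(model, feats)
        mentions.extend(
            labels_to_mentions(sent, labels, doc_text=doc.text, doc_id=doc.doc_id)
        )
    return mentions
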