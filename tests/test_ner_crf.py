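"""CRF inference against brute-force oracles, features, and training."""

import itertools
import math

import numpy as np
import pytest

from kolminer.corpus_io import IO_LABELS, LabeledSentence, Sentence, Token
from kolminer.ner_crf import (
    CrfModel,
    FeatureConfig,
    Lexicons,
    build_thesaurus,
    crf_nll_grad,
    extract_features,
    forward_log_z,
    labels_to_mentions,
    train_crf,
    viterbi_decode,
)

L = len(IO_LABELS)


def make_model(n_features: int, seed: int | None = None, scale: float = 1.0) -> CrfModel:
    index = {f"f{i}": i for i in range(n_features)}
    if seed is None:
        W = np.zeros((L, n_features))
        T = np.zeros((L, L))
    else:
        rng = np.random.default_rng(seed)
        W = rng.normal(scale=scale, size=(L, n_features))
        T = rng.normal(scale=scale, size=(L, L))
    return CrfModel(labels=IO_LABELS, feature_index=index,
                    state_weights=W, transition_weights=T)


def random_sentence(rng, n_tokens: int, n_features: int):
    """Per-token active feature names and a random gold labeling."""
    feats = [
        [f"f{i}" for i in sorted(rng.choice(n_features, size=3, replace=False))]
        for _ in range(n_tokens)
    ]
    labels = [int(x) for x in rng.integers(0, L, size=n_tokens)]
    return feats, labels


def emissions_of(model, feats):
    enc = model.encode(feats)
    S = np.zeros((len(feats), L))
    for t, ix in enumerate(enc):
        S[t] = model.state_weights[:, ix].sum(axis=1)
    return S


def enum_log_z(S, T):
    scores = [
        sum(S[t, y[t]] for t in range(S.shape[0]))
        + sum(T[y[t - 1], y[t]] for t in range(1, S.shape[0]))
        for y in itertools.product(range(L), repeat=S.shape[0])
    ]
    m = max(scores)
    return m + math.log(sum(math.exp(s - m) for s in scores))


def enum_argmax(S, T):
    best, best_score = None, -math.inf
    for y in itertools.product(range(L), repeat=S.shape[0]):
        score = sum(S[t, y[t]] for t in range(S.shape[0])) + sum(
            T[y[t - 1], y[t]] for t in range(1, S.shape[0])
        )
        if score > best_score + 1e-12:  # first maximum wins, as in decoding
            best, best_score = y, score
    return list(best)


class TestPartitionFunction:
    def test_single_token_zero_weights_is_log4(self):
        model = make_model(4)
        nll, _ = crf_nll_grad(model, [([["f0"]], [0])])
        assert nll == pytest.approx(math.log(4), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_forward_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = make_model(10, seed=seed)
        for n_tokens in (1, 2, 3, 4, 5):
            feats, _ = random_sentence(rng, n_tokens, 10)
            S = emissions_of(model, feats)
            assert forward_log_z(S, model.transition_weights) == pytest.approx(
                enum_log_z(S, model.transition_weights), abs=1e-8
            )

    def test_nll_is_minus_log_gold_probability(self):
        rng = np.random.default_rng(3)
        model = make_model(10, seed=3)
        feats, labels = random_sentence(rng, 3, 10)
        S = emissions_of(model, feats)
        T = model.transition_weights
        gold = sum(S[t, labels[t]] for t in range(3)) + sum(
            T[labels[t - 1], labels[t]] for t in range(1, 3)
        )
        expected = enum_log_z(S, T) - gold
        nll, _ = crf_nll_grad(model, [(feats, labels)])
        assert nll == pytest.approx(expected, abs=1e-8)


class TestGradient:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        model = make_model(10, seed=seed, scale=0.5)
        batch = [random_sentence(rng, n, 10) for n in (2, 4)]
        _, (gW, gT) = crf_nll_grad(model, batch, l2_variance=10.0)
        h = 1e-5
        flat = np.concatenate([model.state_weights.ravel(),
                               model.transition_weights.ravel()])
        analytic = np.concatenate([gW.ravel(), gT.ravel()])
        rng2 = np.random.default_rng(seed + 100)
        for k in rng2.choice(flat.size, size=12, replace=False):
            def f(x):
                w = flat.copy()
                w[k] = x
                model.state_weights = w[: L * 10].reshape(L, 10)
                model.transition_weights = w[L * 10:].reshape(L, L)
                nll, _ = crf_nll_grad(model, batch, l2_variance=10.0)
                return nll

            fd = (f(flat[k] + h) - f(flat[k] - h)) / (2 * h)
            model.state_weights = flat[: L * 10].reshape(L, 10)
            model.transition_weights = flat[L * 10:].reshape(L, L)
            assert analytic[k] == pytest.approx(fd, rel=1e-5, abs=1e-5)


class TestViterbi:
    def test_all_zero_weights_ties_break_to_first_label(self):
        model = make_model(4)
        labels = viterbi_decode(model, [["f0"], ["f1"], ["f2"]])
        assert labels == ["Iperson", "Iperson", "Iperson"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_argmax(self, seed):
        rng = np.random.default_rng(seed)
        model = make_model(10, seed=seed)
        for n_tokens in (1, 2, 3, 4, 5):
            feats, _ = random_sentence(rng, n_tokens, 10)
            S = emissions_of(model, feats)
            expected = [IO_LABELS[i] for i in enum_argmax(S, model.transition_weights)]
            assert viterbi_decode(model, feats) == expected

    def test_dominant_dictionary_feature_forces_person(self):
        model = make_model(2)
        model.feature_index = {"dict=person-first@+0": 0, "f1": 1}
        model.state_weights[0, 0] = 50.0  # Iperson <- dict:person-first
        labels = viterbi_decode(model, [["dict=person-first@+0"], ["f1"]])
        assert labels[0] == "Iperson"

    def test_unknown_features_ignored(self):
        model = make_model(2, seed=1)
        assert viterbi_decode(model, [["nope", "f0"]]) == viterbi_decode(
            model, [["f0"]]
        )

    def test_operation_count_scales_linearly_in_length(self):
        model = make_model(2)
        _, ops8 = viterbi_decode(model, [["f0"]] * 8, return_ops=True)
        _, ops4 = viterbi_decode(model, [["f0"]] * 4, return_ops=True)
        assert ops8 == 7 * L * L and ops4 == 3 * L * L
        assert (ops8 - ops4) == 4 * L * L  # linear in T, quadratic in L


class TestFeatures:
    def sent(self, words, section=None):
        toks, pos = [], 0
        for w in words:
            toks.append(Token(w, pos, pos + len(w), pos="NNP"))
            pos += len(w) + 1
        return Sentence("d", 0, toks, section=section)

    def test_pattern_and_affix_features(self):
        feats = extract_features(self.sent(["Dr."]), config=FeatureConfig())
        own = {f for f in feats[0] if f.endswith("@+0")}
        assert "pat=init-cap@+0" in own
        assert "pat=has-period@+0" in own
        assert "suf2=r.@+0" in own

    def test_dictionary_feature_fires(self):
        lex = Lexicons.from_iterables(["john"], ["doe"], [], [])
        feats = extract_features(self.sent(["John", "Doe"]), lexicons=lex)
        assert "dict=person-first@+0" in feats[0]
        assert "dict=person-last@+0" in feats[1]
        assert "dict=person-last@+1" in feats[0]  # context window

    def test_boundary_markers_instead_of_padding(self):
        feats = extract_features(self.sent(["one", "two"]))
        assert "BOS@-1" in feats[0] and "BOS@-2" in feats[0]
        assert "EOS@+1" in feats[1] and "EOS@+2" in feats[1]
        assert not any(f.endswith("@-1") and not f.startswith("BOS")
                       for f in feats[0])

    def test_section_feature(self):
        feats = extract_features(self.sent(["x"], section="headline"))
        assert "sec=headline@+0" in feats[0]

    def test_config_requires_some_family(self):
        with pytest.raises(ValueError):
            FeatureConfig(dictionary=False, distributional=False, section=False,
                          pos=False, lexical=False)


class TestThesaurus:
    def test_identical_contexts_have_similarity_one(self):
        sents = [["the", "red", "apple", "is", "ripe"],
                 ["the", "red", "pear", "is", "ripe"]] * 2
        th = build_thesaurus(sents, window=2, top_k=3, min_count=2)
        nbrs = dict(th.get("apple"))
        assert nbrs["pear"] == pytest.approx(1.0)

    def test_below_frequency_floor_absent(self):
        sents = [["alpha", "beta"], ["alpha", "gamma"]]
        th = build_thesaurus(sents, min_count=2)
        assert th.get("beta") == ()
        assert "alpha" in th.neighbors

    def test_disjoint_contexts_have_similarity_zero(self):
        sents = [["aa", "bb"], ["aa", "bb"], ["cc", "dd"], ["cc", "dd"]]
        th = build_thesaurus(sents, window=1, top_k=5, min_count=2)
        assert dict(th.get("aa"))["cc"] == pytest.approx(0.0)

    def test_term_is_not_own_neighbor_and_scores_sorted(self, synth_small):
        sents = [[t.text for t in s.tokens] for s in synth_small.train_sentences]
        th = build_thesaurus(sents, min_count=3)
        for term, nbrs in th.neighbors.items():
            assert term not in [n for n, _ in nbrs]
            scores = [s for _, s in nbrs]
            assert scores == sorted(scores, reverse=True)


class TestMentionAssembly:
    def sent(self, words):
        toks, pos = [], 0
        for w in words:
            toks.append(Token(w, pos, pos + len(w)))
            pos += len(w) + 1
        return Sentence("d", 0, toks)

    def test_run_becomes_single_mention(self):
        s = self.sent(["said", "John", "Doe", "today"])
        [m] = labels_to_mentions(s, ["O", "Iperson", "Iperson", "O"])
        assert (m.type, m.char_start, m.char_end) == ("person", 5, 13)

    def test_adjacent_different_types_split(self):
        s = self.sent(["John", "Mayo"])
        ms = labels_to_mentions(s, ["Iperson", "Iorg"])
        assert [m.type for m in ms] == ["person", "organization"]

    def test_all_outside_yields_nothing(self):
        s = self.sent(["a", "b", "c"])
        assert labels_to_mentions(s, ["O", "O", "O"]) == []

    def test_abutting_same_type_entities_merge(self):
        # a known property of the IO scheme: no boundary label exists
        s = self.sent(["John", "Doe", "Jane", "Roe"])
        ms = labels_to_mentions(s, ["Iperson"] * 4)
        assert len(ms) == 1


class TestTraining:
    def test_objective_decreases_and_model_round_trips(self, synth_small, tmp_path):
        model, stats = train_crf(
            synth_small.train_sentences[:40],
            lexicons=synth_small.lexicons,
            max_iter=30,
        )
        hist = stats.objective_history
        assert len(hist) >= 2
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))
        fp = tmp_path / "m.crf"
        model.save(fp)
        loaded = CrfModel.load(fp)
        assert loaded.feature_index == model.feature_index
        assert np.array_equal(loaded.state_weights, model.state_weights)
        assert np.array_equal(loaded.transition_weights, model.transition_weights)

    def test_empty_corpus_rejected(self):
        from kolminer.ner_crf import TrainingError

        with pytest.raises(TrainingError):
            train_crf([])
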