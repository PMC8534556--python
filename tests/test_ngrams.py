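import math

import numpy as np
import pytest

from _oracles import KNReference, positional_entropy_bruteforce
from infocurve.corpus import corpus_from_sentences, split_folds
from infocurve.ngrams import (
    BOS,
    EOS,
    UNK,
    conditional_probability,
    count_ngrams,
    crossval_surprisals,
    fit_kneser_ney,
    positional_entropy,
    read_arpa,
    sentence_log2prob,
    sentence_surprisals,
    write_arpa,
)
from conftest import random_toy_corpus


class TestCounting:
    def test_unigram_tally_counts_eos_not_bos(self):
        c = corpus_from_sentences([["a", "b"], ["a", "c"]])
        counts = count_ngrams(c, 1)
        assert counts.counts == {("a",): 2, ("b",): 1, ("c",): 1, (EOS,): 2}

    def test_trigram_single_bos_padding(self):
        # one begin token per sentence: "a b" -> <s> a b </s>
        c = corpus_from_sentences([["a", "b"]])
        counts = count_ngrams(c, 3)
        assert counts.raw[3] == {(BOS, "a", "b"): 1, ("a", "b", EOS): 1}
        assert counts.raw[2] == {(BOS, "a"): 1, ("a", "b"): 1, ("b", EOS): 1}
        assert counts.raw[1] == {("a",): 1, ("b",): 1, (EOS,): 1}

    def test_no_ngram_crosses_sentence_boundary(self):
        c = corpus_from_sentences([["a", "b"], ["c", "d"]])
        counts = count_ngrams(c, 2)
        assert ("b", "c") not in counts.raw[2]

    def test_real_token_conservation(self, rng):
        c = random_toy_corpus(rng, n_sentences=100)
        counts = count_ngrams(c, 1)
        assert counts.total_tokens == c.n_tokens

    def test_continuation_counts_bounded_by_types(self, tiny_corpus):
        counts = count_ngrams(tiny_corpus, 2)
        n_types = len({g[0] for g in counts.raw[1]})
        assert all(v <= n_types for v in counts.continuation_counts.values())


class TestKneserNey:
    def test_frozen_hand_derived_trigram_probability(self):
        # 3-type corpus repeated 50x; value worked by hand from the
        # modified-KN equations with the 0.75 fallback discount:
        # (50-0.75)/50 + (0.75/50) * [(1-0.75)/1 + 0.75 * ((1-0.75)/4 + 0.75*1/5)]
        c = corpus_from_sentences([["spaghetti", "and", "meatballs"]] * 50)
        m = fit_kneser_ney(count_ngrams(c, 3))
        assert m.prob("meatballs", ("spaghetti", "and")) == pytest.approx(
            0.991140625, abs=1e-12
        )

    def test_continuation_weighting_penalizes_single_context_words(self):
        # "francisco": 20 tokens, always after "san" (1 left context);
        # "the": 20 tokens after 20 distinct words -> higher unigram weight
        sents = [["san", "francisco"]] * 20 + [[f"u{i}", "the"] for i in range(20)]
        m = fit_kneser_ney(count_ngrams(corpus_from_sentences(sents), 2))
        novel_ctx = ("qqq",)  # unseen context backs off to the unigram level
        assert m.prob("francisco", novel_ctx) < m.prob("the", novel_ctx)

    def test_distributions_normalize_over_vocabulary(self, rng):
        for _ in range(4):
            c = random_toy_corpus(rng)
            m = fit_kneser_ney(count_ngrams(c, 3))
            contexts = [(), ("w0",), ("w1", "w0"), (BOS, "w0"), ("zzz", "qqq")]
            for ctx in contexts:
                total = math.fsum(m.prob(w, ctx) for w in m.vocabulary)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_probabilities_strictly_positive(self, rng):
        c = random_toy_corpus(rng)
        m = fit_kneser_ney(count_ngrams(c, 3))
        assert m.prob("never-seen-word", ("also", "unseen")) > 0
        assert m.prob(UNK, ()) > 0

    def test_empty_counts_rejected(self):
        c = corpus_from_sentences([["a"]])
        counts = count_ngrams(c, 1)
        counts.raw[1].clear()
        with pytest.raises(ValueError):
            fit_kneser_ney(counts)


class TestConditionalProbability:
    def test_unigram_model_ignores_context(self, tiny_corpus):
        m = fit_kneser_ney(count_ngrams(tiny_corpus, 1))
        assert m.prob("a", ()) == m.prob("a")

    def test_oov_word_maps_to_unk(self, tiny_corpus):
        m = fit_kneser_ney(count_ngrams(tiny_corpus, 3))
        ctx = ("a", "b")
        assert conditional_probability(m, "xyzzy", ctx) == conditional_probability(
            m, UNK, ctx
        )

    def test_context_longer_than_order_rejected(self, tiny_corpus):
        m = fit_kneser_ney(count_ngrams(tiny_corpus, 2))
        with pytest.raises(ValueError):
            m.prob("a", ("b", "c"))

    def test_short_context_padded_with_bos(self, tiny_corpus):
        m = fit_kneser_ney(count_ngrams(tiny_corpus, 3))
        assert m.prob("a", ("b",)) == m.prob("a", (BOS, "b"))


class TestSentenceSurprisals:
    def test_one_value_per_word_and_nonnegative(self, tiny_corpus):
        m = fit_kneser_ney(count_ngrams(tiny_corpus, 3))
        s = sentence_surprisals(m, ("b", "a", "c"))
        assert len(s) == 3 and all(v >= 0 for v in s)

    def test_bits_are_negative_log2_of_probability(self, tiny_corpus):
        m = fit_kneser_ney(count_ngrams(tiny_corpus, 3))
        sent = ("a", "b")
        surps = sentence_surprisals(m, sent)
        assert surps[0] == pytest.approx(-math.log2(m.prob("a", (BOS, BOS))))
        assert surps[1] == pytest.approx(-math.log2(m.prob("b", (BOS, "a"))))

    def test_chain_rule_including_eos(self, rng):
        # sum of per-word surprisals + the end-token term = -log2 P(sentence),
        # recomputed here as an explicit product of conditionals
        c = random_toy_corpus(rng, n_sentences=30)
        m = fit_kneser_ney(count_ngrams(c, 3))
        sent = c.sentences[0]
        padded = (BOS, BOS) + tuple(sent) + (EOS,)
        direct = 0.0
        for i in range(2, len(padded)):
            direct += math.log2(m.prob(padded[i], padded[i - 2 : i]))
        total = -math.fsum(sentence_surprisals(m, sent)) + math.log2(
            m.prob(EOS, padded[-3:-1])
        )
        assert total == pytest.approx(direct, abs=1e-9)
        assert sentence_log2prob(m, sent) == pytest.approx(direct, abs=1e-9)

    def test_empty_sentence_rejected(self, tiny_corpus):
        m = fit_kneser_ney(count_ngrams(tiny_corpus, 2))
        with pytest.raises(ValueError):
            sentence_surprisals(m, ())


class TestCrossValidation:
    def test_record_count_equals_token_count(self, rng):
        c = random_toy_corpus(rng, n_sentences=40)
        table = crossval_surprisals(c, 1, split_folds(c, 5))
        assert len(table) == c.n_tokens
        assert (table["surprisal"] >= 0).all()
        assert (table["position"] >= 1).all()
        assert (table["position"] <= table["sentence_length"]).all()

    def test_heldout_only_type_scored_as_unk(self):
        sents = [["a", "b"]] * 5 + [["a", "rareword"]] * 5
        c = corpus_from_sentences(sents)
        folds = split_folds(c, 2)  # second fold holds all "rareword" tokens
        table = crossval_surprisals(c, 3, folds)
        rare = table[table["token"] == "rareword"]
        assert len(rare) == 5
        train = corpus_from_sentences(sents[:5])
        m = fit_kneser_ney(count_ngrams(train, 3))
        expect = -math.log2(m.prob(UNK, (BOS, "a")))
        assert rare["surprisal"].to_numpy() == pytest.approx(expect)
        assert np.isfinite(rare["surprisal"]).all()

    def test_two_fold_matches_manual_two_model_computation(self):
        c = corpus_from_sentences([["a", "b", "c"], ["a", "c", "b"]])
        table = crossval_surprisals(c, 3, split_folds(c, 2))
        for idx, other in ((0, 1), (1, 0)):
            train = corpus_from_sentences([c.sentences[other]])
            m = fit_kneser_ney(count_ngrams(train, 3))
            manual = sentence_surprisals(m, c.sentences[idx])
            got = table[table["sentence_index"] == idx].sort_values("position")
            assert got["surprisal"].to_list() == pytest.approx(manual)

    def test_fold_mismatch_and_small_folds_rejected(self, tiny_corpus):
        folds = split_folds(tiny_corpus, 3)
        bigger = corpus_from_sentences([["a"]] * 5)
        with pytest.raises(ValueError):
            crossval_surprisals(bigger, 1, folds)


class TestPositionalEntropy:
    class _StubModel:
        def __init__(self, probs):
            self.probs = probs

        def prob(self, w, context=()):
            return self.probs[w]

    def test_constant_word_with_probability_half_gives_one_bit(self):
        c = corpus_from_sentences([["x", "y"], ["x", "z"]])
        stub = self._StubModel({"x": 0.5})
        assert positional_entropy(c, stub, position=1, sentence_length=2) == pytest.approx(1.0)

    def test_mixed_position_with_quarter_probability_words_gives_two_bits(self):
        c = corpus_from_sentences([["p", "q"], ["q", "p"], ["r", "s"]])
        stub = self._StubModel({w: 0.25 for w in "pqrs"})
        assert positional_entropy(c, stub, position=1, sentence_length=2) == pytest.approx(2.0)

    def test_matches_bruteforce_sum(self, rng):
        c = random_toy_corpus(rng, n_sentences=60, max_len=6)
        m = fit_kneser_ney(count_ngrams(c, 1))
        for L, pos in ((4, 2), (6, 6), (None, 1)):
            try:
                got = positional_entropy(c, m, position=pos, sentence_length=L)
            except ValueError:
                continue
            want = positional_entropy_bruteforce(
                c.sentences, lambda w: m.prob(w), pos, L
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_errors(self, tiny_corpus):
        m = fit_kneser_ney(count_ngrams(tiny_corpus, 1))
        with pytest.raises(ValueError):
            positional_entropy(tiny_corpus, m, position=3, sentence_length=2)
        with pytest.raises(ValueError):
            positional_entropy(tiny_corpus, m, position=1, sentence_length=9)


class TestArpaSerialization:
    def test_round_trip_preserves_probabilities(self, rng, tmp_path):
        c = random_toy_corpus(rng, n_sentences=40)
        m = fit_kneser_ney(count_ngrams(c, 3))
        path = tmp_path / "model.arpa"
        write_arpa(m, path)
        back = read_arpa(path)
        assert back.order == 3
        queries = [
            ("w0", ()),
            ("w1", ("w0",)),
            ("w2", ("w0", "w1")),
            (EOS, ("w0", "w1")),
            ("unseen-token", ("w3", "w0")),
            ("w0", (BOS, "w1")),
        ]
        for word, ctx in queries:
            assert back.prob(word, ctx) == pytest.approx(m.prob(word, ctx), rel=1e-5)

    def test_matches_reference_after_round_trip(self, rng, tmp_path):
        c = random_toy_corpus(rng, n_sentences=25)
        m = fit_kneser_ney(count_ngrams(c, 2))
        path = tmp_path / "model2.arpa"
        write_arpa(m, path)
        back = read_arpa(path)
        ref = KNReference(c.sentences, 2)
        for s in c.sentences[:5]:
            mine = [-math.log2(back.prob(w, ctx)) for w, ctx in _bigram_queries(s)]
            want = ref.sentence_surprisals(s)
            assert mine == pytest.approx(want, abs=1e-5)


def _bigram_queries(sentence):
    padded = (BOS,) + tuple(sentence)
    return [(padded[i], (padded[i - 1],)) for i in range(1, len(padded))]
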