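"""N-gram language models with modified Kneser-Ney smoothing and per-word surprisal.

The models here are interpolated modified Kneser-Ney estimators in the Chen &
Goodman formulation: three count-class discounts (D1, D2, D3+) per order are
estimated from counts-of-counts, and lower orders are estimated from
continuation counts (the number of distinct left contexts an n-gram extends)
rather than raw frequencies, so that a word like "francisco" that is frequent
but occurs only after "san" receives little unigram weight.

Conventions (shared with the standard n-gram toolkits):

* Each sentence is padded with a single begin token ``<s>`` and a single end
  token ``</s>``; n-grams never cross sentence boundaries.
* Counts for every order 1..n are collected from the padded sentence. The
  begin token is never counted (or predicted) as a unigram.
* N-grams that start with ``<s>`` keep their raw counts at lower orders, since
  nothing can precede the begin token.
* Scoring the first word of a sentence uses a context of begin tokens; the
  all-``<s>`` trigram context is unobserved, so the probability backs off to
  the observed (``<s>``, w1) bigram.
* The open-vocabulary token ``<unk>`` receives the fully interpolated base
  mass, so held-out out-of-vocabulary words always have finite surprisal.
* Surprisal is measured in bits: ``-log2 P``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus import FoldAssignment, TokenizedCorpus

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"

#: fixed discount used when the Chen-Goodman count-of-count formulas are
#: undefined (tiny corpora with degenerate count diversity)
FALLBACK_DISCOUNT = 0.75

__all__ = [
    "BOS",
    "EOS",
    "UNK",
    "NgramCounts",
    "NgramModel",
    "count_ngrams",
    "fit_kneser_ney",
    "conditional_probability",
    "sentence_surprisals",
    "sentence_log2prob",
    "crossval_surprisals",
    "positional_entropy",
    "write_arpa",
    "read_arpa",
    "save_surprisal_table",
    "load_surprisal_table",
]


@dataclass
class NgramCounts:
    """Raw n-gram tallies for orders 1..order from one corpus.

    ``raw[k]`` maps each observed k-gram (token tuple) to its frequency.
    ``counts`` exposes the top-order tallies; ``continuation_counts`` the
    number of distinct left-extending types per (order-1)-gram.
    """

    order: int
    raw: dict[int, dict[tuple[str, ...], int]]
    vocabulary: frozenset[str]  # predicted types: word types + EOS + UNK (no BOS)

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return self.raw[self.order]

    @property
    def continuation_counts(self) -> dict[tuple[str, ...], int]:
        if self.order < 2:
            return {}
        cont: Counter[tuple[str, ...]] = Counter()
        for gram in self.raw[self.order]:
            cont[gram[1:]] += 1
        return dict(cont)

    @property
    def total_tokens(self) -> int:
        """Total count of real word tokens (excluding padding)."""
        return sum(c for g, c in self.raw[1].items() if g[0] != EOS)


def count_ngrams(corpus: TokenizedCorpus, order: int) -> NgramCounts:
    """Tally all k-grams (k = 1..order) from begin/end-padded sentences.

    For ``order >= 2`` each sentence is padded with one ``<s>`` and one
    ``</s>``; for ``order == 1`` only ``</s>`` is appended. The begin token is
    never counted as a unigram. No n-gram spans two sentences.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    raw: dict[int, dict[tuple[str, ...], int]] = {k: {} for k in range(1, order + 1)}
    for sent in corpus.sentences:
        padded = ((BOS,) if order >= 2 else ()) + tuple(sent) + (EOS,)
        n = len(padded)
        for k in range(1, order + 1):
            tally = raw[k]
            for i in range(n - k + 1):
                gram = padded[i : i + k]
                if k == 1 and gram[0] == BOS:
                    continue
                tally[gram] = tally.get(gram, 0) + 1
    vocab = frozenset(g[0] for g in raw[1]) | {EOS, UNK}
    return NgramCounts(order=order, raw=raw, vocabulary=vocab)


def _estimate_discounts(values: Iterable[int]) -> tuple[float, float, float]:
    """Chen-Goodman modified discounts (D1, D2, D3+) from counts-of-counts.

    Falls back to a fixed 0.75 for all three classes when the closed-form
    estimates are undefined or out of their valid ranges.
    """
    n = Counter()
    for v in values:
        if 1 <= v <= 4:
            n[v] += 1
    n1, n2, n3, n4 = n[1], n[2], n[3], n[4]
    if min(n1, n2, n3, n4) == 0:
        return (FALLBACK_DISCOUNT,) * 3
    y = n1 / (n1 + 2.0 * n2)
    d1 = 1.0 - 2.0 * y * n2 / n1
    d2 = 2.0 - 3.0 * y * n3 / n2
    d3 = 3.0 - 4.0 * y * n4 / n3
    if not (0.0 < d1 <= 1.0 and 0.0 < d2 <= 2.0 and 0.0 < d3 <= 3.0):
        return (FALLBACK_DISCOUNT,) * 3
    return (d1, d2, d3)


@dataclass
class NgramModel:
    """Interpolated modified Kneser-Ney model of a given order.

    ``prob(word, context)`` returns a strictly positive probability; for every
    observed context the probabilities over the prediction vocabulary (word
    types + ``</s>`` + ``<unk>``) sum to one. ``log_base`` is fixed at 2.
    """

    order: int
    vocabulary: frozenset[str]
    discounts: dict[int, tuple[float, float, float]]
    log_base: int = 2
    # per order k: adjusted counts, per-context totals and discount-class type
    # tallies (N1, N2, N3+); internal estimation state
    _adjusted: dict[int, dict[tuple[str, ...], int]] = field(repr=False, default_factory=dict)
    _ctx_total: dict[int, dict[tuple[str, ...], int]] = field(repr=False, default_factory=dict)
    _ctx_classes: dict[int, dict[tuple[str, ...], tuple[int, int, int]]] = field(
        repr=False, default_factory=dict
    )

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)

    def map_token(self, token: str) -> str:
        if token == BOS or token in self.vocabulary:
            return token
        return UNK

    def _interp_prob(self, k: int, context: tuple[str, ...], word: str) -> float:
        if k == 0:
            return 1.0 / self.vocab_size
        total = self._ctx_total[k].get(context)
        if not total:
            return self._interp_prob(k - 1, context[1:], word)
        c = self._adjusted[k].get(context + (word,), 0)
        d1, d2, d3 = self.discounts[k]
        n1, n2, n3p = self._ctx_classes[k][context]
        gamma = (d1 * n1 + d2 * n2 + d3 * n3p) / total
        disc = 0.0 if c == 0 else (d1 if c == 1 else d2 if c == 2 else d3)
        return max(c - disc, 0.0) / total + gamma * self._interp_prob(k - 1, context[1:], word)

    def prob(self, word: str, context: Sequence[str] = ()) -> float:
        """P(word | context); context shorter than order-1 is left-padded with <s>."""
        context = tuple(context)
        if len(context) > self.order - 1:
            raise ValueError(
                f"context of length {len(context)} too long for order-{self.order} model"
            )
        if len(context) < self.order - 1:
            context = (BOS,) * (self.order - 1 - len(context)) + context
        word = self.map_token(word)
        context = tuple(self.map_token(t) for t in context)
        return self._interp_prob(self.order, context, word)

    def surprisal(self, word: str, context: Sequence[str] = ()) -> float:
        """-log2 P(word | context), in bits."""
        return -math.log2(self.prob(word, context))

    def unigram_surprisal_table(self) -> dict[str, float]:
        """Precomputed -log2 P(w) for every vocabulary type (fast scoring path)."""
        empty = (BOS,) * (self.order - 1)
        return {
            w: -math.log2(self._interp_prob(self.order, empty, w))
            for w in self.vocabulary
        }

    def observed_contexts(self, k: int | None = None) -> list[tuple[str, ...]]:
        k = self.order if k is None else k
        return list(self._ctx_total[k])


def fit_kneser_ney(counts: NgramCounts) -> NgramModel:
    """Fit an interpolated modified Kneser-Ney model from n-gram tallies.

    Top-order n-grams keep raw counts; each lower order uses continuation
    counts (distinct left-extending types), except n-grams that start with the
    begin token, which keep raw counts because nothing can precede ``<s>``.
    Discounts are estimated per order from the counts-of-counts of the counts
    actually used at that order.
    """
    if not counts.raw[counts.order]:
        raise ValueError("cannot fit a model from empty counts")
    order = counts.order
    adjusted: dict[int, dict[tuple[str, ...], int]] = {order: dict(counts.raw[order])}
    for k in range(order - 1, 0, -1):
        cont: dict[tuple[str, ...], int] = {}
        for gram in counts.raw[k + 1]:
            suffix = gram[1:]
            if suffix[0] == BOS:
                continue
            cont[suffix] = cont.get(suffix, 0) + 1
        # begin-of-sentence n-grams are never continuations; keep raw counts
        for gram, c in counts.raw[k].items():
            if gram[0] == BOS:
                cont[gram] = c
        adjusted[k] = cont

    discounts = {k: _estimate_discounts(adjusted[k].values()) for k in adjusted}

    ctx_total: dict[int, dict[tuple[str, ...], int]] = {}
    ctx_classes: dict[int, dict[tuple[str, ...], tuple[int, int, int]]] = {}
    for k, table in adjusted.items():
        totals: dict[tuple[str, ...], int] = {}
        classes: dict[tuple[str, ...], list[int]] = {}
        for gram, c in table.items():
            ctx = gram[:-1]
            totals[ctx] = totals.get(ctx, 0) + c
            cls = classes.setdefault(ctx, [0, 0, 0])
            if c == 1:
                cls[0] += 1
            elif c == 2:
                cls[1] += 1
            elif c >= 3:
                cls[2] += 1
        ctx_total[k] = totals
        ctx_classes[k] = {ctx: tuple(v) for ctx, v in classes.items()}

    return NgramModel(
        order=order,
        vocabulary=counts.vocabulary,
        discounts=discounts,
        _adjusted=adjusted,
        _ctx_total=ctx_total,
        _ctx_classes=ctx_classes,
    )


def conditional_probability(
    model: NgramModel, word: str, context: Sequence[str] = ()
) -> float:
    """P(word | context) under the model; see :meth:`NgramModel.prob`."""
    return model.prob(word, context)


def sentence_surprisals(model: NgramModel, sentence: Sequence[str]) -> list[float]:
    """Per-word surprisal (bits) for positions 1..len(sentence).

    Position i is scored with the preceding order-1 tokens as context, using
    begin-token padding for the first words. The end token is never scored.
    """
    if not sentence:
        raise ValueError("cannot score an empty sentence")
    ctx_len = model.order - 1
    padded = (BOS,) * ctx_len + tuple(sentence)
    return [
        model.surprisal(padded[i], padded[i - ctx_len : i])
        for i in range(ctx_len, len(padded))
    ]


def sentence_log2prob(model: NgramModel, sentence: Sequence[str]) -> float:
    """log2 of the full sentence probability, including the end token."""
    ctx_len = model.order - 1
    padded = (BOS,) * ctx_len + tuple(sentence) + (EOS,)
    return sum(
        math.log2(model.prob(padded[i], padded[i - ctx_len : i]))
        for i in range(ctx_len, len(padded))
    )


def crossval_surprisals(
    corpus: TokenizedCorpus, order: int, folds: FoldAssignment
) -> pd.DataFrame:
    """Cross-validated per-word surprisal: each sentence is scored by a model
    fit on every other fold.

    Returns a tidy table with one record per real word token, with columns
    ``sentence_index, position, token, surprisal, fold, sentence_length``.
    Word types confined to the held-out fold are scored through ``<unk>`` and
    therefore receive positive finite surprisal.
    """
    if folds.n_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(folds.fold_of_sentence) != len(corpus.sentences):
        raise ValueError("fold assignment does not match corpus size")
    sizes = folds.fold_sizes()
    if any(s == 0 for s in sizes):
        raise ValueError(f"every fold must be nonempty; sizes {sizes}")

    records: list[tuple[int, int, str, float, int, int]] = []
    for fold in range(folds.n_folds):
        train_sents = tuple(
            s for i, s in enumerate(corpus.sentences) if folds.fold_of_sentence[i] != fold
        )
        train = TokenizedCorpus(
            language_id=corpus.language_id, sentences=train_sents, register=corpus.register
        )
        model = fit_kneser_ney(count_ngrams(train, order))
        uni_table = model.unigram_surprisal_table() if order == 1 else None
        for idx in folds.indices_in_fold(fold):
            sent = corpus.sentences[idx]
            if uni_table is not None:
                unk_s = uni_table[UNK]
                surps = [uni_table.get(w, unk_s) for w in sent]
            else:
                surps = sentence_surprisals(model, sent)
            n = len(sent)
            records.extend(
                (idx, p + 1, sent[p], surps[p], fold, n) for p in range(n)
            )
    df = pd.DataFrame.from_records(
        records,
        columns=["sentence_index", "position", "token", "surprisal", "fold", "sentence_length"],
    )
    return df.sort_values(["sentence_index", "position"], ignore_index=True)


def positional_entropy(
    corpus: TokenizedCorpus,
    unigram_model: NgramModel,
    position: int,
    sentence_length: int | None = None,
) -> float:
    """Frequency-weighted average unigram surprisal of words at one position.

    H(X) = -sum_w P(w in X) log2 P(w), where X is the word position
    (1-based), P(w in X) is the relative frequency of w among tokens at that
    position, and P(w) is the corpus-wide unigram probability under
    ``unigram_model``. With ``sentence_length`` given, only sentences of
    exactly that length contribute; otherwise all sentences with at least
    ``position`` words do.
    """
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    if sentence_length is not None and position > sentence_length:
        raise ValueError(f"position {position} exceeds sentence_length {sentence_length}")
    if sentence_length is None:
        pool = [s for s in corpus.sentences if len(s) >= position]
    else:
        pool = [s for s in corpus.sentences if len(s) == sentence_length]
    if not pool:
        raise ValueError("no sentences match the requested length/position")
    freqs = Counter(s[position - 1] for s in pool)
    n = len(pool)
    return sum(
        (c / n) * -math.log2(unigram_model.prob(w)) for w, c in freqs.items()
    )


# ---------------------------------------------------------------------------
# ARPA serialization


def _log10(p: float) -> float:
    return math.log10(p)


def write_arpa(model: NgramModel, path: str | Path) -> None:
    """Serialize the model in the standard ARPA n-gram format.

    Probabilities are the interpolated estimates; backoff weights are the
    per-context leftover mass, so backoff querying of the file reproduces the
    interpolated model exactly. The begin token gets the conventional dummy
    log-probability of -99.
    """
    order = model.order
    sections: dict[int, list[str]] = {}
    ngram_counts: dict[int, int] = {}

    def gamma(k: int, ctx: tuple[str, ...]) -> float | None:
        total = model._ctx_total[k].get(ctx)
        if not total:
            return None
        d1, d2, d3 = model.discounts[k]
        n1, n2, n3p = model._ctx_classes[k][ctx]
        return (d1 * n1 + d2 * n2 + d3 * n3p) / total

    # unigrams cover the whole prediction vocabulary plus <s>
    lines = []
    uni_types = sorted(model.vocabulary)
    for w in uni_types:
        p = model._interp_prob(1, (), w)
        entry = f"{_log10(p):.7f}\t{w}"
        if order >= 2:
            g = gamma(2, (w,))
            if g is not None:
                entry += f"\t{_log10(g):.7f}"
        lines.append(entry)
    if order >= 2:
        g = gamma(2, (BOS,))
        bo = f"\t{_log10(g):.7f}" if g is not None else ""
        lines.append(f"-99\t{BOS}{bo}")
    sections[1] = lines
    ngram_counts[1] = len(lines)

    for k in range(2, order + 1):
        lines = []
        for gram in sorted(model._adjusted[k]):
            p = model._interp_prob(k, gram[:-1], gram[-1])
            entry = f"{_log10(p):.7f}\t{' '.join(gram)}"
            if k < order:
                g = gamma(k + 1, gram)
                if g is not None:
                    entry += f"\t{_log10(g):.7f}"
            lines.append(entry)
        sections[k] = lines
        ngram_counts[k] = len(lines)

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        for k in range(1, order + 1):
            fh.write(f"ngram {k}={ngram_counts[k]}\n")
        for k in range(1, order + 1):
            fh.write(f"\n\\{k}-grams:\n")
            fh.write("\n".join(sections[k]))
            fh.write("\n")
        fh.write("\n\\end\\\n")


@dataclass
class ArpaModel:
    """Query-only backoff model reconstructed from an ARPA file.

    ``prob(word, context)`` follows standard backoff semantics: use the
    longest stored n-gram; otherwise multiply the context's backoff weight by
    the lower-order probability.
    """

    order: int
    logprob: dict[tuple[str, ...], float]
    backoff: dict[tuple[str, ...], float]
    vocabulary: frozenset[str]

    def map_token(self, token: str) -> str:
        if token == BOS or token in self.vocabulary:
            return token
        return UNK

    def _p(self, context: tuple[str, ...], word: str) -> float:
        gram = context + (word,)
        lp = self.logprob.get(gram)
        if lp is not None:
            return 10.0 ** lp
        if not context:
            raise KeyError(f"unigram {word!r} missing from ARPA file")
        bo = self.backoff.get(context, 0.0)
        return (10.0 ** bo) * self._p(context[1:], word)

    def prob(self, word: str, context: Sequence[str] = ()) -> float:
        context = tuple(context)
        if len(context) > self.order - 1:
            raise ValueError("context too long for model order")
        if len(context) < self.order - 1:
            context = (BOS,) * (self.order - 1 - len(context)) + context
        word = self.map_token(word)
        context = tuple(self.map_token(t) for t in context)
        # drop leading context words until a stored context is reachable
        while context and context not in self.backoff and context + (word,) not in self.logprob:
            context = context[1:]
        return self._p(context, word)

    def surprisal(self, word: str, context: Sequence[str] = ()) -> float:
        return -math.log2(self.prob(word, context))


def read_arpa(path: str | Path) -> ArpaModel:
    """Parse an ARPA n-gram file into a query-only backoff model."""
    logprob: dict[tuple[str, ...], float] = {}
    backoff: dict[tuple[str, ...], float] = {}
    order = 0
    section = 0
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("\\data\\") or line.startswith("ngram "):
                continue
            if line.startswith("\\end\\"):
                break
            if line.startswith("\\") and line.endswith("-grams:"):
                section = int(line[1:].split("-")[0])
                order = max(order, section)
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
                parts = [parts[0], " ".join(parts[1:section + 1])] + parts[section + 1 :]
            gram = tuple(parts[1].split())
            logprob[gram] = float(parts[0])
            if len(parts) > 2 and parts[2] != "":
                backoff[gram] = float(parts[2])
    vocab = frozenset(g[0] for g in logprob if len(g) == 1 and g[0] != BOS)
    return ArpaModel(order=order, logprob=logprob, backoff=backoff, vocabulary=vocab)


def save_surprisal_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_surprisal_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
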