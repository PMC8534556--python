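"""Reading, normalizing, filtering, and fold-splitting one-sentence-per-line corpora.

The expected input format is flattened text: UTF-8, one sentence per line,
tokens separated by whitespace. Tokenization decisions (sentence segmentation,
compound handling, punctuation) are assumed to have happened upstream; this
module only casefolds and splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "TokenizedCorpus",
    "LengthFilter",
    "FoldAssignment",
    "load_corpus",
    "corpus_from_sentences",
    "filter_by_length",
    "split_folds",
    "save_jsonl",
    "load_jsonl",
]


class EmptyCorpusError(ValueError):
    """Raised when a corpus source contains no non-empty lines."""


@dataclass(frozen=True)
class TokenizedCorpus:
    """An ordered collection of tokenized sentences for one language/register.

    Tokens are casefolded strings with no internal whitespace. Sentence order
    is preserved from the source file. ``register`` is metadata only and has
    no effect on any computation.
    """

    language_id: str
    sentences: tuple[tuple[str, ...], ...]
    register: str = "written"

    def __post_init__(self) -> None:
        if self.register not in ("written", "spoken"):
            raise ValueError(f"register must be 'written' or 'spoken', got {self.register!r}")
        for s in self.sentences:
            if len(s) == 0:
                raise ValueError("every sentence must have at least one token")

    def __len__(self) -> int:
        return len(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def lengths(self) -> list[int]:
        return [len(s) for s in self.sentences]


@dataclass(frozen=True)
class LengthFilter:
    """Inclusive sentence-length bounds, in words.

    Defaults follow the written-corpus convention (5-45 words); spoken corpora
    conventionally use (5, 15).
    """

    min_len: int = 5
    max_len: int = 45

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(f"need 1 <= min_len <= max_len, got ({self.min_len}, {self.max_len})")

    def admits(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


@dataclass(frozen=True)
class FoldAssignment:
    """Assignment of every sentence index to exactly one of ``n_folds`` folds."""

    n_folds: int
    fold_of_sentence: tuple[int, ...]

    def indices_in_fold(self, fold: int) -> list[int]:
        return [i for i, f in enumerate(self.fold_of_sentence) if f == fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.fold_of_sentence:
            sizes[f] += 1
        return sizes


def _tokenize_line(line: str, pre_hook: Callable[[str], str] | None = None) -> tuple[str, ...]:
    if pre_hook is not None:
        line = pre_hook(line)
    return tuple(tok.casefold() for tok in line.split())


def corpus_from_sentences(
    sentences: Iterable[Sequence[str]],
    language_id: str = "und",
    register: str = "written",
) -> TokenizedCorpus:
    """Build a corpus from already-tokenized sentences (casefolding each token)."""
    sents = tuple(tuple(t.casefold() for t in s) for s in sentences)
    if not sents:
        raise EmptyCorpusError(f"no sentences provided for language {language_id!r}")
    return TokenizedCorpus(language_id=language_id, sentences=sents, register=register)


def load_corpus(
    path: str | Path,
    language_id: str,
    register: str = "written",
    pre_tokenize_hook: Callable[[str], str] | None = None,
) -> TokenizedCorpus:
    """Read a one-sentence-per-line UTF-8 text file into a :class:`TokenizedCorpus`.

    Each line is split on runs of whitespace and every token is casefolded
    (Unicode-aware lowercasing). Empty lines are dropped.

    Parameters
    ----------
    path:
        Path to the flattened corpus file.
    language_id:
        Identifier attached to the resulting corpus (e.g., an ISO code).
    register:
        ``"written"`` or ``"spoken"``; metadata only.
    pre_tokenize_hook:
        Optional line-level rewrite applied before splitting, e.g., to rejoin
        corpus-specific compounds. Off by default.

    Raises
    ------
    OSError
        If the file cannot be read.
    EmptyCorpusError
        If the file contains no non-empty lines.
    """
    path = Path(path)
    sentences: list[tuple[str, ...]] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            toks = _tokenize_line(line, pre_tokenize_hook)
            if toks:
                sentences.append(toks)
    if not sentences:
        raise EmptyCorpusError(f"{path} contains no non-empty lines")
    return TokenizedCorpus(language_id=language_id, sentences=tuple(sentences), register=register)


def filter_by_length(
    corpus: TokenizedCorpus, length_filter: LengthFilter
) -> tuple[TokenizedCorpus, float]:
    """Keep sentences whose length lies within the inclusive filter bounds.

    Returns the filtered corpus and the retained fraction (retained / original
    sentence count). The filtered corpus may be empty, in which case the
    fraction is 0 and the corpus object has zero sentences.
    """
    kept = tuple(s for s in corpus.sentences if length_filter.admits(len(s)))
    fraction = len(kept) / len(corpus.sentences) if corpus.sentences else 0.0
    filtered = TokenizedCorpus(
        language_id=corpus.language_id, sentences=kept, register=corpus.register
    )
    return filtered, fraction


def split_folds(
    corpus: TokenizedCorpus, n_folds: int = 10, seed: int = 0, shuffle: bool = False
) -> FoldAssignment:
    """Partition sentences into ``n_folds`` sub-corpora of (near-)equal size.

    By default folds are contiguous blocks of sentence indices, so each
    sub-corpus is a document-coherent slice; fold sizes differ by at most one
    sentence. With ``shuffle=True`` sentence indices are permuted with a
    generator seeded by ``seed`` before the block split, giving a randomized
    but still balanced assignment.
    """
    n = len(corpus.sentences)
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    if n < n_folds:
        raise ValueError(f"corpus has {n} sentences, fewer than {n_folds} folds")
    order = list(range(n))
    if shuffle:
        import numpy as np

        rng = np.random.default_rng(seed)
        order = list(rng.permutation(n))
    base, extra = divmod(n, n_folds)
    assignment = [0] * n
    pos = 0
    for f in range(n_folds):
        size = base + (1 if f < extra else 0)
        for i in order[pos : pos + size]:
            assignment[i] = f
        pos += size
    return FoldAssignment(n_folds=n_folds, fold_of_sentence=tuple(assignment))


def save_jsonl(corpus: TokenizedCorpus, path: str | Path) -> None:
    """Write tokenized sentences as newline-delimited JSON records."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, s in enumerate(corpus.sentences):
            fh.write(json.dumps({"sentence_index": i, "tokens": list(s)}, ensure_ascii=False))
            fh.write("\n")


def load_jsonl(path: str | Path, language_id: str, register: str = "written") -> TokenizedCorpus:
    """Read tokenized sentences from newline-delimited JSON (inverse of save_jsonl)."""
    sentences: list[tuple[str, ...]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            sentences.append(tuple(rec["tokens"]))
    if not sentences:
        raise EmptyCorpusError(f"{path} contains no records")
    return TokenizedCorpus(language_id=language_id, sentences=tuple(sentences), register=register)
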