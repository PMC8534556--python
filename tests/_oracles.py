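"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
package implementation: exhaustive enumeration for DTW, full materialized
probability tables for modified Kneser-Ney, naive double loops for grouped
means and pairwise matrices, and the printed positional-entropy sum evaluated
term by term.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from itertools import product

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"


# ---------------------------------------------------------------------------
# exhaustive DTW


def dtw_enumerate(a, b) -> float:
    """Minimal squared-difference warping cost by enumerating every monotone
    path from (0,0) to (len(a)-1, len(b)-1). Exponential; lengths <= ~7 only."""
    n, m = len(a), len(b)
    best = [math.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += (a[i] - b[j]) ** 2
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def enumerate_paths(n: int, m: int):
    """All monotone warping paths over an n x m grid (as tuples of (i, j))."""
    paths = []

    def walk(i, j, acc):
        acc = acc + [(i, j)]
        if i == n - 1 and j == m - 1:
            paths.append(tuple(acc))
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, [])
    return paths


def barycenter_bruteforce(seqs, k: int) -> float:
    """Global optimum of the DBA objective for small inputs by enumerating
    every combination of warping paths and solving the induced least-squares
    problem (each barycenter coordinate = mean of its aligned points)."""
    all_paths = [enumerate_paths(k, len(s)) for s in seqs]
    best = math.inf
    for combo in product(*all_paths):
        sums = [0.0] * k
        counts = [0] * k
        for path, s in zip(combo, seqs):
            for ci, sj in path:
                sums[ci] += s[sj]
                counts[ci] += 1
        center = [sums[i] / counts[i] for i in range(k)]
        obj = 0.0
        for path, s in zip(combo, seqs):
            for ci, sj in path:
                obj += (center[ci] - s[sj]) ** 2
        # the fixed-alignment objective upper-bounds the free-alignment DTW
        # objective of this center; the minimum over all combos equals the
        # global DBA optimum
        best = min(best, obj)
    return best


# ---------------------------------------------------------------------------
# modified Kneser-Ney reference (materialized tables)


class KNReference:
    """Literal transcription of the Chen-Goodman interpolated modified
    Kneser-Ney estimator, materializing full per-context distributions.

    Conventions match the package: single <s>/<\\s> padding, continuation
    counts at lower orders except <s>-initial n-grams, per-order (D1, D2, D3+)
    discounts from counts-of-counts with a 0.75 fallback, and a uniform
    1/V base distribution over word types + </s> + <unk>.
    """

    def __init__(self, sentences, order: int):
        self.order = order
        raw = {k: Counter() for k in range(1, order + 1)}
        for sent in sentences:
            padded = ((BOS,) if order >= 2 else ()) + tuple(sent) + (EOS,)
            for k in range(1, order + 1):
                for i in range(len(padded) - k + 1):
                    gram = padded[i : i + k]
                    if k == 1 and gram == (BOS,):
                        continue
                    raw[k][gram] += 1
        self.vocab = sorted({g[0] for g in raw[1]} | {EOS, UNK})
        v = len(self.vocab)

        adjusted = {order: dict(raw[order])}
        for k in range(order - 1, 0, -1):
            cont = Counter()
            for gram in raw[k + 1]:
                cont[gram[1:]] += 1
            for gram, c in raw[k].items():
                if gram[0] == BOS:
                    cont[gram] = c
            adjusted[k] = dict(cont)

        def discounts(values):
            n = Counter(c for c in values if 1 <= c <= 4)
            n1, n2, n3, n4 = n[1], n[2], n[3], n[4]
            if min(n1, n2, n3, n4) == 0:
                return (0.75, 0.75, 0.75)
            y = n1 / (n1 + 2 * n2)
            d = (1 - 2 * y * n2 / n1, 2 - 3 * y * n3 / n2, 3 - 4 * y * n4 / n3)
            if not (0 < d[0] <= 1 and 0 < d[1] <= 2 and 0 < d[2] <= 3):
                return (0.75, 0.75, 0.75)
            return d

        disc = {k: discounts(adjusted[k].values()) for k in adjusted}

        # materialize P_k(. | ctx) bottom-up as full vectors over the vocab
        self.tables: dict[tuple[str, ...], dict[str, float]] = {}
        base = {w: 1.0 / v for w in self.vocab}
        contexts_by_level = {k: set(g[:-1] for g in adjusted[k]) for k in adjusted}
        level_dists: dict[int, dict[tuple[str, ...], dict[str, float]]] = {0: {(): base}}
        for k in range(1, order + 1):
            d1, d2, d3 = disc[k]
            level_dists[k] = {}
            by_ctx = defaultdict(dict)
            for gram, c in adjusted[k].items():
                by_ctx[gram[:-1]][gram[-1]] = c
            for ctx in contexts_by_level[k]:
                counts = by_ctx[ctx]
                total = sum(counts.values())
                n1 = sum(1 for c in counts.values() if c == 1)
                n2 = sum(1 for c in counts.values() if c == 2)
                n3p = sum(1 for c in counts.values() if c >= 3)
                gamma = (d1 * n1 + d2 * n2 + d3 * n3p) / total
                lower = self._lower_dist(level_dists, k - 1, ctx[1:])
                dist = {}
                for w in self.vocab:
                    c = counts.get(w, 0)
                    dcut = 0.0 if c == 0 else (d1 if c == 1 else d2 if c == 2 else d3)
                    dist[w] = max(c - dcut, 0.0) / total + gamma * lower[w]
                level_dists[k][ctx] = dist
        self.level_dists = level_dists

    def _lower_dist(self, level_dists, k, ctx):
        while k > 0 and ctx not in level_dists[k]:
            ctx = ctx[1:]
            k -= 1
        return level_dists[k][ctx if k > 0 else ()]

    def prob(self, word: str, context) -> float:
        context = tuple(context)
        if len(context) < self.order - 1:
            context = (BOS,) * (self.order - 1 - len(context)) + context
        word = word if word in self.level_dists[0][()] else UNK
        context = tuple(t if (t == BOS or t in self.level_dists[0][()]) else UNK for t in context)
        k = self.order
        while k > 1 and context not in self.level_dists[k]:
            context = context[1:]
            k -= 1
        dist = self.level_dists[k].get(context, self.level_dists[0][()]) if k >= 1 else self.level_dists[0][()]
        return dist[word]

    def sentence_surprisals(self, sentence):
        ctx_len = self.order - 1
        padded = (BOS,) * ctx_len + tuple(sentence)
        return [
            -math.log2(self.prob(padded[i], padded[i - ctx_len : i]))
            for i in range(ctx_len, len(padded))
        ]


# ---------------------------------------------------------------------------
# positional entropy (printed formula, term by term)


def positional_entropy_bruteforce(sentences, word_prob, position: int, sentence_length=None):
    """H(X) = -sum_w P(w in X) log2 P(w) evaluated as the literal sum over
    word types; ``word_prob`` maps a word to its corpus-wide probability."""
    if sentence_length is None:
        pool = [s for s in sentences if len(s) >= position]
    else:
        pool = [s for s in sentences if len(s) == sentence_length]
    words = [s[position - 1] for s in pool]
    h = 0.0
    for w in sorted(set(words)):
        p_in_x = words.count(w) / len(words)
        h += -p_in_x * math.log2(word_prob(w))
    return h
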