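"""Synthetic corpora and typology tables with known ground truth.

Every pipeline stage can be exercised without external corpora:

* :func:`generate_positional_corpus` plants a per-position expected unigram
  surprisal profile by drawing each token from a position-indexed mixture
  over frequency-ranked word classes, and returns the analytic expectation
  alongside the corpus.
* :func:`generate_markov_corpus` samples from a random order-2 Markov source,
  so that context-aware (trigram) models genuinely beat unigram models on
  held-out text.
* :func:`generate_language_family` builds a family of languages whose single
  latent parameter drives both their planted information-curve shape and
  their categorical typological features, with missing cells masked
  completely at random -- the ground truth for curve/typology covariation
  analyses.

Positional profiles are specified in "ladder space": a coordinate u in [0, 1]
at each relative sentence position selects between word classes arranged on a
surprisal ladder (u = 0 the most frequent class, u = 1 the rarest). Because a
word's corpus-level probability is its class's usage mass divided by the class
size, class sizes are *solved from* the profile's usage marginals so that the
ladder spans a configured number of bits regardless of how unevenly the
profile uses the classes; the planted expectation returned to the caller is
computed from the realized (integer) class sizes and is exact.

Word identities are integers rendered as strings ("w0001"), which keeps the
vocabulary language-neutral and stably sortable. All generators are
bit-reproducible given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .corpus import TokenizedCorpus
from .typology import FEATURE_CATEGORIES, TypologyTable

__all__ = [
    "GeneratorSpec",
    "FamilySpec",
    "MarkovSource",
    "ProfileLayout",
    "length_distribution",
    "profile_layout",
    "analytic_word_surprisals",
    "generate_positional_corpus",
    "generate_markov_corpus",
    "generate_language_family",
    "planted_curve",
]

#: named positional profiles in ladder space: piecewise-linear anchors
#: (relative position r, ladder coordinate u in [0, 1])
PROFILE_ANCHORS: dict[str, tuple[tuple[float, float], ...]] = {
    "flat": ((0.0, 0.5), (1.0, 0.5)),
    "increasing": ((0.0, 0.0), (1.0, 1.0)),
    "decreasing": ((0.0, 1.0), (1.0, 0.0)),
    # low start, mid-sentence plateau, penultimate dip, steep final rise
    "three_step": ((0.0, 0.0), (0.2, 0.5), (0.7, 0.5), (0.85, 0.3), (1.0, 1.0)),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Configuration of a synthetic corpus with a planted positional profile.

    ``positional_profile`` is either a named shape ("flat", "increasing",
    "decreasing", "three_step") or explicit (r, u) anchors in ladder space.
    A constant profile plants the equiprobable distribution (every word type
    has probability exactly 1/V at every position), the uniform-density null.
    ``ladder_span_bits`` sets the nominal surprisal difference between the
    most frequent and the rarest word class. ``markov_order`` 0 selects the
    positional generator, 2 the Markov-chain generator.
    """

    vocabulary_size: int = 248
    min_len: int = 5
    max_len: int = 45
    positional_profile: str | tuple[tuple[float, float], ...] = "flat"
    markov_order: int = 0
    n_sentences: int = 5000
    seed: int = 0
    n_groups: int = 5
    ladder_span_bits: float = 4.0
    # truncated negative-binomial sentence-length distribution (right-skewed)
    nbinom_n: float = 4.0
    nbinom_p: float = 0.25

    def __post_init__(self) -> None:
        if self.vocabulary_size < 2:
            raise ValueError("vocabulary_size must be >= 2")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be >= 1")
        if self.markov_order not in (0, 2):
            raise ValueError("markov_order must be 0 or 2")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.ladder_span_bits <= 0:
            raise ValueError("ladder_span_bits must be positive")


@dataclass(frozen=True)
class FamilySpec:
    """Configuration of a synthetic language family.

    Each language i has a latent parameter theta_i in [0, 1] that drives both
    its planted curve shape (theta = 0 decreasing, 1 increasing) and its
    categorical feature values (theta discretized through feature-specific
    random thresholds after Gaussian noise). ``sever_dependence`` replaces the
    theta used for features with an independent draw, removing the planted
    covariation while leaving both marginal structures intact.
    """

    n_languages: int = 30
    n_features_per_category: int = 8
    missingness_rate: float = 0.2
    feature_noise_sd: float = 0.15
    category_noise: dict[str, float] = field(default_factory=dict)
    sever_dependence: bool = False
    latent_params: tuple[float, ...] | None = None
    n_sentences: int = 200
    vocabulary_size: int = 120
    min_len: int = 5
    max_len: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_languages < 2:
            raise ValueError("n_languages must be >= 2")
        if not (0.0 <= self.missingness_rate < 1.0):
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.latent_params is not None and len(self.latent_params) != self.n_languages:
            raise ValueError("latent_params must have one entry per language")


def length_distribution(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the truncated negative-binomial length law."""
    lengths = np.arange(spec.min_len, spec.max_len + 1)
    pmf = sps.nbinom.pmf(lengths - spec.min_len, spec.nbinom_n, spec.nbinom_p)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("length distribution has no mass on the requested range")
    return lengths, pmf / total


def _profile_anchors(
    profile: str | tuple[tuple[float, float], ...],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, str):
        try:
            anchors = PROFILE_ANCHORS[profile]
        except KeyError:
            raise ValueError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILE_ANCHORS)}"
            ) from None
    else:
        anchors = tuple(profile)
    rs = np.array([a[0] for a in anchors], dtype=float)
    us = np.array([a[1] for a in anchors], dtype=float)
    if np.any(np.diff(rs) <= 0) or rs[0] != 0.0 or rs[-1] != 1.0:
        raise ValueError("profile anchors must have strictly increasing r from 0 to 1")
    if np.any((us < 0.0) | (us > 1.0)):
        raise ValueError("profile ladder coordinates must lie in [0, 1]")
    return rs, us


def _grid_mixtures(
    rs: np.ndarray, us: np.ndarray, r_grid: np.ndarray, n_groups: int
) -> np.ndarray:
    """Class mixtures at each relative position.

    The ladder coordinate u maps to a Binomial(n_groups - 1, u) mixture over
    classes: the mean class index moves linearly with u while every class
    keeps non-trivial mass at interior u, so no class's usage collapses to a
    sliver when a profile hovers near a class boundary. Because the class
    surprisal ladder is increasing and the Binomial family is stochastically
    increasing in u, the expected surprisal is strictly increasing in u.
    Constant profiles collapse to the single whole-vocabulary class (see
    :func:`profile_layout`).
    """
    if np.allclose(us, us[0]):
        mix = np.zeros(n_groups)
        mix[0] = 1.0
        return np.tile(mix, (r_grid.size, 1))
    u_interp = np.interp(r_grid, rs, us)
    gs = np.arange(n_groups)
    return sps.binom.pmf(gs[None, :], n_groups - 1, u_interp[:, None])


def _relative_positions(length: int) -> np.ndarray:
    if length == 1:
        return np.zeros(1)
    return np.arange(length) / (length - 1)


@dataclass(frozen=True)
class ProfileLayout:
    """Realized word-class layout for one positional-profile spec.

    ``sizes[g]`` is the number of word types in class g (0 for classes the
    profile never uses), ``marginals[g]`` the class's corpus-level usage mass,
    and ``class_surprisal[g] = -log2(marginals[g] / sizes[g])`` the analytic
    surprisal of every word in the class (inf for unused classes).
    ``expected[L]`` is the planted expected surprisal at each position of a
    length-L sentence; it is exact under the generating distributions.
    """

    sizes: np.ndarray
    offsets: np.ndarray
    marginals: np.ndarray
    class_surprisal: np.ndarray
    mix_by_len: dict[int, np.ndarray]
    expected: dict[int, np.ndarray]


def profile_layout(spec: GeneratorSpec) -> ProfileLayout:
    """Solve the word-class layout that realizes the spec's planted profile.

    For a constant profile the whole vocabulary forms one equiprobable class.
    Otherwise the class usage marginals are fixed by the profile (they do not
    depend on class sizes), and the class sizes are chosen so that class g
    sits ``g * ladder_span_bits / (n_groups - 1)`` bits above class 0 on the
    surprisal ladder, up to integer rounding; the reported expectation uses
    the realized integer sizes and is exact.

    Raises ``ValueError`` when the vocabulary is too small to realize a
    strictly increasing ladder (the bound is reported in the message).
    """
    rs, us = _profile_anchors(spec.positional_profile)
    g = spec.n_groups
    v = spec.vocabulary_size
    lengths, pl = length_distribution(spec)
    mix_by_len: dict[int, np.ndarray] = {}
    weighted = np.zeros(g)
    total_weight = 0.0
    for length, p in zip(lengths, pl):
        mixes = _grid_mixtures(rs, us, _relative_positions(int(length)), g)
        mix_by_len[int(length)] = mixes
        weighted += p * mixes.sum(axis=0)
        total_weight += p * length
    marginals = weighted / total_weight
    used = marginals > 0

    if np.allclose(us, us[0]):
        sizes = np.zeros(g, dtype=int)
        sizes[0] = v
    else:
        delta = spec.ladder_span_bits / (g - 1)
        scale = v / float(marginals @ np.exp2(delta * np.arange(g)))
        sizes_float = marginals * scale * np.exp2(delta * np.arange(g))
        sizes = np.where(used, np.maximum(np.round(sizes_float), 1.0), 0.0).astype(int)
        drift = v - int(sizes.sum())
        sizes[int(np.argmax(sizes))] += drift

    with np.errstate(divide="ignore", invalid="ignore"):
        class_surprisal = np.where(
            sizes > 0, -np.log2(marginals / np.maximum(sizes, 1)), np.inf
        )
    fin = class_surprisal[used & (sizes > 0)]
    if np.any(sizes[used] < 1) or (fin.size > 1 and np.any(np.diff(fin) <= 0)):
        # sufficient condition: every used class deserves >= 2 word types
        delta = spec.ladder_span_bits / (g - 1)
        weights = marginals * np.exp2(delta * np.arange(g))
        need = int(np.ceil(2.0 * weights[used].sum() / weights[used].min()))
        raise ValueError(
            f"vocabulary_size={v} cannot realize a strictly increasing "
            f"{spec.ladder_span_bits}-bit surprisal ladder over {g} word classes "
            f"with this profile; you need at least roughly {need} word types, "
            "or a smaller ladder_span_bits / n_groups"
        )

    finite = np.where(np.isfinite(class_surprisal), class_surprisal, 0.0)
    expected = {length: mixes @ finite for length, mixes in mix_by_len.items()}
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    return ProfileLayout(
        sizes=sizes,
        offsets=offsets,
        marginals=marginals,
        class_surprisal=class_surprisal,
        mix_by_len=mix_by_len,
        expected=expected,
    )


def analytic_word_surprisals(spec: GeneratorSpec) -> dict[str, float]:
    """Map each word type to -log2 of its generating marginal probability."""
    layout = profile_layout(spec)
    out: dict[str, float] = {}
    wid = 0
    for size, s in zip(layout.sizes, layout.class_surprisal):
        for _ in range(int(size)):
            out[f"w{wid:04d}"] = float(s)
            wid += 1
    return out


def generate_positional_corpus(
    spec: GeneratorSpec,
) -> tuple[TokenizedCorpus, dict[int, np.ndarray]]:
    """Sample a corpus whose expected unigram surprisal follows a planted
    per-position profile.

    Token generation: at relative position r the word class is drawn from the
    profile's ladder mixture and the word uniformly within the class. The
    expected unigram surprisal at a position is
    ``sum_g pi_r(g) * -log2(m_g / N_g)`` with m_g the corpus-level class
    usage mass and N_g the realized class size.

    Returns ``(corpus, expected)`` where ``expected[L][p-1]`` is the exact
    expected surprisal (bits) at position p of a length-L sentence.
    """
    if spec.markov_order != 0:
        raise ValueError("positional generator requires markov_order = 0")
    layout = profile_layout(spec)
    sizes, offsets = layout.sizes, layout.offsets

    rng = np.random.default_rng(spec.seed)
    lengths, pl = length_distribution(spec)
    sent_lengths = rng.choice(lengths, size=spec.n_sentences, p=pl)
    words = [f"w{wid:04d}" for wid in range(spec.vocabulary_size)]
    # draw all sentences of one length together, one vectorized draw per position
    tokens_by_length: dict[int, np.ndarray] = {}
    for length in np.unique(sent_lengths):
        length = int(length)
        n_here = int((sent_lengths == length).sum())
        mixes = layout.mix_by_len[length]
        word_ids = np.empty((n_here, length), dtype=int)
        for p in range(length):
            groups = rng.choice(spec.n_groups, size=n_here, p=mixes[p])
            within = rng.integers(0, sizes[groups])
            word_ids[:, p] = offsets[groups] + within
        tokens_by_length[length] = word_ids
    cursor = {int(l): 0 for l in tokens_by_length}
    sentences: list[tuple[str, ...]] = []
    for length in sent_lengths:
        length = int(length)
        row = tokens_by_length[length][cursor[length]]
        cursor[length] += 1
        sentences.append(tuple(words[wid] for wid in row))
    corpus = TokenizedCorpus(language_id="synth", sentences=tuple(sentences))
    return corpus, layout.expected


@dataclass(frozen=True)
class MarkovSource:
    """A random order-2 Markov source with retrievable parameters."""

    start1: np.ndarray  # P(w1), shape (V,)
    start2: np.ndarray  # P(w2 | w1), shape (V, V)
    trans: np.ndarray  # P(w | u, v), shape (V, V, V)

    @property
    def vocabulary_size(self) -> int:
        return self.start1.size

    def mean_conditional_entropy_bits(self) -> float:
        """Unweighted mean entropy of the order-2 transition rows (bits)."""
        p = self.trans
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=-1)
        return float(h.mean())


def generate_markov_corpus(
    spec: GeneratorSpec, concentration: float = 0.1
) -> tuple[TokenizedCorpus, MarkovSource]:
    """Sample sentences from a randomly parameterized order-2 Markov chain.

    Transition rows are Dirichlet(``concentration``) draws, so small
    concentrations give low conditional entropy (predictable chains) while
    the marginal word distribution stays broad -- exactly the regime where a
    trigram model beats a unigram model on held-out text.
    """
    if spec.markov_order != 2:
        raise ValueError("Markov generator requires markov_order = 2")
    rng = np.random.default_rng(spec.seed)
    v = spec.vocabulary_size
    alpha = np.full(v, concentration)
    start1 = rng.dirichlet(np.full(v, 1.0))
    start2 = rng.dirichlet(np.full(v, 1.0), size=v)
    trans = rng.dirichlet(alpha, size=(v, v))
    source = MarkovSource(start1=start1, start2=start2, trans=trans)

    lengths, pl = length_distribution(spec)
    sent_lengths = rng.choice(lengths, size=spec.n_sentences, p=pl)
    sentences: list[tuple[str, ...]] = []
    for length in sent_lengths:
        tokens = np.empty(int(length), dtype=int)
        tokens[0] = rng.choice(v, p=start1)
        if length > 1:
            tokens[1] = rng.choice(v, p=start2[tokens[0]])
        for p in range(2, int(length)):
            tokens[p] = rng.choice(v, p=trans[tokens[p - 2], tokens[p - 1]])
        sentences.append(tuple(f"w{w:04d}" for w in tokens))
    corpus = TokenizedCorpus(language_id="synth-markov", sentences=tuple(sentences))
    return corpus, source


def _theta_profile(theta: float) -> tuple[tuple[float, float], ...]:
    """Latent parameter -> profile anchors: decreasing (0) to increasing (1)."""
    return ((0.0, 1.0 - theta), (1.0, theta))


def _family_generator_spec(spec: FamilySpec, theta: float, seed: int = 0) -> GeneratorSpec:
    return GeneratorSpec(
        vocabulary_size=spec.vocabulary_size,
        min_len=spec.min_len,
        max_len=spec.max_len,
        positional_profile=_theta_profile(theta),
        n_sentences=spec.n_sentences,
        seed=seed,
    )


def planted_curve(spec: FamilySpec, theta: float, k: int = 5) -> np.ndarray:
    """Analytic expected-surprisal curve for latent ``theta`` on a k-point grid."""
    gspec = _family_generator_spec(spec, float(theta))
    layout = profile_layout(gspec)
    rs, us = _profile_anchors(gspec.positional_profile)
    grid = np.linspace(0.0, 1.0, k)
    mixes = _grid_mixtures(rs, us, grid, gspec.n_groups)
    finite = np.where(np.isfinite(layout.class_surprisal), layout.class_surprisal, 0.0)
    return mixes @ finite


def generate_language_family(
    spec: FamilySpec, include_corpora: bool = True
) -> tuple[dict[str, TokenizedCorpus], TypologyTable, dict[str, np.ndarray]]:
    """Generate a language family with planted typology-curve covariation.

    Returns ``(corpora, typology_table, truth)`` where ``truth`` maps each
    language to its planted 5-point expected-surprisal curve. Languages with
    nearby latent parameters receive both similar curves and correlated
    feature values; with ``sever_dependence=True`` the features are driven by
    an independent latent draw instead. ``include_corpora=False`` skips the
    (comparatively expensive) corpus simulation and returns an empty corpus
    dict -- useful when only the planted curves and features are needed.
    """
    rng = np.random.default_rng(spec.seed)
    langs = [f"lang{i:02d}" for i in range(spec.n_languages)]
    if spec.latent_params is not None:
        theta = np.asarray(spec.latent_params, dtype=float)
    else:
        theta = rng.uniform(0.0, 1.0, size=spec.n_languages)
    feature_theta = (
        rng.uniform(0.0, 1.0, size=spec.n_languages) if spec.sever_dependence else theta
    )

    corpora: dict[str, TokenizedCorpus] = {}
    truth: dict[str, np.ndarray] = {}
    for i, lang in enumerate(langs):
        corpus_seed = int(rng.integers(0, 2**31 - 1))
        if include_corpora:
            gspec = _family_generator_spec(spec, float(theta[i]), seed=corpus_seed)
            corpus, _ = generate_positional_corpus(gspec)
            corpora[lang] = TokenizedCorpus(
                language_id=lang, sentences=corpus.sentences, register=corpus.register
            )
        truth[lang] = planted_curve(spec, float(theta[i]))

    columns: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    for cat in FEATURE_CATEGORIES:
        noise_sd = spec.category_noise.get(cat, spec.feature_noise_sd)
        for j in range(spec.n_features_per_category):
            feat = f"{cat.replace(' ', '_')}_{j:02d}"
            n_values = int(rng.integers(2, 5))
            cuts = np.sort(rng.uniform(0.1, 0.9, size=n_values - 1))
            noisy = feature_theta + rng.normal(0.0, noise_sd, size=spec.n_languages)
            bins = np.searchsorted(cuts, noisy)
            columns[feat] = [f"v{b}" for b in bins]
            categories[feat] = cat
    values = pd.DataFrame(columns, index=pd.Index(langs, name="language_id"), dtype=object)
    if spec.missingness_rate > 0:
        mask = rng.uniform(size=values.shape) < spec.missingness_rate
        # never blank out a language's entire row
        for i in range(mask.shape[0]):
            if mask[i].all():
                mask[i, rng.integers(0, mask.shape[1])] = False
        values = values.mask(mask)
    table = TypologyTable(values=values, feature_category=categories)
    return corpora, table, truth
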