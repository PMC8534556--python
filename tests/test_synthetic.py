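import math

import numpy as np
import pytest
from scipy import stats as sps

from infocurve.corpus import split_folds
from infocurve.curves import center_curve
from infocurve.ngrams import crossval_surprisals
from infocurve.stats import cluster_languages
from infocurve.synthetic import (
    FamilySpec,
    GeneratorSpec,
    analytic_word_surprisals,
    generate_language_family,
    generate_markov_corpus,
    generate_positional_corpus,
    length_distribution,
    planted_curve,
    profile_layout,
)
from infocurve.typology import curve_similarity_matrix, shared_feature_proportion


class TestPositionalGenerator:
    def test_reproducible_given_seed(self):
        spec = GeneratorSpec(n_sentences=50, seed=99)
        c1, e1 = generate_positional_corpus(spec)
        c2, e2 = generate_positional_corpus(spec)
        assert c1.sentences == c2.sentences
        assert all(np.array_equal(e1[k], e2[k]) for k in e1)

    def test_flat_profile_constant_expectation_and_empirical_means(self):
        spec = GeneratorSpec(positional_profile="flat", n_sentences=5000, seed=2)
        corpus, expected = generate_positional_corpus(spec)
        # analytic expectation exactly constant across lengths and positions
        vals = np.concatenate([v for v in expected.values()])
        assert np.allclose(vals, vals[0])
        # empirical per-position means (scored with analytic token surprisal)
        # agree with the expectation within 3 standard errors
        word_s = analytic_word_surprisals(spec)
        by_pos = {}
        for s in corpus.sentences:
            for p, w in enumerate(s):
                by_pos.setdefault((len(s), p), []).append(word_s[w])
        for (length, p), obs in by_pos.items():
            if len(obs) < 20:
                continue
            se = np.std(obs, ddof=1) / np.sqrt(len(obs)) + 1e-12
            assert abs(np.mean(obs) - expected[length][p]) <= 3 * se + 1e-9

    def test_increasing_profile_monotone_expectation_and_final_peak(self):
        spec = GeneratorSpec(positional_profile="increasing", n_sentences=3000, seed=5)
        corpus, expected = generate_positional_corpus(spec)
        for length, exp in expected.items():
            if length >= 3:
                assert np.all(np.diff(exp) > 0)
        # empirically, the final position is the most surprising on average
        word_s = analytic_word_surprisals(spec)
        firsts = [word_s[s[0]] for s in corpus.sentences]
        finals = [word_s[s[-1]] for s in corpus.sentences]
        mids = [word_s[w] for s in corpus.sentences for w in s[1:-1]]
        assert np.mean(finals) > np.mean(mids) > np.mean(firsts)

    def test_three_step_profile_shape(self):
        spec = GeneratorSpec(positional_profile="three_step", n_sentences=1, seed=0)
        _, expected = generate_positional_corpus(spec)
        exp = expected[45]
        assert exp[-1] == max(exp)  # steep final rise
        assert exp[0] == min(exp)  # low-information start
        dip = exp[int(round(0.85 * 44))]
        plateau = exp[int(round(0.5 * 44))]
        assert dip < plateau  # penultimate dip below the mid-sentence plateau

    def test_infeasible_vocabulary_error_explains_bound(self):
        with pytest.raises(ValueError, match="at least"):
            generate_positional_corpus(
                GeneratorSpec(
                    positional_profile="increasing", vocabulary_size=6,
                    n_groups=5, n_sentences=10,
                )
            )

    def test_token_frequencies_match_generator_marginals(self):
        # chi-square goodness of fit on word-class counts, 10 seeds at n=5000:
        # reject at the 0.01 level in at most one seed
        rejected = 0
        for seed in range(10):
            spec = GeneratorSpec(
                positional_profile="increasing", n_sentences=5000, seed=seed
            )
            corpus, _ = generate_positional_corpus(spec)
            layout = profile_layout(spec)
            bounds = np.cumsum(layout.sizes)
            counts = np.zeros(len(layout.sizes))
            for s in corpus.sentences:
                for w in s:
                    counts[np.searchsorted(bounds, int(w[1:]), side="right")] += 1
            stat = sps.chisquare(counts, counts.sum() * layout.marginals)
            if stat.pvalue < 0.01:
                rejected += 1
        assert rejected <= 1

    def test_length_distribution_normalized_and_supported(self):
        spec = GeneratorSpec(min_len=5, max_len=45)
        lengths, pmf = length_distribution(spec)
        assert lengths[0] == 5 and lengths[-1] == 45
        assert pmf.sum() == pytest.approx(1.0)
        assert (pmf > 0).all()


class TestMarkovGenerator:
    def test_reproducible_and_requires_order_two(self):
        spec = GeneratorSpec(vocabulary_size=12, markov_order=2, n_sentences=30, seed=4)
        c1, s1 = generate_markov_corpus(spec)
        c2, s2 = generate_markov_corpus(spec)
        assert c1.sentences == c2.sentences
        assert np.array_equal(s1.trans, s2.trans)
        with pytest.raises(ValueError):
            generate_markov_corpus(GeneratorSpec(markov_order=0))

    def test_near_deterministic_chain_has_tiny_trigram_surprisal(self):
        spec = GeneratorSpec(
            vocabulary_size=8, min_len=6, max_len=10, markov_order=2,
            n_sentences=300, seed=11,
        )
        corpus, source = generate_markov_corpus(spec, concentration=1e-6)
        assert source.mean_conditional_entropy_bits() < 0.01
        table = crossval_surprisals(corpus, 3, split_folds(corpus, 5))
        late = table[table["position"] >= 3]["surprisal"]
        assert late.mean() < 1.0  # near-zero source entropy up to smoothing

    def test_uniform_chain_approaches_log2_vocab(self):
        v = 16
        spec = GeneratorSpec(
            vocabulary_size=v, min_len=6, max_len=10, markov_order=2,
            n_sentences=400, seed=7,
        )
        corpus, source = generate_markov_corpus(spec, concentration=1e6)
        assert source.mean_conditional_entropy_bits() == pytest.approx(
            math.log2(v), abs=0.01
        )
        table = crossval_surprisals(corpus, 3, split_folds(corpus, 5))
        assert table["surprisal"].mean() == pytest.approx(math.log2(v), abs=0.35)

    def test_trigram_beats_unigram_on_predictable_chains(self):
        for seed in range(3):
            spec = GeneratorSpec(
                vocabulary_size=20, min_len=5, max_len=15, markov_order=2,
                n_sentences=400, seed=seed,
            )
            corpus, _ = generate_markov_corpus(spec, concentration=0.1)
            folds = split_folds(corpus, 10)
            uni = crossval_surprisals(corpus, 1, folds)["surprisal"].mean()
            tri = crossval_surprisals(corpus, 3, folds)["surprisal"].mean()
            assert tri < uni


class TestFamilyGenerator:
    def test_reproducible(self):
        spec = FamilySpec(n_languages=4, n_sentences=20, seed=6)
        c1, t1, g1 = generate_language_family(spec)
        c2, t2, g2 = generate_language_family(spec)
        assert all(c1[l].sentences == c2[l].sentences for l in c1)
        assert t1.values.equals(t2.values)
        assert all(np.array_equal(g1[l], g2[l]) for l in g1)

    def test_identical_latents_no_noise_full_feature_agreement(self):
        spec = FamilySpec(
            n_languages=4,
            latent_params=(0.4,) * 4,
            feature_noise_sd=0.0,
            missingness_rate=0.0,
            n_sentences=10,
            seed=1,
        )
        _, table, _ = generate_language_family(spec, include_corpora=False)
        langs = table.languages
        for i in range(len(langs)):
            for j in range(i + 1, len(langs)):
                assert shared_feature_proportion(table, langs[i], langs[j]) == 1.0

    def test_planted_curves_track_latent_parameter(self):
        spec = FamilySpec(n_languages=2, seed=0)
        inc = planted_curve(spec, 1.0)
        dec = planted_curve(spec, 0.0)
        assert np.all(np.diff(inc) > 0)
        assert np.all(np.diff(dec) < 0)
        assert inc == pytest.approx(dec[::-1])

    def test_two_latent_clusters_recovered_by_clustering(self):
        spec = FamilySpec(
            n_languages=16,
            latent_params=tuple([0.1] * 8 + [0.9] * 8),
            n_sentences=10,
            seed=2,
        )
        _, _, truth = generate_language_family(spec, include_corpora=False)
        curves = {l: center_curve(v) for l, v in truth.items()}
        tree = cluster_languages(curve_similarity_matrix(curves))
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(tree.linkage, t=2, criterion="maxclust")
        langs = sorted(curves)
        lo = {labels[langs.index(f"lang{i:02d}")] for i in range(8)}
        hi = {labels[langs.index(f"lang{i:02d}")] for i in range(8, 16)}
        assert len(lo) == 1 and len(hi) == 1 and lo != hi

    def test_missingness_rate_respected(self):
        spec = FamilySpec(n_languages=20, missingness_rate=0.3, n_sentences=10, seed=9)
        _, table, _ = generate_language_family(spec, include_corpora=False)
        frac_missing = table.values.isna().to_numpy().mean()
        assert frac_missing == pytest.approx(0.3, abs=0.05)
        assert (table.values.notna().sum(axis=1) > 0).all()

    def test_severed_dependence_changes_features_not_curves(self):
        base = FamilySpec(n_languages=6, n_sentences=10, seed=13)
        severed = FamilySpec(n_languages=6, n_sentences=10, seed=13, sever_dependence=True)
        _, tb, gb = generate_language_family(base, include_corpora=False)
        _, ts, gs = generate_language_family(severed, include_corpora=False)
        assert all(np.array_equal(gb[l], gs[l]) for l in gb)
        assert not tb.values.equals(ts.values)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FamilySpec(n_languages=1)
        with pytest.raises(ValueError):
            FamilySpec(missingness_rate=1.0)
        with pytest.raises(ValueError):
            FamilySpec(n_languages=3, latent_params=(0.5, 0.5))
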