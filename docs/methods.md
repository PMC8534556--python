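# Methods

This note documents the models and procedures implemented in `infocurve`,
the parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the package's known limitations.

## Corpus handling

Input is flattened text: UTF-8, one sentence per line, tokens separated by
whitespace. Tokens are Unicode-casefolded (not merely lowercased), so the
pipeline behaves sensibly across scripts; punctuation is not stripped —
tokens are whatever whitespace splitting yields, matching the upstream
preprocessing conventions of the corpora this method is applied to.
Length filtering is inclusive on both bounds, with defaults of 5–45 words
for written registers and 5–15 for spoken ones (spoken utterances are much
shorter, and positions beyond ~15 have almost no support there).

Cross-validation folds are contiguous blocks of sentences (10 by default,
sizes differing by at most one). Contiguity keeps each held-out sub-corpus
document-coherent, which is the conservative choice for text with local
topical structure; a seeded shuffled mode is available when exchangeability
is preferred.

## N-gram models and surprisal

Both the unigram and trigram models use interpolated modified Kneser-Ney
smoothing (Chen & Goodman's formulation):

* per order, three discounts D1, D2, D3+ estimated from the counts-of-counts
  n1..n4 of the counts used at that order (Y = n1/(n1+2n2); D_k = k −
  (k+1) Y n_{k+1}/n_k). When any n_k is zero or an estimate leaves its valid
  range — which happens only on degenerate toy corpora — all three discounts
  fall back to a fixed 0.75, the conventional default;
* lower orders use continuation counts (number of distinct left-extending
  word types) instead of raw frequencies, except n-grams that start with the
  begin token, which keep raw counts because nothing can precede it;
* the base of the interpolation is the uniform distribution over the
  prediction vocabulary (word types + end token + `<unk>`), so the
  open-vocabulary `<unk>` type receives exactly the interpolated base mass
  and held-out out-of-vocabulary words always get finite surprisal.

Sentences are padded with a single begin token and a single end token, and
counts for all orders are collected from the padded sentence; n-grams never
cross sentence boundaries. The first word of a sentence is scored with a
begin-token context; since the all-begin trigram context is never observed,
its probability backs off to the observed (begin, w1) bigram — the behavior
of the standard n-gram toolkits. The end token is scored during model
estimation (it carries probability mass) but is never reported as a word
position. Surprisal is in bits (base-2 logs); the base is a global constant
that cancels after curve centering, so nothing downstream depends on it.

For every observed context the conditional probabilities sum to 1 to within
1e-9 (verified exactly in the acceptance suite by full vocabulary sums with
compensated summation). Models serialize to and from the standard ARPA
format; because the in-memory model is fully interpolated, the ARPA backoff
representation reproduces it exactly (stored probabilities are the
interpolated ones, backoff weights are the per-context leftover mass).

The positional-entropy replication computes the frequency-weighted average
unigram surprisal of the words occupying one sentence position,
H(X) = −Σ_w P(w∈X) log2 P(w). Whether the position frequencies are
conditioned on an exact sentence length or pooled over all long-enough
sentences is exposed as a parameter, since both readings of the original
analysis are defensible.

## Curve extraction

Per-word surprisals are averaged position-wise within each sentence length,
giving one variable-length curve per observed length. These are aggregated by
DTW Barycenter Averaging:

* DTW uses squared-difference local cost, the symmetric step set
  {(1,0),(0,1),(1,1)}, and no window; backtrace ties prefer diagonal, then
  vertical, then horizontal, so alignments are deterministic;
* DBA initializes from the medoid input (minimal summed DTW distance to the
  others) resampled to length K by linear interpolation, then alternates
  aligning all inputs to the barycenter and replacing each coordinate with
  the mean of its aligned points, until the relative objective improvement
  falls below 1e-6 or 100 iterations;
* the objective (summed DTW distance) is non-increasing at every iteration —
  an exact property of this EM scheme, asserted on every run via the stored
  objective trajectory.

K defaults to 5 — enough coordinates to express the rise/plateau/dip/rise
shapes of interest while keeping every coordinate supported by many aligned
points — and is a configuration knob throughout. Per-length curves enter DBA
unweighted (one curve per length); an optional weight argument allows
weighting by sentence support instead. Curves are mean-centered before any
cross-language comparison because absolute surprisal level tracks corpus
size; family-level curves are DBA barycenters of the member languages'
centered curves, while each language's own barycenter is computed on raw
surprisal curves and centered afterwards.

DBA is a local optimizer: the identical-inputs fixed point is exact, but on
heterogeneous inputs the EM limit can sit above the global optimum of the
objective (verified against exhaustive alignment enumeration on small
instances). Tests therefore treat the enumerated optimum as a lower bound
rather than an equality.

## Typological similarity and imputation

Typology tables are languages × categorical features (seven feature
categories: phonology, nominal categories, verbal categories, nominal
syntax, word order, simple clauses, other), with missing entries. Pairwise
typological similarity is the proportion of *jointly observed* features with
exactly matching values; pairs with no jointly observed features are
undefined and are masked out of both similarity matrices (not set to zero)
so correlations always run over the same pair set. Exact match is used even
for features with ordered values; a graded plug-in point exists but is off
by default.

Missing values can be imputed with a single-imputation regularized iterative
procedure on the dummy-coded table: initialize missing cells at observed
column means, then alternate column-centered rank-`n_components` SVD
reconstruction with re-imputation of the missing cells until the largest
change falls below 1e-6; each missing categorical cell finally takes the
category with the highest reconstructed score. Observed cells are never
altered. `n_components` defaults to 5; the number of retained dimensions is
genuinely arbitrary and is exposed in the interface, as is an
`n_imputations`-style extension point for a future multiple-imputation
variant with pooling. Features observed in fewer than two languages are
dropped with a warning.

## Cross-language statistics

Curve similarity (cosine of centered curves) and typological similarity are
correlated over the upper-triangle pairs with Pearson's r. Two inference
methods are provided: the conventional pair-level t-test
(t = r sqrt((n−2)/(1−r²)), n = number of pairs), which treats dependent
pairs as independent and is therefore anti-conservative, and a Mantel
permutation test (≥999 label permutations of one matrix, seeded) whose null
calibration is verified in the acceptance suite. The t-test is the default
for comparability with prior reports; the permutation test is used wherever
a calibrated decision is needed. Per-feature-category correlations restrict
the shared-feature computation to one category at a time and carry Fisher-z
95% intervals.

Across-language dispersion is summarized by the sample variance of centered
curve values at each barycenter position, with a percentile bootstrap CI
(1000 resamples over languages, seeded) for the positional mean; resampling
is over languages, not positions, since languages are the exchangeable
units. Hierarchical clustering uses distance 1 − cosine with average linkage
(no linkage is canonical here; the choice is exposed), and trees export to
Newick with merge heights as branch lengths.

## Synthetic data

The generators produce the package's own test bed; they emulate the
*structure* of the real analyses, not natural language.

**Positional corpora.** The vocabulary is split into word classes on a
surprisal ladder; a profile assigns each relative sentence position a ladder
coordinate u ∈ [0,1], realized as a Binomial(G−1, u) mixture over the G
classes (mean class index moves linearly with u; every class keeps interior
mass, and because the ladder is increasing and the Binomial family is
stochastically increasing in u, expected surprisal is strictly increasing
in u). A word's marginal probability is its class's usage mass divided by
the class size, so class sizes are *solved from* the profile's usage
marginals to realize a configured ladder span (default 4 bits across 5
classes, roughly the spread between frequent function words and rare content
words); the planted per-position expectation is computed from the realized
integer sizes and is exact. Requesting a ladder a small vocabulary cannot
support raises an error stating the required vocabulary size. Constant
profiles plant the equiprobable distribution — every word type at
probability 1/V, the textbook uniform-information-density null, with zero
token-level surprisal spread. Sentence lengths follow a truncated negative
binomial (defaults n=4, p=0.25 on 5–45), a right-skewed shape chosen as
generically realistic for utterance lengths; the parameters are
configuration, not claims about any corpus.

**Markov corpora.** An order-2 chain with Dirichlet-sampled transition rows
(concentration 0.1 by default: low conditional entropy, broad marginals) —
the regime where context genuinely helps, so held-out trigram surprisal must
undercut unigram surprisal.

**Language families.** Each language has a latent θ ∈ [0,1] that drives
both its planted curve (θ=0 decreasing through θ=1 increasing) and its
categorical features (θ plus feature-specific Gaussian noise, sd 0.15 by
default, cut at feature-specific random thresholds into 2–4 values; 8
features in each of the 7 categories). Missingness is completely at random
(default rate 0.2, with every language keeping at least one observed
feature). A severed-dependence switch redraws the feature latent
independently, giving an exact null for covariation tests. Defaults (30
languages, 200 sentences each, vocabulary 120, lengths 5–15) are sized so a
full-family pipeline runs in seconds while leaving the planted signal
recoverable.

What passing tests on these generators shows: the estimator chain recovers
planted positional structure, benefits from context exactly when the source
has it, and detects (with calibrated error rates) a planted dependence
between curve shape and feature structure. What it does not show: behavior
under Zipfian vocabularies, topical drift, real typological feature
dependencies, or WALS's highly structured missingness — all deliberately
absent from the generators.

## Numerical and size choices

* Discount fallback 0.75; probability normalization tolerance 1e-9
  (compensated summation).
* DBA: tol 1e-6 relative, max 100 iterations; deterministic tie-breaks.
* Imputation: tol 1e-6, max 200 iterations; rank capped at matrix rank − 1.
* Mantel: 999 permutations by default; p = (1 + #{|r*| ≥ |r|})/(N+1),
  one-sided variants available.
* Verification problem sizes: shape recovery uses 5,000-sentence corpora;
  context benefit 500-sentence Markov corpora; covariation 30-language
  families with full per-language pipelines, and a 500-replicate
  ground-truth-curve null for calibration. These sizes keep the full
  verification suite at desk scale while leaving each planted effect many
  standard errors above its sampling noise.

## Known limitations

* **DBA amplifies thin-support noise.** Per-length mean curves from lengths
  with very few sentences carry large sampling noise, and DTW's value-based
  alignment converts that noise into spurious barycenter shape (alignment
  routes high points to high coordinates). With heavy-tailed length
  distributions and small corpora, the barycenter of a truly flat process
  can show visible structure. Remedies: restrict the length range, weight
  per-length curves by support (the optional DBA weights), or use corpora
  large enough that every analyzed length is well supported.
* DBA is a local optimizer (see above); different initializations can give
  slightly different barycenters on adversarial inputs.
* The pair-level t-test is anti-conservative under matrix dependence; use
  the Mantel method for calibrated decisions.
* Single imputation underestimates the uncertainty added by imputed cells;
  correlations on imputed tables should be read as point summaries.
* The generators' word classes are uniform within class; none of the
  heavy-tailed within-class structure of real lexicons is modeled.
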