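# infocurve

Characteristic information curves of languages: per-word surprisal from
cross-validated n-gram models, aggregated across sentence lengths into a
fixed-length curve by dynamic time warping barycenter averaging, and compared
across languages against categorical typological similarity.

## The problem

The Uniform Information Density (UID) hypothesis predicts that speakers
spread information evenly across an utterance. Testing this within sentences
requires a position-by-position measure of information: the **surprisal** of
the word at position *i*,

    surprisal(w_i) = -log2 P(w_i)                       (unigram)
    surprisal(w_i) = -log2 P(w_i | w_{i-2}, w_{i-1})    (trigram)

estimated from a corpus with an n-gram language model under **modified
Kneser-Ney smoothing** (count-class discounts D1/D2/D3+ estimated from
counts-of-counts; lower orders weighted by continuation counts — the number
of distinct left contexts — so a word like "francisco" that is frequent but
occurs only after "san" gets little unigram weight). Surprisal is computed
with 10-fold cross-validation so no word is scored by a model that saw it.

Sentences of different lengths cannot be averaged position-wise, so the mean
surprisal curves of each observed length are summarized by **DTW Barycenter
Averaging (DBA)**: the length-K sequence (default K = 5) minimizing the
summed dynamic-time-warping distance to the per-length curves, fit by
expectation-maximization. The resulting barycenter is a language's
*characteristic information curve*. After mean-centering (surprisal level
tracks corpus size), curves are compared across languages by cosine
similarity, and that similarity matrix is correlated — with pair-level
t-tests and a Mantel permutation test — against the proportion of exactly
matching categorical typological features (WALS-style tables, with optional
iterative low-rank imputation of missing values).

The package is aimed at quantitative linguists and cognitive scientists who
want to compute these curves for their own corpora (plain text, one sentence
per line, whitespace-tokenized) or to study the method's behavior on
synthetic corpora with known ground truth.

## Worked example

A synthetic corpus with a planted "three-step" profile (low-information
start, mid-sentence plateau, penultimate dip, steep final rise):

```python
from infocurve.synthetic import GeneratorSpec, generate_positional_corpus
from infocurve.pipeline import characteristic_curve
from infocurve.curves import center_curve

spec = GeneratorSpec(positional_profile="three_step", n_sentences=2000, seed=7)
corpus, expected = generate_positional_corpus(spec)
print(f"{len(corpus)} sentences, {corpus.n_tokens} tokens")

bary = characteristic_curve(corpus, order=1, n_folds=10, k=5)
print("unigram barycenter (bits):", [round(v, 2) for v in bary.values])
print("centered:", [round(v, 2) for v in center_curve(bary).values])
```

prints

```
2000 sentences, 33812 tokens
unigram barycenter (bits): [6.13, 7.7, 7.61, 7.24, 9.2]
centered: [-1.44, 0.13, 0.03, -0.34, 1.63]
```

The recovered 5-point curve shows exactly the planted shape: a
low-information first position (6.1 bits), a plateau near 7.6 bits, a dip in
the fourth coordinate, and a steep final rise to 9.2 bits. The centered curve
is what enters cross-language comparisons.

The same stages are available from the shell:

```bash
infocurve simulate --kind family --n-languages 5 --n-sentences 300 \
    --min-len 5 --max-len 15 --vocabulary-size 120 --seed 1 --output-dir sim/
infocurve compare --typology sim/typology.csv --output-dir run/ \
    --register spoken --orders 1,3 \
    --corpus lang00=sim/lang00.txt --corpus lang01=sim/lang01.txt \
    --corpus lang02=sim/lang02.txt --corpus lang03=sim/lang03.txt \
    --corpus lang04=sim/lang04.txt
```

which writes per-language surprisal tables and barycenters, similarity
matrices, correlation tables, per-position variance profiles, and a Newick
dendrogram into `run/`.

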