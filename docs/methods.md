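# Methods

## Problem

Event-based surveillance teams read outbreak bulletins and (a) decide
whether each article describes an event worth a database entry, and
(b) reduce the article to one key fact per class: disease, country,
date, confirmed-case count. Both are modelled here: (b) as entity
filtering over an annotator's mentions, (a) as binary text
classification under strong class imbalance.

## Annotation

The annotator is a contract, not a commitment to a particular NER
stack: downstream code consumes `EntityMention` objects (class, span,
sentence index, normalised value) and works with any producer of them.
The bundled implementation is deliberately simple and fully
deterministic:

* **Sentences** split at terminal punctuation (`.!?`) followed by
  whitespace. No abbreviation handling; decimal points and ISO dates
  survive because the boundary requires trailing whitespace.
* **Diseases and places** come from two-column TSV gazetteers
  (surface → canonical). Matching is case-insensitive, word-boundary
  anchored, leftmost-longest, non-overlapping within a class — so
  "Democratic Republic of the Congo" wins over its substring "Congo".
* **Dates** cover ISO (`2018-05-10`), `10 May 2018`, `May 10, 2018`,
  and year-less forms resolved against a reference date (the article's
  publication date when known). A range (`2018-05-10 to 2018-05-12`)
  collapses to its midpoint: real annotators often return ranges, the
  downstream value must be a scalar, and the midpoint is the unbiased
  scalar choice; the three-day evaluation window absorbs the resulting
  error. Invalid calendar dates are skipped.
* **Counts** are digit groups with optional thousand separators.
  Date spans take precedence on overlapping digits, so a year never
  parses as a case count.

Known failure mode, kept on purpose as realism: a disease name that
embeds a place name ("Crimean-Congo haemorrhagic fever") also produces
a spurious geographic mention, occasionally misleading the country
filter — the analogue of the systematic annotator failures seen with
real tools.

## Key-entity filtering

*Most-frequent approach*: the mode of a class's mention values, ties
broken toward the value whose first occurrence is earliest (a
deterministic, order-respecting rule). The country is the mode of the
**first three** geographic mentions only, because bulletins name the
affected country early and neighbours later.

*Key-sentence approach*: sentences containing at least one mention of
the target class become training examples, labelled *key* iff some
mention matches the gold value — exact equality for counts, a ±3-day
window for dates. The window is the same one used at evaluation time;
labelling range-derived midpoints by exact match would produce almost
no positives, so the window is applied consistently in both places.

The classifier is a self-contained two-class naive Bayes with Laplace
smoothing α = 1 (the standard default):

* **Bernoulli** over binary presence vectors:
  P(t | c) = (n_{t,c} + 1) / (n_c + 2).
* **Multinomial** over tf-idf-weighted counts:
  θ_{t,c} = (W_{t,c} + 1) / (W_c + |V|), where W sums tf-idf weights.
  The tf-idf is max-normalised term frequency times ln(N / df), with N
  and the document frequencies frozen on the training sentences
  (natural logarithm: the base is a uniform rescaling; one fixed choice
  is documented and tested).

Both variants are verified against a brute-force Bayes-rule oracle over
every binary sentence of a ≤10-term vocabulary and against scikit-learn's
reference estimators on identical feature matrices; scikit-learn is
never the implementation. One model is trained per class (date, count),
matching the separate evaluation datasets the two classes produce.
Extraction takes the argmax-posterior sentence among those containing a
class mention and returns its first mention by offset — even when all
posteriors are below 0.5, some value is still the best available.

A training set duplicated example-for-example does *not* reproduce
bit-identical posteriors under α = 1 smoothing (the smoothed estimates
shift slightly with the sample size); correctness is asserted through
the closed-form oracle instead.

## Relevance scoring

Features are either count bag-of-words (for multinomial/complement
naive Bayes, whose event model matches occurrence counts) or
mean-pooled word embeddings (for logistic regression, kNN, SVM, MLP).
Out-of-vocabulary tokens are excluded from the mean rather than
contributing zero vectors, so short OOV-heavy documents are not pulled
toward the origin.

Embeddings are trained on the corpus itself by a count-based method:
positive pointwise mutual information over a symmetric 5-token
co-occurrence window, factorised by truncated SVD, embedding = U·√S
(100 dimensions by default — ample for the synthetic vocabulary;
deterministic given the seed). Count-based factorisation was chosen
over stochastic skip-gram training because it is exactly reproducible
and fast at the corpus sizes used here; externally trained skip-gram
vectors in word2vec text format are loadable through the same
`EmbeddingModel` interface and are interchangeable downstream. A
fixed-length (400-word, zero-padded) word-matrix representation is
provided for convolutional models; no convolutional classifier is
bundled (its architecture is deliberately out of scope, and no
deep-learning framework is a dependency).

**Up-sampling.** The minority class is inflated before fitting by a
literal three-step loop: pick a minority point uniformly, pick one of
its 5 nearest minority neighbours (Euclidean), emit a uniform convex
combination of the two; repeat until minority ≥ target ratio × majority
(1:1 default). Uniform selection of the seed point means this is the
SMOTE-like reading of the procedure — canonical ADASYN's
density-weighted seed selection is intentionally **not** implemented.
Consequence (tested): synthetic points never leave the convex hull of
the minority class. Up-sampling is applied to training folds only.

Splits are stratified (default 25% test; a 60/20/20 three-way split is
available for validation-hungry models). The decision threshold is
fixed at 0.5 and not optimised. Classifier hyperparameters are the
scikit-learn defaults, exposed but untuned. Scores order the reading
list; nothing is filtered out.

## Metrics

Precision, sensitivity, specificity, F1 from confusion counts; a
zero denominator raises a distinguished `UndefinedMetricError` rather
than silently returning 0, since silent zeros corrupt model
comparisons. IBA_α = (1 + α(sens − spec))·sens·spec with α = 0.1.
Two-decimal table comparisons use round-half-to-even. Key-extraction
accuracy: exact match except dates, correct within an inclusive ±3-day
window. ROC points are swept over unique scores and anchored at (0,0)
and (1,1).

## Synthetic corpus generator

The generator emulates the structural difficulty of real bulletins, not
their language:

* one **key sentence** per article ("As of {date}, {count} cases of
  {disease} have been confirmed in {country}.") placed at a random
  position after an intro sentence that names the disease and country;
* **distractors** drawn per article from a pool: a publication date
  repeated in two sentences (> 3 days from the key date), a cumulative
  regional total repeated twice (≠ key count), other countries, another
  disease, neutral filler. The repetitions make the most-frequent
  heuristic fail for date and count — exactly the failure observed on
  real news — while the key sentence's distinctive wording
  ("confirmed") keeps the sentence classifier learnable. Distractor
  dates are always more than 3 days from the key date, so the
  evaluation window is unambiguous on clean corpora.
* **relevance** is a known deterministic rule — relevant iff the
  disease is on a priority list AND the confirmed count reaches 100 —
  optionally flipped with probability `label_noise`. Exactly
  `round(n_articles · relevant_fraction)` articles satisfy the rule
  (default 5%), so imbalance is exact by construction. The rule gives
  classifier checks a known reference; the count half of the rule is
  nearly invisible to a mean-pooled embedding, so the learnable signal
  is genuine but imperfect, as in real relevance data.

Defaults: 100 articles, 5% relevant, 3–6 distractors, dates in 2018,
counts 5–2000, threshold 100, noise 0, seed 0.

What passing tests on this corpus do **not** show: robustness to real
news language (paraphrase, negation, syndromic descriptions,
multilinguality), annotator recall failures beyond the one embedded
place-name case, or transfer of the relevance signal to human
judgements of newsworthiness. A `corrupt` fixture (key-sentence
dropout, character noise) supports degradation studies but is not a
model of OCR error.

## Problem sizes and determinism

Unit and oracle tests run on toy inputs (vocabulary ≤ 10, corpora ≤ 80
articles). End-to-end recovery checks use a 1000-article corpus at 5%
relevance — large enough for ~37 minority training examples after the
25% stratified split, small enough to keep the whole suite around ten
seconds. All randomness flows through explicit integer seeds (NumPy
`default_rng`, scikit-learn `random_state`); every generator, split,
up-sampling and fit is reproducible bit-for-bit given the seed.

## Known limitations

* The sentence splitter has no abbreviation list; "Dr. Smith" splits.
* Gazetteer NER cannot find unlisted surface forms (no fuzzy matching).
* The naive Bayes models use no keyword features or hyperparameter
  tuning; both are documented extension points, not defaults.
* The relevance suite reports probabilities from scikit-learn's
  default calibrations (SVM via Platt scaling), which are only as good
  as those defaults.
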