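# epinews

Key-entity extraction and relevance scoring for outbreak news, for
event-based surveillance (EBS) teams and researchers. Public-health
agents sift daily through outbreak bulletins (WHO Disease Outbreak
News, ProMED and similar feeds), decide which articles describe a
database-worthy event, and type the event's key facts — *disease*,
*country*, *date*, *confirmed-case count* — into an incident database.
`epinews` automates both halves of that workflow and ships a synthetic
corpus generator so every stage can be developed and tested fully
offline.

## What it does

**1. Annotation.** A deterministic, pluggable annotator segments
sentences and recognises four entity classes: diseases and places by
case-insensitive, longest-match gazetteer lookup (bundled gazetteers:
70+ countries, 30+ diseases), dates and counts by regular expressions.
Date ranges collapse to their midpoint; digits inside a date never
become case counts.

**2. Key-entity filtering.** An article mentions many candidate values
per class; the incident database wants one. Two filters:

* *most-frequent approach*: the modal value among a class's mentions,
  restricted to the first three geographic mentions for the country.
  Works well for disease and country; fails for date and count, whose
  modes are dominated by publication dates and cumulative totals.
* *key-sentence approach*: a naive Bayes classifier (Bernoulli over
  binary bag-of-words vectors, or multinomial over tf-idf-weighted
  counts) scores each sentence's probability of being the *key*
  sentence — the one whose entity matches the database entry. The
  extracted date/count is the mention in the highest-scoring sentence
  that contains one, even when every sentence scores below 0.5.

  The tf-idf variant is max-normalised:
  `tfidf(t, d) = (f_{t,d} / max_{t'} f_{t',d}) · ln(N / df_t)`.

**3. Relevance scoring.** Articles are labelled *relevant* iff their
event belongs in the database — about 5% of articles, so the pipeline
up-samples the minority class by convex interpolation between nearest
minority neighbours until classes are 1:1, then fits any of six
classifiers (multinomial/complement naive Bayes on bag-of-words;
logistic regression, kNN, SVM, MLP on mean-pooled word embeddings).
Scores sort the analyst's reading list; they never filter it. The
headline metric is the **index balanced accuracy**

    IBA_α = (1 + α · (sensitivity − specificity)) · sensitivity · specificity,  α = 0.1

which rewards true-positive performance on imbalanced data. Dates count
as correct within an inclusive three-day window; everything else must
match exactly.

## Worked example

```bash
python examples/03_key_extraction.py
```

```
accuracy on 100 held-out articles (3-day window for dates):
  most-frequent : {'disease': 1.0, 'country': 0.95, 'date': 0.49, 'count': 0.37}
  key-sentence  : {'disease': 1.0, 'country': 0.95, 'date': 1.0, 'count': 1.0}
```

On a 400-article synthetic corpus the mode recovers disease and country
almost perfectly but picks the wrong date/count half the time (the
generator plants a twice-repeated publication date and cumulative
total, as real bulletins do); the key-sentence classifier, trained on
300 articles, recovers both on the held-out 100. See
`examples/04_relevance_scoring.py` for the imbalance story: logistic
regression without up-sampling reaches sensitivity 0.00 on a 5%-relevant
corpus, 0.58 with it.

The same workflow is available from a shell:

```bash
epinews synth --n 200 --seed 1 --out-corpus corpus.jsonl --out-gold gold.csv
epinews train-key --corpus corpus.jsonl --gold gold.csv --entity-class date --out date.json
epinews train-key --corpus corpus.jsonl --gold gold.csv --entity-class count --out count.json
epinews train-relevance --corpus corpus.jsonl --gold gold.csv --out rel.pkl \
    --embeddings-out emb.txt
epinews analyze --corpus corpus.jsonl --date-model date.json --count-model count.json \
    --relevance-model rel.pkl --embeddings emb.txt --out analysis.csv
epinews evaluate --analysis analysis.csv --gold gold.csv --out metrics.json
```

## Layout

- `src/epinews/corpus.py` — article/gold data model, JSONL + CSV I/O
- `src/epinews/annotate.py` — sentence splitting, gazetteer/regex NER
- `src/epinews/features.py` — bag-of-words, tf-idf, embeddings
- `src/epinews/keyinfo.py` — most-frequent filter, key-sentence naive Bayes
- `src/epinews/relevance.py` — splits, up-sampling, classifier suite
- `src/epinews/metrics.py` — precision/sensitivity/specificity/F1/IBA, ROC
- `src/epinews/synth.py` — synthetic corpus generator, corruption fixture
- `src/epinews/pipeline.py`, `src/epinews/cli.py` — composition and CLI
- `docs/methods.md` — models, assumptions, design choices, limitations
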