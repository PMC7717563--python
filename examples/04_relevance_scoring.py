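"""Score article relevance with logistic regression on document embeddings.

Demonstrates the imbalance problem (5% relevant): without minority
up-sampling the classifier all but ignores the positive class; with
up-sampling sensitivity recovers, at some cost in specificity.
"""

import numpy as np

from epinews.features import tokenize, train_embeddings
from epinews.metrics import confusion, evaluate
from epinews.pipeline import embedding_dataset
from epinews.relevance import (
    SplitSpec, fit_relevance, rank_articles, score_many, stratified_split,
)
from epinews.synth import GeneratorConfig, generate

corpus = generate(GeneratorConfig(n_articles=1000, relevant_fraction=0.05, seed=3))
embeddings = train_embeddings([tokenize(a.text) for a in corpus.articles],
                              dimension=100, seed=3)
dataset = embedding_dataset(corpus.articles, corpus.gold, embeddings)
train, test = stratified_split(dataset, SplitSpec(test_fraction=0.25, seed=3))
x_test = np.stack([d.dense() for d in test])
y_test = [d.label for d in test]

for upsample in (False, True):
    model = fit_relevance(train, "logistic_regression", seed=3, upsample=upsample)
    scores = score_many(model, x_test)
    y_pred = ["relevant" if s >= 0.5 else "irrelevant" for s in scores]
    c = confusion(y_test, y_pred, "relevant")
    sens = c.TP / (c.TP + c.FN)
    spec = c.TN / (c.TN + c.FP)
    print(f"up-sampling={upsample}:  sensitivity={sens:.2f}  specificity={spec:.2f}  "
          f"TP={c.TP} FN={c.FN}")

model = fit_relevance(train, "logistic_regression", seed=3)
ranked = rank_articles(list(zip([d.article_id for d in test], score_many(model, x_test))))
print("top of the reading list:", [a for a, _ in ranked[:5]])
# Scores sort the analyst's reading list; they never drop articles.
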