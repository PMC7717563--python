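"""Generate a small synthetic outbreak-news corpus with ground truth.

Each article hides its key facts (disease, country, date, confirmed-case
count) in one key sentence among distractor sentences; a gold record per
article carries those facts plus a relevance label (~5% relevant).
"""

from epinews.corpus import write_corpus, write_gold
from epinews.synth import GeneratorConfig, generate

corpus = generate(GeneratorConfig(n_articles=100, relevant_fraction=0.05, seed=42))
write_corpus(corpus.articles, "corpus.jsonl")
write_gold(corpus.gold, "gold.csv")

n_relevant = sum(g.relevant for g in corpus.gold)
print(f"articles: {len(corpus.articles)}  relevant: {n_relevant}")
print("--- first article ---")
print(corpus.articles[0].text)
print("--- its gold record ---")
print(corpus.gold[0])
# The printed counts show the engineered class imbalance (5 of 100 relevant);
# the gold record is what a perfect extraction pipeline should recover.
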