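import pytest

from epinews.annotate import Gazetteer
from epinews.pipeline import annotate_corpus
from epinews.synth import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-article synthetic corpus with ground truth."""
    return generate(GeneratorConfig(n_articles=60, relevant_fraction=0.1, seed=11))


@pytest.fixture(scope="session")
def small_docs(small_corpus):
    return annotate_corpus(small_corpus.articles)


@pytest.fixture()
def toy_disease_gazetteer():
    return Gazetteer({"cholera": "Cholera", "ebola": "Ebola virus disease"}, "disease")


@pytest.fixture()
def toy_geo_gazetteer():
    return Gazetteer(
        {
            "Democratic Republic of the Congo": "Democratic Republic of the Congo",
            "Congo": "Republic of the Congo",
            "France": "France",
            "Germany": "Germany",
            "United States": "United States",
        },
        "geo",
    )
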