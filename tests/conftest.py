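import numpy as np
import pytest

from pathkey.config import prepare_statements
from pathkey.preprocessing import normalize, train_wordpiece_vocabulary
from pathkey.synthetic import CorpusConfig, generate_corpus, iter_statements
from pathkey.similarity import Taxonomy


@pytest.fixture(scope="session")
def corpus():
    """A small separable corpus shared across tests (300 reports)."""
    return generate_corpus(CorpusConfig(n_reports=300, seed=11))


@pytest.fixture(scope="session")
def vocab(corpus):
    words = [w for _, text, _ in iter_statements(corpus)
             for w in normalize(text)]
    return train_wordpiece_vocabulary(words, size=2000)


@pytest.fixture(scope="session")
def tokenized(corpus, vocab):
    return prepare_statements(corpus, vocab)


@pytest.fixture(scope="session")
def fixture_taxonomy():
    """Hand-built ~30-node anatomy/diagnosis taxonomy for similarity tests.

    Depths (root = 1):
      entity(1)
        anatomy(2)
          organ(3)
            digestive(4): stomach(5), colon(5), liver(5)
              colon -> sigmoid(6), rectum(6)
            gland(4): thyroid(5), prostate(5)
          tissue(3): epithelium(4), mucosa(4)
        disease(2)
          neoplasm(3)
            benign(4): adenoma(5) -> tubular(6), villous(6); lipoma(5)
            malignant(4): carcinoma(5) -> adenocarcinoma(6), melanoma(6)?
          inflammation(3): gastritis(4), colitis(4)
        procedure(2): biopsy(3), excision(3)
    """
    parents = {
        "entity": (),
        "anatomy": ("entity",),
        "disease": ("entity",),
        "intervention": ("entity",),
        "organ": ("anatomy",),
        "tissue": ("anatomy",),
        "digestive": ("organ",),
        "gland": ("organ",),
        "stomach": ("digestive",),
        "colon": ("digestive",),
        "liver": ("digestive",),
        "sigmoid": ("colon",),
        "rectum": ("colon",),
        "thyroid": ("gland",),
        "prostate": ("gland",),
        "epithelium": ("tissue",),
        "mucosa": ("tissue",),
        "neoplasm": ("disease",),
        "inflammation": ("disease",),
        "benign": ("neoplasm",),
        "malignant": ("neoplasm",),
        "adenoma": ("benign",),
        "lipoma": ("benign",),
        "tubular": ("adenoma",),
        "villous": ("adenoma",),
        "carcinoma": ("malignant",),
        "adenocarcinoma": ("carcinoma",),
        "gastritis": ("inflammation",),
        "colitis": ("inflammation",),
        "biopsy": ("intervention",),
        "excision": ("intervention",),
    }
    word_senses = {w: frozenset({w}) for w in parents if w != "entity"}
    # a polysemous word: "polyp" maps to both a benign neoplasm sense and
    # a mucosa sense
    word_senses["polyp"] = frozenset({"benign", "mucosa"})
    return Taxonomy(parents=parents, word_senses=word_senses)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
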