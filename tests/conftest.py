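import pytest

from il17pred import (
    GeneratorConfig,
    SVMConfig,
    generate_corpus,
    train_svm,
)
from il17pred.evaluate import kfold_cv

POLY2 = SVMConfig(kernel="polynomial", d=2)


@pytest.fixture(scope="session")
def default_corpus():
    """The generator's default corpus: 300 positives / 800 negatives with
    the fully planted compositional signal."""
    return generate_corpus()


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced corpus for fast model-level tests."""
    return generate_corpus(GeneratorConfig(n_pos=80, n_neg=200, seed=3))


@pytest.fixture(scope="session")
def dpc_model(small_corpus):
    return train_svm(small_corpus, "DPC", POLY2)


@pytest.fixture(scope="session")
def cv_dpc_default(default_corpus):
    """10-fold CV of the polynomial-d2 DPC SVM on the default corpus
    (shared by the recovery and ordering checks)."""
    return kfold_cv(default_corpus, "DPC", "SVM", POLY2, k=10, seed=1)


@pytest.fixture(scope="session")
def cv_aac_default(default_corpus):
    return kfold_cv(default_corpus, "AAC", "SVM", POLY2, k=10, seed=1)
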