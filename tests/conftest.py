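import numpy as np
import pytest

from scfp import GenParams, MotifDetector, SCFPClassifier, generate_planted_dataset

ASPIRIN = "CC(=O)OC1=CC=CC=C1C(=O)O"  # canonical Kekulé form


@pytest.fixture(scope="session")
def aspirin():
    return ASPIRIN


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny balanced planted-motif set for fast unit tests."""
    return generate_planted_dataset(GenParams(n_active=30, n_inactive=30, seed=7))


@pytest.fixture(scope="session")
def planted_dataset():
    """The full planted-motif benchmark: 200 actives / 200 inactives,
    carboxy-like fragment C(=O)O planted in the actives."""
    return generate_planted_dataset(GenParams(n_active=200, n_inactive=200, seed=1))


@pytest.fixture(scope="session")
def planted_split(planted_dataset):
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(planted_dataset.ids))
    tr, te = train_test_split(idx, test_size=0.25, stratify=planted_dataset.labels, random_state=1)
    return tr, te


@pytest.fixture(scope="session")
def trained_classifier(planted_dataset, planted_split):
    """Default-architecture network trained 30 epochs on the benchmark.

    Session-scoped: the motif-recovery, chemical-space and end-to-end
    acceptance tests all reuse this single training run.
    """
    tr, te = planted_split
    smiles = np.array(planted_dataset.smiles)
    clf = SCFPClassifier(max_len=100, epochs=30, random_state=1)
    clf.fit(list(smiles[tr]), planted_dataset.labels[tr],
            list(smiles[te]), planted_dataset.labels[te])
    return clf


@pytest.fixture(scope="session")
def screening_reference(planted_dataset):
    """Reference set for filter statistics with screening-like composition.

    Motif calling at Z > 2.58 presumes the reference distribution is
    dominated by inactives (as in real assay collections, ~1:10); a
    balanced reference caps attainable Z-scores near sqrt((1-p)/p) = 1.
    """
    extra = generate_planted_dataset(GenParams(n_active=0, n_inactive=1800, seed=2))
    return list(planted_dataset.smiles) + list(extra.smiles)


@pytest.fixture(scope="session")
def fitted_detector(trained_classifier, screening_reference):
    return MotifDetector(trained_classifier).fit(screening_reference)


@pytest.fixture(scope="session")
def tiny_classifier(small_dataset):
    """Small fast model for tests that only need a trained network."""
    clf = SCFPClassifier(max_len=80, conv1_filters=16, conv2_filters=8,
                         hidden_units=8, epochs=8, random_state=3)
    clf.fit(small_dataset.smiles, small_dataset.labels)
    return clf
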