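"""Scikit-learn estimator interface to the SMILES convolution network.

:class:`SCFPClassifier` is a binary classifier over SMILES strings (or
pre-featurized matrices) exposing ``fit`` / ``predict`` / ``predict_proba``
and, as a transformer, ``transform`` returning the learned fingerprints —
so it composes with sklearn pipelines and model selection.
:class:`MotifDetector` fits per-filter reference statistics on a dataset and
calls motifs on individual compounds.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .featurizer import FeaturizerConfig, featurize
from .model import ModelConfig, SCFPNetwork, build_model
from .motif import MOTIF_Z_THRESHOLD, detect_motifs, fit_filter_stats, normalize_scfp
from .training import TrainConfig, compute_scfp_batch, evaluate_roc_auc, predict_scores, train


def _as_matrices(X, max_len: int):
    """Accept a list of SMILES or an (n, L, 42) array; return (X, valid_lens)."""
    if isinstance(X, np.ndarray) and X.ndim == 3:
        # padded rows are all-zero by construction; recover valid lengths
        nonzero = np.abs(X).sum(axis=2) > 0
        lens = np.where(nonzero.any(axis=1), X.shape[1] - nonzero[:, ::-1].argmax(axis=1), 0)
        return X, lens.astype(np.int64)
    cfg = FeaturizerConfig(max_len=max_len)
    fms = [featurize(s, cfg) for s in X]
    return np.stack([f.values for f in fms]), np.array([f.valid_len for f in fms], dtype=np.int64)


class SCFPClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Two-stage 1-D CNN classifier on SMILES feature matrices.

    Parameters mirror the architecture and training knobs: ``conv1_*`` /
    ``pool1_*`` / ``conv2_*`` describe the convolution stages (windows of 7
    with stride 1 by default), ``scfp_dim`` is the number of second-stage
    filters and hence the fingerprint length, and training runs Adam at
    ``learning_rate`` 0.01 on binary cross-entropy for ``epochs`` epochs.

    Attributes after fitting: ``model_`` (the trained network),
    ``history_`` (per-epoch loss / validation AUC), ``classes_``.
    """

    def __init__(
        self,
        max_len: int = 400,
        conv1_filters: int = 128,
        conv1_window: int = 7,
        conv1_stride: int = 1,
        pool1_type: str = "average",
        pool1_window: int = 7,
        pool1_stride: int = 1,
        conv2_filters: int = 64,
        conv2_window: int = 7,
        conv2_stride: int = 1,
        pool2_type: str = "none",
        hidden_units: int = 96,
        activation: str = "leaky_relu",
        batch_norm: bool = False,
        dropout: float = 0.0,
        mask_padding: bool = True,
        optimizer: str = "adam",
        learning_rate: float = 0.01,
        minibatch_size: int = 32,
        loss: str = "cross-entropy",
        epochs: int = 20,
        patience: int | None = None,
        random_state: int = 0,
    ):
        self.max_len = max_len
        self.conv1_filters = conv1_filters
        self.conv1_window = conv1_window
        self.conv1_stride = conv1_stride
        self.pool1_type = pool1_type
        self.pool1_window = pool1_window
        self.pool1_stride = pool1_stride
        self.conv2_filters = conv2_filters
        self.conv2_window = conv2_window
        self.conv2_stride = conv2_stride
        self.pool2_type = pool2_type
        self.hidden_units = hidden_units
        self.activation = activation
        self.batch_norm = batch_norm
        self.dropout = dropout
        self.mask_padding = mask_padding
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.minibatch_size = minibatch_size
        self.loss = loss
        self.epochs = epochs
        self.patience = patience
        self.random_state = random_state

    # -- config plumbing ------------------------------------------------

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            conv1_filters=self.conv1_filters,
            conv1_window=self.conv1_window,
            conv1_stride=self.conv1_stride,
            pool1_type=self.pool1_type,
            pool1_window=self.pool1_window,
            pool1_stride=self.pool1_stride,
            conv2_filters=self.conv2_filters,
            conv2_window=self.conv2_window,
            conv2_stride=self.conv2_stride,
            pool2_type=self.pool2_type,
            hidden_units=self.hidden_units,
            activation=self.activation,
            batch_norm=self.batch_norm,
            dropout=self.dropout,
            mask_padding=self.mask_padding,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            minibatch_size=self.minibatch_size,
            loss=self.loss,
            epochs=self.epochs,
            seed=self.random_state,
            patience=self.patience,
        )

    # -- estimator API --------------------------------------------------

    def fit(self, X, y, X_valid=None, y_valid=None):
        y = np.asarray(y, dtype=float)
        Xm, lens = _as_matrices(X, self.max_len)
        vXm = vlens = None
        if X_valid is not None:
            vXm, vlens = _as_matrices(X_valid, self.max_len)
        self.model_ = build_model(self.model_config(), seed=self.random_state)
        _, self.history_ = train(
            self.model_, Xm, y, vXm, y_valid,
            config=self.train_config(),
            train_valid_lens=lens, valid_valid_lens=vlens,
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        Xm, lens = _as_matrices(X, self.max_len)
        p = predict_scores(self.model_, Xm, lens)
        return np.column_stack([1 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def transform(self, X) -> np.ndarray:
        """Fingerprints: one SCFP row per compound."""
        check_is_fitted(self, "model_")
        Xm, lens = _as_matrices(X, self.max_len)
        return compute_scfp_batch(self.model_, Xm, lens)

    def score_auc(self, X, y) -> float:
        check_is_fitted(self, "model_")
        Xm, lens = _as_matrices(X, self.max_len)
        return evaluate_roc_auc(self.model_, Xm, y, lens)


class MotifDetector(BaseEstimator):
    """Motif caller bound to a trained classifier (or raw network).

    ``fit(X)`` estimates per-filter global-max statistics on a reference
    dataset; ``detect(smiles)`` returns :class:`~scfp.motif.MotifHit` lists;
    ``transform(X)`` returns Z-scored fingerprints.
    """

    def __init__(self, classifier=None, threshold: float = MOTIF_Z_THRESHOLD, max_len: int = 400):
        self.classifier = classifier
        self.threshold = threshold
        self.max_len = max_len

    def _network(self) -> SCFPNetwork:
        if isinstance(self.classifier, SCFPNetwork):
            return self.classifier
        if self.classifier is None:
            raise ValueError("MotifDetector needs a classifier or network")
        check_is_fitted(self.classifier, "model_")
        return self.classifier.model_

    def _max_len(self) -> int:
        if isinstance(self.classifier, SCFPClassifier):
            return self.classifier.max_len
        return self.max_len

    def fit(self, X, y=None):
        Xm, lens = _as_matrices(X, self._max_len())
        self.stats_ = fit_filter_stats(self._network(), Xm, lens)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "stats_")
        Xm, lens = _as_matrices(X, self._max_len())
        return normalize_scfp(compute_scfp_batch(self._network(), Xm, lens), self.stats_)

    def detect(self, smiles: str, compound_id: str = ""):
        check_is_fitted(self, "stats_")
        return detect_motifs(
            self._network(), smiles, self.stats_,
            threshold=self.threshold, max_len=self._max_len(), compound_id=compound_id,
        )
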