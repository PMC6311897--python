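"""Mini-batch training, ROC-AUC evaluation and five-fold cross-validation.

The network is trained by mini-batch stochastic gradient descent with Adam
at learning rate 0.01 on the binary cross-entropy of the sigmoid output.
All randomness (shuffling, initialization) is derived from a single seed, so
a run is bit-reproducible on CPU.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import _nn
from .model import ModelConfig, SCFPNetwork, build_model

logger = logging.getLogger(__name__)

_OPTIMIZERS = {"adam": _nn.Adam, "adagrad": _nn.AdaGrad}
_LOSSES = {"cross-entropy": _nn.bce_with_logits, "mean-squared-error": _nn.mse_on_probs}
MINIBATCH_CHOICES = (32, 64, 128, 256, 512)


class TrainingError(ValueError):
    pass


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.01
    minibatch_size: int = 32
    loss: str = "cross-entropy"
    epochs: int = 20
    seed: int = 0
    patience: int | None = None  # early stop on validation AUC, off by default
    class_weight: str | None = None  # "balanced" reweights the loss; off by default

    def __post_init__(self):
        if self.optimizer not in _OPTIMIZERS:
            raise TrainingError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in _LOSSES:
            raise TrainingError(f"unknown loss {self.loss!r}")
        if self.learning_rate <= 0:
            raise TrainingError("learning_rate must be > 0")
        if self.minibatch_size < 1:
            raise TrainingError("minibatch_size must be >= 1")
        if self.epochs < 1:
            raise TrainingError("epochs must be >= 1")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    valid_auc: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)


def _check_binary(y: np.ndarray, what: str):
    classes = np.unique(y[~np.isnan(y)])
    if classes.size < 2:
        raise TrainingError(f"{what} contains a single class; need both 0 and 1")
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise TrainingError(f"{what} labels must be binary 0/1, got {classes}")


def evaluate_roc_auc(model: SCFPNetwork, X, y, valid_lens=None, batch_size: int = 256) -> float:
    """Rank-based area under the ROC curve of model scores against labels."""
    y = np.asarray(y, dtype=float)
    _check_binary(y, "evaluation set")
    scores = predict_scores(model, X, valid_lens, batch_size)
    return float(roc_auc_score(y, scores))


def predict_scores(model: SCFPNetwork, X, valid_lens=None, batch_size: int = 256) -> np.ndarray:
    """Sigmoid output probabilities, batched to bound memory."""
    X = np.asarray(X)
    out = []
    for lo in range(0, len(X), batch_size):
        vl = None if valid_lens is None else np.asarray(valid_lens)[lo : lo + batch_size]
        out.append(model.forward(X[lo : lo + batch_size], valid_lens=vl)["probs"].ravel())
    return np.concatenate(out)


def compute_scfp_batch(model: SCFPNetwork, X, valid_lens=None, batch_size: int = 256) -> np.ndarray:
    """(n, scfp_dim) fingerprints for a stacked feature-matrix array."""
    X = np.asarray(X)
    out = []
    for lo in range(0, len(X), batch_size):
        vl = None if valid_lens is None else np.asarray(valid_lens)[lo : lo + batch_size]
        out.append(model.forward(X[lo : lo + batch_size], valid_lens=vl)["scfp"])
    return np.concatenate(out)


def train(
    model: SCFPNetwork,
    X_train,
    y_train,
    X_valid=None,
    y_valid=None,
    config: TrainConfig | None = None,
    train_valid_lens=None,
    valid_valid_lens=None,
) -> tuple[SCFPNetwork, History]:
    """Train in place; returns the model and the per-epoch history.

    Validation AUC is recorded each epoch when a validation set is given;
    with ``patience`` set, training stops once the validation AUC has not
    improved for that many epochs.
    """
    config = config or TrainConfig()
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=float)
    if len(X_train) == 0:
        raise TrainingError("empty training set")
    _check_binary(y_train, "training set")

    loss_fn = _LOSSES[config.loss]
    opt = _OPTIMIZERS[config.optimizer](model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = History()
    n = len(X_train)
    sample_w = None
    if config.class_weight == "balanced":
        pos = y_train.mean()
        sample_w = np.where(y_train == 1, 0.5 / max(pos, 1e-12), 0.5 / max(1 - pos, 1e-12))

    best_auc, since_best = -np.inf, 0
    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.minibatch_size):
            idx = order[lo : lo + config.minibatch_size]
            vl = None if train_valid_lens is None else np.asarray(train_valid_lens)[idx]
            out = model.forward(X_train[idx], valid_lens=vl, train=True, rng=rng)
            loss, dz = loss_fn(out["logits"], y_train[idx])
            if sample_w is not None:
                w = sample_w[idx].reshape(-1, 1)
                dz = dz * w
                loss = float(loss * np.mean(sample_w[idx]))
            grads = model.backward(out, dz)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / n)

        if X_valid is not None and y_valid is not None:
            auc = evaluate_roc_auc(model, X_valid, y_valid, valid_valid_lens)
            history.valid_auc.append(auc)
            if config.patience is not None:
                if auc > best_auc:
                    best_auc, since_best = auc, 0
                else:
                    since_best += 1
                    if since_best >= config.patience:
                        history.epoch_seconds.append(time.perf_counter() - t0)
                        logger.info("early stop at epoch %d", epoch + 1)
                        break
        history.epoch_seconds.append(time.perf_counter() - t0)
        logger.info(
            "epoch %d: loss=%.4f%s (%.1fs)",
            epoch + 1,
            history.train_loss[-1],
            f" val_auc={history.valid_auc[-1]:.3f}" if history.valid_auc else "",
            history.epoch_seconds[-1],
        )
    model.trained = True
    return model, history


def cross_validate(
    X,
    y,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    valid_lens=None,
) -> dict:
    """Stratified k-fold cross-validation; returns per-fold and mean AUC.

    Folds are label-stratified (class proportions within one compound of
    each other across folds) and each compound lands in exactly one
    validation fold.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    if k < 2:
        raise TrainingError("k must be >= 2")
    if len(X) < k:
        raise TrainingError(f"dataset of {len(X)} too small for {k} folds")
    _check_binary(y, "dataset")
    counts = np.bincount(y.astype(int))
    if counts.min() < k:
        raise TrainingError(f"cannot stratify: smallest class has {counts.min()} < k={k} members")

    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs, assignments = [], np.empty(len(X), dtype=int)
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        assignments[va] = fold
        model = build_model(model_config, seed=seed + fold)
        cfg = TrainConfig(**{**train_config.__dict__, "seed": seed + fold})
        vl_tr = None if valid_lens is None else np.asarray(valid_lens)[tr]
        vl_va = None if valid_lens is None else np.asarray(valid_lens)[va]
        train(model, X[tr], y[tr], config=cfg, train_valid_lens=vl_tr)
        fold_aucs.append(evaluate_roc_auc(model, X[va], y[va], vl_va))
        logger.info("fold %d/%d: auc=%.3f", fold + 1, k, fold_aucs[-1])
    return {
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)),
        "sd_auc": float(np.std(fold_aucs, ddof=1)),
        "fold_assignments": assignments,
    }
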