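"""Bilayer fully connected network and the 5-fold evaluation protocol.

The classifier is a two-hidden-layer perceptron (512 and 248 ReLU units by
default) with a softmax output over the emotional states, trained by
mini-batch stochastic gradient descent on flattened spectral feature rows.
Training follows a fixed protocol:

* up to 500 epochs, stopping early when the validation loss has not improved
  for 20 consecutive epochs (best weights restored);
* 10% of the training split held out as the validation set;
* initial learning rate 0.001; after 10 consecutive epochs without
  validation-loss improvement the rate is multiplied by ``lr_factor``
  (default 1.25 — note this *increases* the rate on plateau; set
  0.75 for the conventional decay);
* per-feature standardization fitted on the training split only.

Evaluation is stratified 5-fold cross-validation: each fold trains on the
remaining four and is scored on the held-out fold, so every trial is tested
exactly once.  Accuracy, per-class precision/recall/F1 and confusion
matrices are aggregated into an :class:`EvalReport`.

The trainer is implemented directly on NumPy so the epoch-level protocol
(loss histories, patience counters, learning-rate schedule) is explicit and
deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, DataError
from .feature_builder import FeatureTensor

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "NeuralNetClassifier",
    "EvalReport",
    "make_folds",
    "train_classifier",
    "cross_validate",
    "metrics_from_confusion",
]


@dataclass
class TrainConfig:
    """Network architecture and training-protocol parameters."""

    hidden_sizes: tuple[int, ...] = (512, 248)
    loss: str = "categorical_ce"  # or "per_class_bce"
    max_epochs: int = 500
    early_stop_patience: int = 20  # epochs without val-loss improvement
    initial_lr: float = 0.001
    lr_patience: int = 10  # stagnant epochs before adjusting the rate
    lr_factor: float = 1.25
    batch_size: int = 16
    k_folds: int = 5
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ConfigError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.k_folds < 2:
            raise ConfigError(f"k_folds must be >= 2, got {self.k_folds}")
        if any(h < 1 for h in self.hidden_sizes):
            raise ConfigError("hidden sizes must be positive")
        if self.loss not in ("categorical_ce", "per_class_bce"):
            raise ConfigError(f"unknown loss {self.loss!r}")
        if self.max_epochs < 1 or self.initial_lr <= 0:
            raise ConfigError("max_epochs and initial_lr must be positive")


def make_folds(n_trials: int, labels: list[str] | np.ndarray, k: int,
               seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, disjoint, exhaustive k-fold split of trial indices.

    Falls back to an unstratified split (with a warning) when some class has
    fewer members than ``k``.
    """
    labels = np.asarray(labels)
    if n_trials < k:
        raise DataError(f"cannot make {k} folds from {n_trials} trials")
    if len(labels) != n_trials:
        raise DataError("labels length must equal n_trials")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} < k={k} members; "
            "falling back to unstratified folds", stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros(n_trials))]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n_trials), labels)]


@dataclass
class TrainingHistory:
    """Epoch-level record of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_epoch: int = 0
    lr_changes: list[int] = field(default_factory=list)  # epochs where lr changed


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class NeuralNetClassifier:
    """Minimal fully connected softmax classifier trained with SGD."""

    def __init__(self, cfg: TrainConfig, classes: np.ndarray):
        self.cfg = cfg
        self.classes = np.asarray(classes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self.scaler: StandardScaler | None = None
        self.history = TrainingHistory()

    # -- forward/backward ---------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = (n_features, *self.cfg.hidden_sizes, len(self.classes))
        # single-precision throughout: halves the gemm cost at these sizes
        # with no effect on the protocol
        self.weights = [
            (rng.standard_normal((a, b)) * np.sqrt(2.0 / a)).astype(np.float32)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [np.zeros(b, dtype=np.float32) for b in sizes[1:]]

    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [x]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            acts.append(np.maximum(acts[-1] @ w + b, 0.0))  # ReLU
        probs = _softmax(acts[-1] @ self.weights[-1] + self.biases[-1])
        return acts, probs

    def _loss(self, probs: np.ndarray, onehot: np.ndarray) -> float:
        p = np.clip(probs, 1e-12, 1 - 1e-12)
        if self.cfg.loss == "categorical_ce":
            return float(-np.mean(np.sum(onehot * np.log(p), axis=1)))
        # mean binary cross-entropy over the class outputs
        return float(-np.mean(onehot * np.log(p) + (1 - onehot) * np.log(1 - p)))

    def _grad_logits(self, probs: np.ndarray, onehot: np.ndarray) -> np.ndarray:
        n, c = probs.shape
        if self.cfg.loss == "categorical_ce":
            return (probs - onehot) / n
        p = np.clip(probs, 1e-12, 1 - 1e-12)
        dl_dp = (-onehot / p + (1 - onehot) / (1 - p)) / (n * c)
        # back through softmax: dz = p * (dl_dp - <dl_dp, p>)
        inner = np.sum(dl_dp * p, axis=1, keepdims=True)
        return p * (dl_dp - inner)

    def _step(self, x: np.ndarray, onehot: np.ndarray, lr: float) -> float:
        """One SGD minibatch update; returns the pre-update batch loss."""
        acts, probs = self._forward(x)
        loss = self._loss(probs, onehot)
        delta = self._grad_logits(probs, onehot).astype(np.float32)
        for i in range(len(self.weights) - 1, -1, -1):
            gw = acts[i].T @ delta
            gb = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
            self.weights[i] -= lr * gw
            self.biases[i] -= lr * gb
        return loss

    # -- training -----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray) -> "NeuralNetClassifier":
        """Standardize, split off the inner validation set, and train."""
        cfg = self.cfg
        x = np.asarray(x, dtype=float)
        if not np.isfinite(x).all():
            raise DataError("non-finite feature values")
        if len(np.unique(y)) < 2:
            raise DataError("degenerate single-class training split")
        rng = np.random.default_rng(cfg.seed)

        self.scaler = StandardScaler().fit(x)
        xs = self.scaler.transform(x).astype(np.float32)
        onehot = (y[:, None] == self.classes[None, :]).astype(np.float32)

        # stratified inner validation split; classes with a single member
        # stay in training (too small to spare a validation example)
        val_idx: list[int] = []
        for cls in self.classes:
            members = np.flatnonzero(y == cls)
            if len(members) < 2:
                continue
            rng.shuffle(members)
            n_val = max(1, int(round(cfg.val_fraction * len(members))))
            val_idx.extend(members[:n_val])
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[val_idx] = True
        if val_mask.all() or not val_mask.any():
            # degenerate tiny split: monitor the training loss instead
            val_mask[:] = False
        x_tr, y_tr = xs[~val_mask], onehot[~val_mask]
        if val_mask.any():
            x_va, y_va = xs[val_mask], onehot[val_mask]
        else:
            x_va, y_va = x_tr, y_tr

        self._init_params(xs.shape[1], rng)
        hist = self.history = TrainingHistory()
        lr = cfg.initial_lr
        best_val = np.inf
        best_params: tuple[list[np.ndarray], list[np.ndarray]] | None = None
        since_best = 0

        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(x_tr))
            batch_losses = []
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                batch_losses.append(self._step(x_tr[sel], y_tr[sel], lr))

            _, p_va = self._forward(x_va)
            hist.train_loss.append(float(np.mean(batch_losses)))
            hist.val_loss.append(self._loss(p_va, y_va))
            hist.learning_rates.append(lr)
            hist.stop_epoch = epoch

            if hist.val_loss[-1] < best_val:
                best_val = hist.val_loss[-1]
                best_params = ([w.copy() for w in self.weights],
                               [b.copy() for b in self.biases])
                hist.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best % cfg.lr_patience == 0:
                    lr *= cfg.lr_factor
                    hist.lr_changes.append(epoch)
                if since_best >= cfg.early_stop_patience:
                    break

        if best_params is not None:
            self.weights, self.biases = best_params
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            raise DataError("classifier is not fitted")
        xs = self.scaler.transform(np.asarray(x, dtype=float)).astype(np.float32)
        _, probs = self._forward(xs)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(x), axis=1)]


def train_classifier(features: np.ndarray, labels: np.ndarray | list[str],
                     cfg: TrainConfig | None = None) -> NeuralNetClassifier:
    """Train one network on flattened feature rows; deterministic given seed."""
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    return NeuralNetClassifier(cfg, classes).fit(np.asarray(features, float), labels)


def metrics_from_confusion(confusion: np.ndarray) -> dict:
    """Per-class precision/recall/F1 from a square count matrix.

    Rows are true classes, columns predictions.  Zero denominators yield 0
    and set the ``degenerate`` flag for that class.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
        raise DataError("confusion must be a square non-negative matrix")
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    degenerate = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    for i in range(c.shape[0]):
        if tp[i] + fp[i] == 0 or tp[i] + fn[i] == 0:
            degenerate.append(i)
    return {"precision": precision, "recall": recall, "f1": f1,
            "degenerate_classes": degenerate}


@dataclass
class EvalReport:
    """Cross-validation outcome: accuracies, per-class metrics, confusions."""

    class_names: list[str]
    fold_accuracies: list[float]
    confusion_matrices: list[np.ndarray]  # one per fold
    stop_epochs: list[int]
    config: dict
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum(self.confusion_matrices, axis=0)

    @property
    def per_class_metrics(self) -> dict:
        return metrics_from_confusion(self.pooled_confusion)

    def to_json(self, path: str | None = None) -> dict:
        m = self.per_class_metrics
        doc = {
            "class_names": self.class_names,
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "precision": m["precision"].tolist(),
            "recall": m["recall"].tolist(),
            "f1": m["f1"].tolist(),
            "confusion_matrices": [c.tolist() for c in self.confusion_matrices],
            "stop_epochs": self.stop_epochs,
            "config": self.config,
            "seed": self.seed,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=2)
        return doc


def cross_validate(tensor: FeatureTensor, cfg: TrainConfig | None = None,
                   labels: list[str] | None = None) -> EvalReport:
    """Stratified k-fold evaluation of the network on a feature tensor.

    ``labels`` overrides the tensor's own labels (e.g. for permutation
    controls).  Per-fold training uses an inner 10% validation split; the
    standardizer is fitted on each training split only, so held-out folds
    never leak into it.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(labels if labels is not None else tensor.labels)
    x = tensor.flattened()
    if len(y) != x.shape[0]:
        raise DataError("label count does not match trial count")
    classes = np.unique(y)
    folds = make_folds(x.shape[0], y, cfg.k_folds, cfg.seed)

    fold_acc, confusions, stops = [], [], []
    for fold_id, (tr, te) in enumerate(folds):
        fold_cfg = TrainConfig(**{**asdict(cfg),
                                  "seed": int(np.random.default_rng(
                                      [cfg.seed, fold_id]).integers(2 ** 31))})
        net = NeuralNetClassifier(fold_cfg, classes).fit(x[tr], y[tr])
        pred = net.predict(x[te])
        fold_acc.append(float(np.mean(pred == y[te])))
        conf = np.zeros((len(classes), len(classes)), dtype=int)
        for yt, yp in zip(y[te], pred):
            conf[np.searchsorted(classes, yt), np.searchsorted(classes, yp)] += 1
        confusions.append(conf)
        stops.append(net.history.stop_epoch)

    return EvalReport(
        class_names=[str(c) for c in classes],
        fold_accuracies=fold_acc,
        confusion_matrices=confusions,
        stop_epochs=stops,
        config=asdict(cfg),
        seed=cfg.seed,
    )
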