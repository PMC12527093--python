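"""Weighted cross-entropy training with Adam, early stopping, and
subject-wise k-fold cross-validation.

Protocol: Adam (beta1 = 0.9, beta2 = 0.999, lr = 5e-6) on shuffled
mini-batches of 64, weighted cross-entropy with mean-normalised
inverse-frequency class weights, L2 weight decay 1e-3 on convolution/linear
weights (not on norm parameters or biases), early stopping on validation
accuracy with patience 20 and restoration of the best checkpoint, 10-fold
cross-validation with subject-disjoint splits.

The default learning rate is unusually small for Adam from scratch but is the
pinned protocol value; callers can (and the quick smoke problems do) raise it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import ConfusionMatrix, confusion_matrix, summary_metrics
from .model import LMCSleepNet, ModelConfig
from .nn import Parameter, softmax

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainResult",
    "Adam",
    "EarlyStopping",
    "compute_class_weights",
    "weighted_cross_entropy",
    "train",
    "make_folds",
    "cross_validate",
]

N_CLASSES = 5


@dataclass
class TrainConfig:
    lr: float = 5e-6
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    weight_decay: float = 1e-3
    patience: int = 20
    max_epochs: int = 200
    folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("lr", "beta1", "beta2", "batch_size", "weight_decay",
                     "max_epochs", "folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class FoldSplit:
    fold_id: int
    train_subjects: list
    val_subjects: list

    def __post_init__(self):
        if set(self.train_subjects) & set(self.val_subjects):
            raise ValueError("train and validation subject sets overlap")


@dataclass
class TrainResult:
    history: list  # (epoch, train_loss, val_accuracy), 1-indexed epochs
    best_epoch: int
    best_val_accuracy: float
    confusion: ConfusionMatrix


# ---------------------------------------------------------------------------
# loss and class weights
# ---------------------------------------------------------------------------


def compute_class_weights(counts) -> np.ndarray:
    """Mean-normalised inverse-frequency weights: w_c = N / (K * n_c)."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        missing = np.where(counts <= 0)[0].tolist()
        raise ValueError(
            f"class(es) {missing} have no samples; drop or merge them before "
            "computing inverse-frequency weights")
    return counts.sum() / (len(counts) * counts)


def weighted_cross_entropy(probabilities, labels, weights) -> float:
    """Mean over the batch of -w_y * log P_y (log clamped at 1e-12)."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    p_true = probabilities[np.arange(len(labels)), labels]
    return float(np.mean(-weights[labels] * np.log(np.maximum(p_true, 1e-12))))


def _loss_and_grad(logits, labels, weights):
    """Softmax + weighted CE fused: returns (loss, dloss/dlogits)."""
    probs = softmax(logits, axis=1)
    loss = weighted_cross_entropy(probs, labels, weights)
    b = len(labels)
    grad = probs.astype(np.float64)
    grad[np.arange(b), labels] -= 1.0
    grad *= weights[labels][:, None] / b
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# optimizer and early stopping
# ---------------------------------------------------------------------------


class Adam:
    """Adam with coupled L2 weight decay on decay-flagged parameters only."""

    def __init__(self, params: list, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, weight_decay: float = 0.0,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without strict improvement.

    Ties do not reset patience.  ``update`` returns True when training should
    stop; the caller restores the checkpoint from ``best_epoch``.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_value = -np.inf
        self.best_epoch = 0
        self._since = 0
        self._epoch = 0

    def update(self, value: float) -> bool:
        self._epoch += 1
        if value > self.best_value:
            self.best_value = value
            self.best_epoch = self._epoch
            self._since = 0
            return False
        self._since += 1
        return self._since >= max(1, self.patience)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def _accuracy_and_confusion(model, x, y, batch_size):
    pred = model.predict(x, batch_size=batch_size)
    cm = confusion_matrix(y, pred)
    return float((pred == y).mean()), cm


def train(model: LMCSleepNet, train_data, val_data,
          config: TrainConfig | None = None, class_weights=None,
          log=None) -> TrainResult:
    """Train on ``(X, y)`` tuples; early-stop on validation accuracy.

    Class weights default to mean-normalised inverse frequency of the
    training labels.  Deterministic given ``config.seed`` on one device.
    """
    config = config or TrainConfig()
    config.validate()
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation split")
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)

    if class_weights is None:
        counts = np.bincount(y_train, minlength=N_CLASSES)
        class_weights = compute_class_weights(counts)
    class_weights = np.asarray(class_weights, dtype=np.float64)

    rng = np.random.default_rng(config.seed)
    model.dropout.rng = np.random.default_rng(rng.integers(0, 2**31))
    optimizer = Adam(model.parameters(), lr=config.lr, beta1=config.beta1,
                     beta2=config.beta2, weight_decay=config.weight_decay)
    stopper = EarlyStopping(config.patience)
    history = []
    best_state = model.state_dict()

    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x_train[idx])
            loss, dlogits = _loss_and_grad(logits, y_train[idx], class_weights)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        model.eval()
        val_acc, _ = _accuracy_and_confusion(model, x_val, y_val,
                                             config.batch_size)
        history.append((epoch, float(np.mean(losses)), val_acc))
        if log is not None:
            log(f"epoch {epoch}: train loss {np.mean(losses):.4f}, "
                f"val acc {val_acc:.4f}")
        stop = stopper.update(val_acc)
        if stopper.best_epoch == epoch:  # new best this epoch
            best_state = model.state_dict()
        if stop:
            break

    model.load_state_dict(best_state)
    model.eval()
    _, cm = _accuracy_and_confusion(model, x_val, y_val, config.batch_size)
    return TrainResult(history=history, best_epoch=stopper.best_epoch,
                       best_val_accuracy=float(stopper.best_value),
                       confusion=cm)


def make_folds(subjects, n_folds: int, seed: int = 0) -> list:
    """Partition unique subject ids into ``n_folds`` disjoint validation sets
    (round-robin after a seeded shuffle)."""
    unique = sorted(set(map(str, subjects)))
    if len(unique) < n_folds:
        raise ValueError(
            f"{len(unique)} subjects cannot be split into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    val_sets = [order[i::n_folds] for i in range(n_folds)]
    return [
        FoldSplit(fold_id=i,
                  train_subjects=sorted(set(order) - set(val)),
                  val_subjects=sorted(val))
        for i, val in enumerate(val_sets)
    ]


def cross_validate(x, y, subjects, model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   subject_wise: bool = True, log=None):
    """k-fold cross-validation; returns (fold results, pooled confusion, summary).

    ``subject_wise=True`` (default) keeps every subject's epochs on one side
    of each split, preventing subject leakage; ``False`` splits at the epoch
    level (round-robin over a seeded shuffle of epochs) for comparability.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    train_config.validate()
    y = np.asarray(y, dtype=np.int64)
    subjects = np.asarray([str(s) for s in subjects])

    if subject_wise:
        splits = make_folds(subjects, train_config.folds, seed=train_config.seed)
        fold_masks = [np.isin(subjects, split.val_subjects) for split in splits]
    else:
        rng = np.random.default_rng(train_config.seed)
        order = rng.permutation(len(y))
        fold_masks = []
        for i in range(train_config.folds):
            mask = np.zeros(len(y), dtype=bool)
            mask[order[i::train_config.folds]] = True
            fold_masks.append(mask)

    results = []
    pooled = None
    for fold_id, val_mask in enumerate(fold_masks):
        model = LMCSleepNet(model_config,
                            seed=train_config.seed * 1000 + fold_id)
        fold_cfg = replace(train_config, seed=train_config.seed * 1000 + fold_id)
        if log is not None:
            log(f"fold {fold_id}: {int(val_mask.sum())} validation epochs")
        result = train(model, (x[~val_mask], y[~val_mask]),
                       (x[val_mask], y[val_mask]), fold_cfg, log=log)
        results.append(result)
        pooled = result.confusion if pooled is None else pooled + result.confusion

    fold_stats = [summary_metrics(r.confusion) for r in results]
    summary = {
        "pooled": summary_metrics(pooled),
        "fold_mean": {
            "accuracy": float(np.mean([s.accuracy for s in fold_stats])),
            "macro_f1": float(np.mean([s.macro_f1 for s in fold_stats])),
            "kappa": float(np.nanmean([s.kappa for s in fold_stats])),
        },
        "fold_sd": {
            "accuracy": float(np.std([s.accuracy for s in fold_stats])),
            "macro_f1": float(np.std([s.macro_f1 for s in fold_stats])),
            "kappa": float(np.nanstd([s.kappa for s in fold_stats])),
        },
    }
    return results, pooled, summary
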