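"""CNN classifiers for motor-imagery feature grids.

The primary architecture is a shallow "layer-modified" CNN: two tanh
convolutional layers each followed by batch normalization, one 2x2
max-pooling layer, dropout 0.5, then a 100-unit ReLU dense layer and a
softmax output (3 classes by default: RELAX / LEFT / RIGHT).  Three
comparison stacks (CNN2-CNN4, ReLU convolutions and selu dense layers) are
built from the same engine.  Training uses Adam (lr 0.001, beta1 0.9,
beta2 0.999); batch size and epoch count can be chosen by stratified
grid-search cross-validation.

All randomness (initialization, shuffling, dropout) derives from the config
seed, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .features import FeatureMatrix

__all__ = [
    "ARCHITECTURES",
    "DivergenceError",
    "ModelConfig",
    "TrainedClassifier",
    "Metrics",
    "build_model",
    "train",
    "predict",
    "evaluate",
    "grid_search_cv",
]

ARCHITECTURES = ("LM-CNN", "CNN2", "CNN3", "CNN4")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "LM-CNN"
    n_classes: int = 3
    conv_filters: tuple[int, ...] = (32, 64)
    kernel: int = 3
    conv_activation: str | None = None  # architecture default if None
    dense_activation: str | None = None
    dense_units: int | None = None
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    beta_1: float = 0.9
    beta_2: float = 0.999
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _arch_spec(cfg: ModelConfig) -> dict:
    """Per-architecture layer recipe (conv/pool counts, activations)."""
    if cfg.architecture == "LM-CNN":
        return dict(convs=2, pools="after_convs", conv_act="tanh",
                    batch_norm=True, dropout=True, dense=100, dense_act="relu")
    if cfg.architecture == "CNN2":
        return dict(convs=2, pools="each", conv_act="relu",
                    batch_norm=False, dropout=False, dense=100, dense_act="selu")
    if cfg.architecture == "CNN3":
        return dict(convs=1, pools="after_convs", conv_act="relu",
                    batch_norm=False, dropout=False, dense=256, dense_act="selu")
    return dict(convs=2, pools="after_convs", conv_act="relu",
                batch_norm=False, dropout=False, dense=256, dense_act="selu")


def build_model(cfg: ModelConfig, input_shape: tuple[int, int]) -> nn.Sequential:
    """Assemble the untrained layer stack for ``input_shape = (rows, cols)``.

    Raises ``ValueError`` when the grid is too small for the pooling stack.
    Identical config and seed produce identical initial parameters.
    """
    spec = _arch_spec(cfg)
    conv_act = cfg.conv_activation or spec["conv_act"]
    dense_act = cfg.dense_activation or spec["dense_act"]
    dense_units = cfg.dense_units or spec["dense"]

    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_drop = (np.random.default_rng(c) for c in ss.spawn(2))

    layers: list[nn.Layer] = []
    h, w = input_shape
    c = 1
    n_pools = 0
    for i in range(spec["convs"]):
        filters = cfg.conv_filters[min(i, len(cfg.conv_filters) - 1)]
        layers.append(nn.Conv2D(c, filters, cfg.kernel, rng_init))
        layers.append(nn.Activation(conv_act))
        if spec["batch_norm"]:
            layers.append(nn.BatchNorm(filters))
        c = filters
        if spec["pools"] == "each":
            layers.append(nn.MaxPool2D())
            h, w = h // 2, w // 2
            n_pools += 1
    if spec["pools"] == "after_convs":
        layers.append(nn.MaxPool2D())
        h, w = h // 2, w // 2
        n_pools += 1
    if h < 1 or w < 1:
        raise ValueError(
            f"input {input_shape} too small for {cfg.architecture}'s pooling stack"
        )
    if spec["dropout"]:
        layers.append(nn.Dropout(cfg.dropout_rate, rng_drop))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(h * w * c, dense_units, rng_init))
    layers.append(nn.Activation(dense_act))
    layers.append(nn.Dense(dense_units, cfg.n_classes, rng_init))
    return nn.Sequential(layers)


@dataclass
class TrainedClassifier:
    """Fitted model with its class label order and training history."""

    model: nn.Sequential
    config: ModelConfig
    classes: tuple[str, ...]
    history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})
    feature_stats: tuple | None = None  # (mu, sigma) used to standardize inputs

    def summary(self) -> list[str]:
        return self.model.summary()


def _as_array(X) -> np.ndarray:
    """Stack FeatureMatrix objects / 2-D grids into (N, H, W, 1)."""
    if isinstance(X, np.ndarray) and X.ndim == 4:
        return X
    grids = [x.grid if isinstance(x, FeatureMatrix) else np.asarray(x) for x in X]
    if len(grids) == 0:
        return np.empty((0, 0, 0, 1))
    return np.stack(grids)[..., None].astype(float)


def _onehot(y_idx: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((y_idx.size, k))
    out[np.arange(y_idx.size), y_idx] = 1.0
    return out


def train(
    model: nn.Sequential,
    X,
    y: Sequence[str],
    cfg: ModelConfig,
    seed: int | None = None,
) -> TrainedClassifier:
    """Train ``model`` with Adam for ``cfg.epochs`` epochs.

    ``X`` is a sequence of feature matrices (or an (N,H,W,1) array), ``y``
    the cue labels.  History records the mean batch loss and the eval-mode
    training accuracy per epoch.  Raises :class:`DivergenceError` on a
    non-finite loss, and ``ValueError`` on a single-class training set.
    """
    Xa = _as_array(X)
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if len(classes) != cfg.n_classes:
        raise ValueError(
            f"training set has {len(classes)} classes but the model outputs "
            f"n_classes={cfg.n_classes}"
        )
    y_idx = np.array([classes.index(lbl) for lbl in y])

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    opt = nn.Adam(model.params(), cfg.learning_rate, cfg.beta_1, cfg.beta_2)
    clf = TrainedClassifier(model=model, config=cfg, classes=classes)

    n = Xa.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(Xa[idx], train=True)
            probs = nn.softmax(logits)
            onehot = _onehot(y_idx[idx], cfg.n_classes)
            loss = nn.cross_entropy(probs, onehot)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            losses.append(loss)
            model.backward((probs - onehot) / idx.size)
            opt.step()
        probs = nn.softmax(model.forward(Xa, train=False))
        acc = float(np.mean(probs.argmax(axis=1) == y_idx))
        clf.history["loss"].append(float(np.mean(losses)))
        clf.history["accuracy"].append(acc)
    return clf


def predict(clf: TrainedClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and softmax probability vectors for a batch."""
    Xa = _as_array(X)
    if Xa.shape[0] == 0:
        return np.array([], dtype=object), np.empty((0, len(clf.classes)))
    probs = nn.softmax(clf.model.forward(Xa, train=False))
    labels = np.array([clf.classes[i] for i in probs.argmax(axis=1)], dtype=object)
    return labels, probs


@dataclass(frozen=True)
class Metrics:
    """Accuracy and macro precision/recall/F1 from the confusion matrix.

    ``confusion_matrix[i, j]`` counts samples of true class i predicted as
    class j, with classes in ``classes`` order.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion_matrix: np.ndarray
    classes: tuple[str, ...]

    @classmethod
    def from_labels(
        cls, y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
    ) -> "Metrics":
        classes = tuple(classes)
        k = len(classes)
        cm = np.zeros((k, k), dtype=int)
        lut = {c: i for i, c in enumerate(classes)}
        for t, p in zip(y_true, y_pred):
            cm[lut[t], lut[p]] += 1
        total = cm.sum()
        accuracy = float(np.trace(cm) / total) if total else 0.0
        prec, rec, f1s = [], [], []
        for i in range(k):
            col, row = cm[:, i].sum(), cm[i, :].sum()
            p_i = cm[i, i] / col if col else 0.0
            r_i = cm[i, i] / row if row else 0.0
            f_i = 2 * p_i * r_i / (p_i + r_i) if (p_i + r_i) else 0.0
            prec.append(p_i)
            rec.append(r_i)
            f1s.append(f_i)
        return cls(
            accuracy=accuracy,
            precision=float(np.mean(prec)),
            recall=float(np.mean(rec)),
            f1=float(np.mean(f1s)),
            confusion_matrix=cm,
            classes=classes,
        )

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "classes": list(self.classes),
        }


def evaluate(clf: TrainedClassifier, X, y: Sequence[str]) -> Metrics:
    """Metrics of ``clf`` on a labeled test set."""
    y = list(y)
    if len(y) == 0:
        raise ValueError("empty test set")
    y_pred, _ = predict(clf, X)
    return Metrics.from_labels(y, y_pred.tolist(), clf.classes)


def grid_search_cv(
    X,
    y: Sequence[str],
    batch_sizes: Sequence[int] = (16, 32, 64),
    epoch_options: Sequence[int] = (20, 50, 100),
    k: int = 3,
    cfg: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[int, int, dict]:
    """Pick (batch_size, epochs) by stratified k-fold cross-validation.

    Returns the cell with the highest mean validation accuracy; ties break
    toward the smaller batch size, then fewer epochs.  Also returns the full
    ``{(batch, epochs): mean_accuracy}`` table.
    """
    if len(batch_sizes) == 0 or len(epoch_options) == 0:
        raise ValueError("empty search grid")
    Xa = _as_array(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} samples per class for stratified CV")
    base = cfg or ModelConfig()
    input_shape = Xa.shape[1:3]
    table: dict[tuple[int, int], float] = {}
    for batch in batch_sizes:
        for epochs in epoch_options:
            cell_cfg = replace(base, batch_size=int(batch), epochs=int(epochs))
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            accs = []
            for tr, va in skf.split(Xa, y):
                model = build_model(cell_cfg, input_shape)
                clf = train(model, Xa[tr], y[tr], cell_cfg)
                accs.append(evaluate(clf, Xa[va], y[va]).accuracy)
            table[(int(batch), int(epochs))] = float(np.mean(accs))
    best = min(table, key=lambda cell: (-table[cell], cell[0], cell[1]))
    return best[0], best[1], table
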