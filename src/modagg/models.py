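"""Recognition and classification models.

* Recognizer: shared fully connected trunk (batch norm + dropout) that
  branches into one presence head per modality, trained with Adam on MSE
  against the binary composition targets; an optional cancer-type head
  (softmax + cross-entropy) turns it into the cancer-specific recogniser.
* Baseline (MCRM): independent per-modality logistic regressions (plus a
  multinomial regression for the cancer label) on the same splits.
* Classifier: feed-forward softmax network mapping patient-level
  concatenated aggregates to cancer type / subtype / TMB class, evaluated
  over repeated independent runs.

Data splits follow one protocol everywhere: 20% of rows held out for
testing, then 20% of the remaining training rows for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score

from . import _nn
from ._nn import (
    Adam,
    BatchNorm,
    Dense,
    Dropout,
    EarlyStopper,
    ReLU,
    Sequential,
    Sigmoid,
    TrainingError,
    softmax,
)
from .aggregation import RecognitionDataset
from .cohort import MODALITIES
from .evaluation import StratifiedReport, classification_metrics, stratified_metrics

__all__ = [
    "RecognizerConfig",
    "Recognizer",
    "TrainedRecognizer",
    "build_recognizer",
    "train_recognizer",
    "predict_composition",
    "fit_baseline_mcrm",
    "BaselineMCRM",
    "ClassifierConfig",
    "train_classifier",
    "ClassifierResult",
    "split_indices",
]

_F = np.float32


def split_indices(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(train, val, test): test = 20% of all rows, val = 20% of the rest."""
    order = rng.permutation(n)
    n_test = int(round(0.2 * n))
    test = order[:n_test]
    rest = order[n_test:]
    n_val = int(round(0.2 * len(rest)))
    return rest[n_val:], rest[:n_val], test


@dataclass(frozen=True)
class RecognizerConfig:
    embed_dim: int = 768
    modalities: tuple[str, ...] = MODALITIES
    shared_layer_sizes: tuple[int, ...] = (1024, 512)
    branch_layer_sizes: tuple[int, ...] = (128,)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    presence_threshold: float = 0.5
    cancer_head: bool = False
    cancer_types: tuple[str, ...] = ()
    cancer_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.modalities:
            raise ValueError("modality list must be non-empty")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.presence_threshold < 1:
            raise ValueError("presence_threshold must be in (0, 1)")
        if self.cancer_head and not self.cancer_types:
            raise ValueError("cancer_head requires cancer_types")


class Recognizer:
    """Shared trunk + per-modality presence branches (+ optional cancer head)."""

    def __init__(self, config: RecognizerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = (config.embed_dim, *config.shared_layer_sizes)
        trunk = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            trunk += [Dense(a, b, rng), BatchNorm(b), ReLU(), Dropout(config.dropout, rng)]
        self.trunk = Sequential(*trunk)
        width = sizes[-1]
        self.branches = []
        for _ in config.modalities:
            bsizes = (width, *config.branch_layer_sizes)
            layers = []
            for a, b in zip(bsizes[:-1], bsizes[1:]):
                layers += [Dense(a, b, rng), ReLU()]
            layers += [Dense(bsizes[-1], 1, rng), Sigmoid()]
            self.branches.append(Sequential(*layers))
        self.cancer_branch = None
        if config.cancer_head:
            self.cancer_branch = Sequential(
                Dense(width, 128, rng), ReLU(), Dense(128, len(config.cancer_types), rng)
            )
        # per-dimension input standardisation, fitted on the training split;
        # aggregate sums mix modalities of very different scales and the
        # small-scale ones otherwise get little gradient credit
        self.input_mean: np.ndarray | None = None
        self.input_scale: np.ndarray | None = None

    def set_input_stats(self, X_train: np.ndarray) -> None:
        self.input_mean = X_train.mean(axis=0).astype(_F)
        self.input_scale = np.maximum(X_train.std(axis=0), 1e-6).astype(_F)

    def _params(self):
        p = self.trunk.params() + [q for b in self.branches for q in b.params()]
        if self.cancer_branch is not None:
            p += self.cancer_branch.params()
        return p

    def _grads(self):
        g = self.trunk.grads() + [q for b in self.branches for q in b.grads()]
        if self.cancer_branch is not None:
            g += self.cancer_branch.grads()
        return g

    def forward(self, X: np.ndarray, train: bool = False):
        X = np.asarray(X, dtype=_F)
        if X.ndim != 2 or X.shape[1] != self.config.embed_dim:
            raise ValueError(f"expected (n, {self.config.embed_dim}) input, got {X.shape}")
        if self.input_mean is not None:
            X = (X - self.input_mean) / self.input_scale
        h = self.trunk.forward(X, train)
        scores = np.concatenate([b.forward(h, train) for b in self.branches], axis=1)
        logits = None
        if self.cancer_branch is not None:
            logits = self.cancer_branch.forward(h, train)
        return scores, logits

    def backward(self, d_scores: np.ndarray, d_logits: np.ndarray | None):
        dh = None
        for j, b in enumerate(self.branches):
            g = b.backward(d_scores[:, j : j + 1].astype(_F))
            dh = g if dh is None else dh + g
        if self.cancer_branch is not None and d_logits is not None:
            dh = dh + self.cancer_branch.backward(d_logits.astype(_F))
        self.trunk.backward(dh)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False)[0]


def build_recognizer(config: RecognizerConfig) -> Recognizer:
    return Recognizer(config)


@dataclass
class TrainedRecognizer:
    model: Recognizer
    config: RecognizerConfig
    history: pd.DataFrame
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def evaluate(self, dataset: RecognitionDataset, indices=None) -> StratifiedReport:
        """Stratified report on the dataset's test split (or given rows)."""
        idx = self.test_idx if indices is None else indices
        Y_pred = predict_composition(self, dataset.X[idx])
        return stratified_metrics(dataset.Y[idx], Y_pred, self.config.modalities)


def _recognizer_losses(model, X, Y, cancer_onehot, train, opt=None, weight=1.0):
    scores, logits = model.forward(X, train)
    n, m = scores.shape
    mse = float(((scores - Y) ** 2).mean())
    loss = mse
    d_logits = None
    if logits is not None and cancer_onehot is not None:
        p = softmax(logits)
        ce = float(-(cancer_onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
        loss = mse + weight * ce
        d_logits = weight * (p - cancer_onehot) / n
    if opt is not None:
        d_scores = 2.0 * (scores - Y) / (n * m)
        model.backward(d_scores, d_logits)
        opt.step()
    return loss


def train_recognizer(
    model: Recognizer,
    dataset: RecognitionDataset,
    config: RecognizerConfig | None = None,
) -> TrainedRecognizer:
    """Train with Adam on MSE (plus cross-entropy on the cancer head)."""
    config = config if config is not None else model.config
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if dataset.modalities != config.modalities:
        raise ValueError("dataset/model modality schema mismatch")
    rng = np.random.default_rng(config.seed + 101)
    X = dataset.X
    Y = dataset.Y.astype(_F)
    cancer = None
    if model.cancer_branch is not None:
        if dataset.cancer_labels is None:
            raise ValueError("cancer head requires cancer labels in dataset")
        lut = {ct: j for j, ct in enumerate(config.cancer_types)}
        col = np.array([lut[c] for c in dataset.cancer_labels])
        cancer = np.zeros((len(dataset), len(config.cancer_types)), dtype=_F)
        cancer[np.arange(len(dataset)), col] = 1.0

    train_idx, val_idx, test_idx = split_indices(len(dataset), rng)
    model.set_input_stats(X[train_idx])
    opt = Adam(model._params(), model._grads(), lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    best = _nn.snapshot(model._params())
    history = []
    for epoch in range(config.max_epochs):
        losses = []
        for idx in _nn.iterate_minibatches(len(train_idx), config.batch_size, rng):
            rows = train_idx[idx]
            loss = _recognizer_losses(
                model, X[rows], Y[rows],
                None if cancer is None else cancer[rows],
                True, opt, config.cancer_loss_weight,
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}", epoch=epoch)
            losses.append(loss)
        val_loss = _recognizer_losses(
            model, X[val_idx], Y[val_idx],
            None if cancer is None else cancer[val_idx],
            False, None, config.cancer_loss_weight,
        )
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best = _nn.snapshot(model._params())
        if stop:
            break
    _nn.restore(model._params(), best)
    return TrainedRecognizer(
        model=model,
        config=config,
        history=pd.DataFrame(history),
        train_idx=train_idx,
        val_idx=val_idx,
        test_idx=test_idx,
    )


def predict_composition(trained, X: np.ndarray) -> np.ndarray:
    """Threshold presence scores at the configured cutoff (inclusive >=)."""
    model = trained.model if isinstance(trained, TrainedRecognizer) else trained
    scores = model.predict_scores(np.asarray(X, dtype=_F))
    return (scores >= model.config.presence_threshold).astype(np.int8)


@dataclass
class BaselineMCRM:
    """Per-modality logistic regressions + optional multinomial cancer head."""

    modality_models: dict[str, object]
    constant_heads: dict[str, int]
    cancer_model: object | None
    modalities: tuple[str, ...]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for m in self.modalities:
            if m in self.constant_heads:
                cols.append(np.full(X.shape[0], self.constant_heads[m], dtype=np.int8))
            else:
                cols.append(self.modality_models[m].predict(X).astype(np.int8))
        return np.stack(cols, axis=1)

    def evaluate(self, dataset: RecognitionDataset, indices=None) -> StratifiedReport:
        idx = self.test_idx if indices is None else indices
        return stratified_metrics(
            dataset.Y[idx], self.predict(dataset.X[idx]), self.modalities
        )


def fit_baseline_mcrm(dataset: RecognitionDataset, seed: int = 0) -> BaselineMCRM:
    """Multiclass-logistic-regression baseline on the recogniser's splits."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed + 101)
    train_idx, val_idx, test_idx = split_indices(len(dataset), rng)
    fit_rows = train_idx
    models: dict[str, object] = {}
    constants: dict[str, int] = {}
    for j, m in enumerate(dataset.modalities):
        y = dataset.Y[fit_rows, j]
        if len(np.unique(y)) < 2:
            import warnings

            warnings.warn(f"single-class target for {m!r}; constant head", stacklevel=2)
            constants[m] = int(y[0]) if len(y) else 0
            continue
        clf = LogisticRegression(max_iter=1000, random_state=seed)
        clf.fit(dataset.X[fit_rows], y)
        models[m] = clf
    cancer_model = None
    if dataset.cancer_labels is not None:
        cancer_model = LogisticRegression(max_iter=1000, random_state=seed)
        cancer_model.fit(dataset.X[fit_rows], dataset.cancer_labels[fit_rows].astype(str))
    return BaselineMCRM(
        modality_models=models,
        constant_heads=constants,
        cancer_model=cancer_model,
        modalities=dataset.modalities,
        train_idx=train_idx,
        val_idx=val_idx,
        test_idx=test_idx,
    )


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_sizes: tuple[int, ...] = (512, 256)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 150
    patience: int = 15
    n_runs: int = 30
    seed: int = 0


class _SoftmaxNet:
    def __init__(self, n_in, n_classes, config: ClassifierConfig, rng):
        sizes = (n_in, *config.hidden_sizes)
        layers = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            layers += [Dense(a, b, rng), ReLU(), Dropout(config.dropout, rng)]
        layers.append(Dense(sizes[-1], n_classes, rng))
        self.net = Sequential(*layers)

    def fit(self, X, y_idx, n_classes, config, rng):
        onehot = np.zeros((len(y_idx), n_classes), dtype=_F)
        onehot[np.arange(len(y_idx)), y_idx] = 1.0
        # internal 80/20 split of the training rows for early stopping
        order = rng.permutation(len(y_idx))
        n_val = max(1, int(round(0.2 * len(y_idx))))
        val, tr = order[:n_val], order[n_val:]
        opt = Adam(self.net.params(), self.net.grads(), lr=config.learning_rate)
        stopper = EarlyStopper(config.patience)
        best = _nn.snapshot(self.net.params())
        for epoch in range(config.max_epochs):
            for idx in _nn.iterate_minibatches(len(tr), config.batch_size, rng):
                rows = tr[idx]
                logits = self.net.forward(X[rows], True)
                p = softmax(logits)
                loss = -(onehot[rows] * np.log(np.clip(p, 1e-12, None))).sum() / len(rows)
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch}", epoch=epoch)
                self.net.backward((p - onehot[rows]) / len(rows))
                opt.step()
            logits = self.net.forward(X[val], False)
            p = softmax(logits)
            val_loss = float(
                -(onehot[val] * np.log(np.clip(p, 1e-12, None))).sum() / len(val)
            )
            improved = val_loss < stopper.best_loss
            stop = stopper.update(epoch, val_loss)
            if improved:
                best = _nn.snapshot(self.net.params())
            if stop:
                break
        _nn.restore(self.net.params(), best)

    def predict(self, X):
        return self.net.forward(np.asarray(X, dtype=_F), False).argmax(axis=1)


@dataclass
class ClassifierResult:
    """Aggregated multi-run classifier evaluation."""

    target: str
    classes: tuple
    runs: pd.DataFrame  # one row per run: mcc, f1_macro, accuracy, ...
    per_class_f1: pd.DataFrame  # runs x classes
    confusion: np.ndarray  # summed over runs

    @property
    def mean_mcc(self) -> float:
        return float(self.runs["mcc"].mean())

    def mean_per_class_f1(self) -> pd.Series:
        return self.per_class_f1.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        return self.runs.agg(["mean", "std"])


def train_classifier(
    X: np.ndarray,
    labels,
    target: str = "cancer_type",
    config: ClassifierConfig | None = None,
    n_runs: int | None = None,
) -> ClassifierResult:
    """Repeated-run feed-forward classification of patient aggregates.

    Each run redraws the 80/20 train/test split, re-initialises the
    network, trains, and records test metrics; results are aggregated over
    runs (default 30).
    """
    config = config if config is not None else ClassifierConfig()
    n_runs = n_runs if n_runs is not None else config.n_runs
    X = np.asarray(X, dtype=_F)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n_samples, n_features) aligned with labels")
    classes, y_idx = np.unique(y, return_inverse=True)
    run_rows, f1_rows = [], []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for run in range(n_runs):
        rng = np.random.default_rng(config.seed + 1000 * run + 17)
        order = rng.permutation(len(y))
        n_test = int(round(0.2 * len(y)))
        test, train = order[:n_test], order[n_test:]
        net = _SoftmaxNet(X.shape[1], len(classes), config, rng)
        net.fit(X[train], y_idx[train], len(classes), config, rng)
        pred = net.predict(X[test])
        met = classification_metrics(y_idx[test], pred, labels=range(len(classes)))
        confusion += met.pop("confusion_matrix")
        met.pop("degenerate")
        run_rows.append({"run": run, **met})
        f1_rows.append(
            f1_score(y_idx[test], pred, labels=range(len(classes)), average=None,
                     zero_division=0)
        )
    return ClassifierResult(
        target=target,
        classes=tuple(classes),
        runs=pd.DataFrame(run_rows),
        per_class_f1=pd.DataFrame(f1_rows, columns=list(classes)),
        confusion=confusion,
    )
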