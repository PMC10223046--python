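"""Training, prediction, evaluation metrics, and the benchmark grid.

Deep models are trained with mini-batch Adam (batch size 32, learning rate
0.001 by default) on softmax cross-entropy.  Evaluation follows the binary
convention with product class 1 (Pennette72) as the positive class:

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Per-class reports are macro-averaged for the benchmark grid.  Classical
baselines (KNN, decision tree, Gaussian naive Bayes, SVM) delegate to
scikit-learn with library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from swirclass.dl_models import MODEL_KINDS, ModelSpec, build_model
from swirclass.nn.layers import Sequential
from swirclass.nn.losses import softmax_cross_entropy
from swirclass.nn.optim import Adam
from swirclass.preprocess import (
    SplitSpec,
    apply_pca,
    apply_standardizer,
    fit_pca,
    fit_standardizer,
    systematic_split,
)
from swirclass.spectra_io import PHYSICAL_STATES, SpectraDataset, subset_by_state

CLASSICAL_KINDS = ("knn", "dt", "nb", "svm")
PROCESSINGS = ("raw", "standardization", "pca")


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch training regime for the deep classifiers."""

    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with class 1 as positive."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def swapped(self) -> "ConfusionCounts":
        """The same predictions viewed with class 0 as positive."""
        return ConfusionCounts(TP=self.TN, FP=self.FN, TN=self.TP, FN=self.FP)


@dataclass
class MetricsReport:
    """Accuracy, precision, recall and F1 as proportions in [0, 1].

    A metric whose denominator is zero is reported as ``None`` with the
    reason recorded in ``undefined`` rather than silently coerced to 0.
    """

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: dict[str, str] = field(default_factory=dict)


def train_classifier(
    model: Sequential, X: np.ndarray, y: np.ndarray, cfg: TrainConfig = TrainConfig()
) -> pd.DataFrame:
    """Train ``model`` in place; returns the per-epoch loss/accuracy log.

    Reproducible given (cfg.seed, inputs): the same seed drives batch
    shuffling and dropout masks.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with one label per row")
    if not np.isin(y, (0, 1)).all():
        bad = y[~np.isin(y, (0, 1))][0]
        raise ValueError(f"labels must be in {{0, 1}}, found {bad!r}")
    y = y.astype(int)
    rng = np.random.default_rng(cfg.seed)
    model.seed_dropout(rng)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = X.shape[0]
    log = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            logits = model.forward(X[idx], training=True)
            loss, grad = softmax_cross_entropy(logits, y[idx])
            model.backward(grad)
            opt.step(model.gradients())
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        log.append(
            {"epoch": epoch + 1, "loss": sum(losses) / n, "accuracy": correct / n}
        )
    return pd.DataFrame(log, columns=["epoch", "loss", "accuracy"])


def predict(model: Sequential, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Deterministic inference-mode class labels, one per row."""
    X = np.asarray(X, dtype=float)
    outs = []
    for start in range(0, X.shape[0], batch_size):
        logits = model.forward(X[start : start + batch_size], training=False)
        outs.append(logits.argmax(axis=1))
    return np.concatenate(outs) if outs else np.empty(0, dtype=int)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """TP/FP/TN/FN with label 1 (Pennette72) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    Recall is TP / (TP + FN), the standard sensitivity; ratios with a zero
    denominator are absent with a reason.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undefined: dict[str, str] = {}
    accuracy = (c.TP + c.TN) / c.total
    if c.TP + c.FP > 0:
        precision = c.TP / (c.TP + c.FP)
    else:
        precision = None
        undefined["precision"] = "no positive predictions (TP + FP == 0)"
    if c.TP + c.FN > 0:
        recall = c.TP / (c.TP + c.FN)
    else:
        recall = None
        undefined["recall"] = "no positive ground-truth samples (TP + FN == 0)"
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
        undefined["f1"] = "precision and recall undefined or both zero"
    return MetricsReport(accuracy, precision, recall, f1, undefined)


def per_class_metrics(c: ConfusionCounts) -> dict[int, MetricsReport]:
    """Metric reports for class 1 (as counted) and class 0 (counts swapped)."""
    return {1: compute_metrics(c), 0: compute_metrics(c.swapped())}


def aggregate_metrics(per_class: dict[int, MetricsReport]) -> MetricsReport:
    """Macro average: unweighted mean of per-class precision/recall/F1.

    Accuracy is shared between the two class views and passes through.
    """
    if set(per_class) != {0, 1}:
        raise ValueError("per_class must contain reports for classes 0 and 1")
    r0, r1 = per_class[0], per_class[1]
    undefined: dict[str, str] = {}

    def macro(name: str) -> float | None:
        a, b = getattr(r0, name), getattr(r1, name)
        if a is None or b is None:
            undefined[name] = f"{name} undefined for one class"
            return None
        return (a + b) / 2

    return MetricsReport(
        accuracy=r1.accuracy,
        precision=macro("precision"),
        recall=macro("recall"),
        f1=macro("f1"),
        undefined=undefined,
    )


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Macro-averaged report straight from label vectors."""
    return aggregate_metrics(per_class_metrics(confusion_counts(y_true, y_pred)))


def _prepare_features(
    train_ds: SpectraDataset, test_ds: SpectraDataset, processing: str, pca_k: int
) -> tuple[np.ndarray, np.ndarray]:
    if processing == "raw":
        return train_ds.X, test_ds.X
    std = fit_standardizer(train_ds)
    train_s = apply_standardizer(train_ds, std)
    test_s = apply_standardizer(test_ds, std)
    if processing == "standardization":
        return train_s.X, test_s.X
    if processing == "pca":
        k = min(pca_k, len(train_s) - 1, train_s.grid.n_points)
        pca = fit_pca(train_s, k)
        return apply_pca(train_s, pca), apply_pca(test_s, pca)
    raise ValueError(f"unknown processing {processing!r}; expected one of {PROCESSINGS}")


def _fit_predict_classical(kind: str, Xtr, ytr, Xte, seed: int) -> np.ndarray:
    if kind == "knn":
        est = KNeighborsClassifier()
    elif kind == "dt":
        est = DecisionTreeClassifier(random_state=seed)
    elif kind == "nb":
        est = GaussianNB()
    elif kind == "svm":
        est = SVC(random_state=seed)
    else:
        raise ValueError(f"unknown classical model {kind!r}")
    est.fit(Xtr, ytr)
    return est.predict(Xte)


def run_benchmark(
    ds: SpectraDataset,
    models: tuple[str, ...] = MODEL_KINDS + CLASSICAL_KINDS,
    processings: tuple[str, ...] = PROCESSINGS,
    cfg: TrainConfig = TrainConfig(),
    pca_k: int = 100,
    split: SplitSpec = SplitSpec(),
) -> pd.DataFrame:
    """Model x processing x physical-state benchmark grid.

    For each combination: subset by state, systematic 7:3 split stratified by
    product class, fit the processing on the training subset only, train the
    model, and report macro-averaged test metrics.  Deterministic for a fixed
    ``cfg.seed``.
    """
    known = set(MODEL_KINDS) | set(CLASSICAL_KINDS)
    unknown = [m for m in models if m not in known]
    if unknown:
        raise ValueError(f"unknown model kind(s) {unknown}; expected from {sorted(known)}")
    states = [s for s in PHYSICAL_STATES if len(subset_by_state(ds, s)) > 0]
    if len(states) < 2:
        raise ValueError("benchmark dataset must contain both physical states")
    rows = []
    for state in states:
        state_ds = subset_by_state(ds, state)
        train_ds, test_ds = systematic_split(state_ds, split)
        ytr, yte = train_ds.labels, test_ds.labels
        for processing in processings:
            Xtr, Xte = _prepare_features(train_ds, test_ds, processing, pca_k)
            for kind in models:
                if kind in CLASSICAL_KINDS:
                    y_pred = _fit_predict_classical(kind, Xtr, ytr, Xte, cfg.seed)
                else:
                    model = build_model(ModelSpec(kind=kind), Xtr.shape[1], seed=cfg.seed)
                    train_classifier(model, Xtr, ytr, cfg)
                    y_pred = predict(model, Xte)
                rep = evaluate_predictions(yte, y_pred)
                rows.append(
                    {
                        "state": state,
                        "processing": processing,
                        "model": kind,
                        "accuracy": rep.accuracy,
                        "precision": rep.precision,
                        "recall": rep.recall,
                        "f1": rep.f1,
                        "seed": cfg.seed,
                        "n_train": len(train_ds),
                        "n_test": len(test_ds),
                    }
                )
    return pd.DataFrame(rows)


def run_replicated_benchmark(
    models: tuple[str, ...] = ("cnn", "lstm", "cnn_lstm"),
    processings: tuple[str, ...] = ("standardization",),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    epochs: int = 3,
    pca_k: int = 100,
    generator_overrides: dict | None = None,
) -> pd.DataFrame:
    """Seed-replicated benchmark on freshly generated synthetic datasets.

    For each seed a new dataset is drawn (generator seed == training seed) and
    the full state x processing x model grid is evaluated; rows from all seeds
    are concatenated.  Group by (state, processing, model) and average to get
    seed-mean performance.
    """
    from swirclass.synthgen import GeneratorConfig, generate_dataset

    overrides = generator_overrides or {}
    frames = []
    for seed in seeds:
        gen = GeneratorConfig(**{**GeneratorConfig().__dict__, **overrides, "seed": seed})
        ds = generate_dataset(gen)
        frames.append(
            run_benchmark(
                ds,
                models=models,
                processings=processings,
                cfg=TrainConfig(epochs=epochs, seed=seed),
                pca_k=pca_k,
            )
        )
    return pd.concat(frames, ignore_index=True)
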