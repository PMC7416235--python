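"""Classifiers, cross-validation and the metric suite.

Feature vectors are either the raw 200-channel sample or a reconstruction
from its circular decomposition (a single IMF, a sum of IMFs, or all IMFs —
i.e. the sample minus its residual trend).  Three classifiers are supported:
an RBF-kernel SVM (K(x1,x2) = exp(-||x1-x2||^2 / 2 sigma^2)), multinomial
logistic regression, and a 300/200/100 feed-forward network.  Evaluation is
leave-one-run-out cross-validation: the acquisition runs are the folds, which
on the reference design gives 10 folds of 216 training and 24 test samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from ._nnet import DenseNet
from .circle_signal import CircularSignal
from .emd_core import IMFSet, SiftConfig, circle_emd, combine_imfs
from .errors import InvalidInputError, InvalidSelectionError
from .preprocess import StudyDataset

__all__ = [
    "FeatureSpec",
    "ClassifierSpec",
    "CVReport",
    "rbf_kernel",
    "decompose_dataset",
    "build_features",
    "train_svm_rbf",
    "train_logistic",
    "train_mlp",
    "run_cross_validation",
    "compute_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSpec:
    """Which representation of each sample to feed the classifier.

    mode "original" uses the raw channel vector; "single_imf" the k-th IMF
    (1-based); "imf_sum" the sum of the listed IMFs; "all_imfs" the sum of
    every IMF, i.e. the sample with its residual trend removed.  Samples whose
    decomposition has fewer components contribute zeros for missing indices.
    """

    mode: str = "original"
    indices: tuple[int, ...] = ()
    emd_config: SiftConfig = SiftConfig()

    def __post_init__(self) -> None:
        if self.mode not in {"original", "single_imf", "imf_sum", "all_imfs"}:
            raise InvalidSelectionError(f"unknown feature mode {self.mode!r}")
        if self.mode == "single_imf" and len(self.indices) != 1:
            raise InvalidSelectionError("single_imf needs exactly one index")
        if self.mode == "imf_sum" and not self.indices:
            raise InvalidSelectionError("imf_sum needs at least one index")
        if any(i < 1 for i in self.indices):
            raise InvalidSelectionError("IMF indices are 1-based")


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier run.

    The SVM follows the common libsvm defaults: C-classification, C = 1,
    kernel bandwidth sigma^2 = n_features / 2 (i.e. gamma = 1/n_features),
    termination tolerance 1e-3, one-vs-one multiclass voting.
    """

    kind: str = "svm_rbf"  # svm_rbf | logistic | mlp
    seed: int = 0
    svm_c: float = 1.0
    svm_tol: float = 1e-3
    logistic_max_iter: int = 2000
    mlp_hidden: tuple[int, ...] = (300, 200, 100)
    mlp_dropout: float = 0.5
    mlp_lr: float = 1e-3
    mlp_epochs: int = 200
    mlp_batch_size: int = 32

    def __post_init__(self) -> None:
        if self.kind not in {"svm_rbf", "logistic", "mlp"}:
            raise InvalidSelectionError(f"unknown classifier kind {self.kind!r}")


@dataclass
class CVReport:
    """Per-fold and pooled results of one cross-validation run."""

    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    confusion: np.ndarray  # (n_classes, n_classes), true x predicted, pooled
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    fold_sizes: list[tuple[int, int]] = field(default_factory=list)  # (train, test)


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma_sq: float) -> float:
    """Gaussian kernel exp(-||x1 - x2||^2 / (2 sigma^2))."""
    d = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    return float(np.exp(-np.dot(d, d) / (2.0 * sigma_sq)))


def decompose_dataset(dataset: StudyDataset, config: SiftConfig = SiftConfig()) -> list[IMFSet]:
    """Circular decomposition of every sample's spatial channel vector."""
    return [circle_emd(CircularSignal(row), config) for row in dataset.samples]


def build_features(
    dataset: StudyDataset,
    spec: FeatureSpec,
    decompositions: list[IMFSet] | None = None,
) -> np.ndarray:
    """Materialise the feature matrix for one feature mode.

    ``decompositions`` may be passed to reuse one decomposition across
    several feature modes; it must align with the dataset rows.
    """
    if dataset.n_samples == 0:
        raise InvalidInputError("dataset is empty")
    if spec.mode == "original":
        return dataset.samples.copy()
    if decompositions is None:
        decompositions = decompose_dataset(dataset, spec.emd_config)
    if len(decompositions) != dataset.n_samples:
        raise InvalidInputError("one decomposition per sample is required")
    feats = np.zeros_like(dataset.samples)
    n_missing = 0
    for i, dec in enumerate(decompositions):
        if spec.mode == "all_imfs":
            if dec.n_imfs:
                feats[i] = combine_imfs(dec, "all")
            continue
        present = [k for k in spec.indices if k <= dec.n_imfs]
        n_missing += len(spec.indices) - len(present)
        if present:
            feats[i] = combine_imfs(dec, present)
    if n_missing:
        logger.info("feature construction: %d requested IMF indices were missing (zeros used)", n_missing)
    return feats


def _make_model(n_features: int, n_classes: int, spec: ClassifierSpec):
    if spec.kind == "svm_rbf":
        return SVC(
            kernel="rbf",
            C=spec.svm_c,
            gamma="auto",  # 1/n_features, i.e. sigma^2 = n_features/2
            tol=spec.svm_tol,
            decision_function_shape="ovo",
            random_state=spec.seed,
        )
    if spec.kind == "logistic":
        return LogisticRegression(max_iter=spec.logistic_max_iter, random_state=spec.seed)
    return DenseNet(
        n_features=n_features,
        n_classes=n_classes,
        hidden=spec.mlp_hidden,
        dropout=spec.mlp_dropout,
        lr=spec.mlp_lr,
        batch_size=spec.mlp_batch_size,
        epochs=spec.mlp_epochs,
        seed=spec.seed,
    )


def _fit(features: np.ndarray, labels: np.ndarray, spec: ClassifierSpec):
    if np.unique(labels).size < 2:
        raise InvalidInputError("training labels contain a single class")
    model = _make_model(features.shape[1], int(np.max(labels)) + 1, spec)
    return model.fit(features, labels)


def train_svm_rbf(features, labels, spec: ClassifierSpec = ClassifierSpec(kind="svm_rbf")):
    """Fit the one-vs-one Gaussian-kernel SVM; returns the fitted model."""
    return _fit(features, labels, replace(spec, kind="svm_rbf"))


def train_logistic(features, labels, spec: ClassifierSpec = ClassifierSpec(kind="logistic")):
    """Fit multinomial softmax regression minimising cross-entropy."""
    return _fit(features, labels, replace(spec, kind="logistic"))


def train_mlp(features, labels, spec: ClassifierSpec = ClassifierSpec(kind="mlp")):
    """Fit the 300/200/100 ReLU network with dropout and batch norm."""
    return _fit(features, labels, replace(spec, kind="mlp"))


def compute_metrics(confusion: np.ndarray) -> tuple[float, float, float]:
    """Weighted precision, recall and F1 from a true-by-predicted count matrix.

    Weights are the true-class supports.  A class never predicted has
    undefined precision; it contributes 0 with a warning.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
        raise InvalidInputError("confusion matrix must be square with nonnegative counts")
    total = c.sum()
    if total == 0:
        raise InvalidInputError("confusion matrix is all zeros")
    support = c.sum(axis=1)
    diag = np.diag(c)
    col = c.sum(axis=0)
    if np.any((col == 0) & (support > 0)):
        warnings.warn("a class was never predicted; its precision counts as 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(col > 0, diag / col, 0.0)
        rec = np.where(support > 0, diag / support, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    w = support / total
    return float(w @ prec), float(w @ rec), float(w @ f1)


def run_cross_validation(
    features: np.ndarray,
    labels: np.ndarray,
    run_id: np.ndarray,
    classifier: ClassifierSpec = ClassifierSpec(),
) -> CVReport:
    """Leave-one-run-out cross-validation.

    Each unique run id is one fold; the model is refit from scratch per fold
    (the fold index perturbs the training seed deterministically).  Reports
    per-fold accuracy, the pooled confusion matrix over all test folds, and
    weighted precision/recall/F1.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    run_id = np.asarray(run_id)
    folds = np.unique(run_id)
    if folds.size < 2:
        raise InvalidInputError("cross-validation needs at least 2 runs/folds")
    n_classes = int(np.max(labels)) + 1
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    accs, sizes = [], []
    for f_idx, fold in enumerate(folds):
        test = run_id == fold
        train = ~test
        model = _fit(features[train], labels[train], replace(classifier, seed=classifier.seed + f_idx))
        pred = np.asarray(model.predict(features[test]), dtype=int)
        truth = labels[test]
        accs.append(float(np.mean(pred == truth)))
        sizes.append((int(train.sum()), int(test.sum())))
        for t, p in zip(truth, pred):
            confusion[t, p] += 1
    precision, recall, f1 = compute_metrics(confusion)
    return CVReport(
        per_fold_accuracy=np.array(accs),
        mean_accuracy=float(np.mean(accs)),
        confusion=confusion,
        weighted_precision=precision,
        weighted_recall=recall,
        weighted_f1=f1,
        fold_sizes=sizes,
    )
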