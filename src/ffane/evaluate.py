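"""Pair features, classifiers, cross-validated metrics and the alpha sweep.

A candidate pair (a, b) is represented by concatenating the two proteins'
embedding vectors (width 2d).  Classifiers (RBF-kernel SVM by default;
XGBoost, random forest and Gaussian naive Bayes as alternatives) are scored
under stratified k-fold cross-validation with the usual confusion-matrix
suite — accuracy, precision, sensitivity, F1, Matthews correlation
coefficient — plus ROC/AUC from the classifier's continuous output.

``grid_search_alpha`` sweeps the fusion weight over {0, 0.125, ..., 1},
running fuse -> SAE -> embed -> pair features -> CV for each value and
selecting the weight with the best mean accuracy (ties to the smaller
weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .data_io import InteractionNetwork, PairDataset, ProteinSet
from .embedding import SAEConfig, encode, train_sae
from .similarity import SimilarityMatrix, fuse

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "f1", "mcc", "auc")

#: The fusion-weight grid: 0 to 1 in steps of 0.125 (9 values).
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(i / 8 for i in range(9))

CLASSIFIER_KINDS = ("svm_rbf", "xgboost", "random_forest", "naive_bayes")


@dataclass(frozen=True)
class PairFeatureMatrix:
    """Rows aligned with a PairDataset; row = embedding[a] ++ embedding[b]."""

    features: np.ndarray  # (m, 2d)
    labels: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        lab = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if f.ndim != 2 or f.shape[0] != lab.shape[0]:
            raise ValueError("features and labels must align")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm_rbf"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier {self.kind!r}; choose from {CLASSIFIER_KINDS}")
        hp = self.hyperparameters
        if "C" in hp and not hp["C"] > 0:
            raise ValueError("C must be positive")
        if "gamma" in hp and not (hp["gamma"] == "scale" or hp["gamma"] > 0):
            raise ValueError("gamma must be positive or 'scale'")


@dataclass(frozen=True)
class FoldMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    mcc: float
    auc: float = float("nan")
    roc_points: np.ndarray | None = None
    undefined_rates: bool = False

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "acc": self.accuracy, "prec": self.precision, "sen": self.sensitivity,
            "f1": self.f1, "mcc": self.mcc, "auc": self.auc,
        }


@dataclass
class CVReport:
    k: int
    folds: list[FoldMetrics]
    mean: dict[str, float]
    std: dict[str, float]
    classifier: ClassifierSpec | None = None
    alpha: float | None = None

    def to_dict(self) -> dict:
        short = {"accuracy": "acc", "precision": "prec", "sensitivity": "sen",
                 "f1": "f1", "mcc": "mcc", "auc": "auc"}
        return {
            "alpha": self.alpha,
            "classifier": None if self.classifier is None else {
                "kind": self.classifier.kind,
                "hyperparameters": self.classifier.hyperparameters,
                "seed": self.classifier.seed,
            },
            "k": self.k,
            "folds": [f.to_dict() for f in self.folds],
            "mean": {short[m]: v for m, v in self.mean.items()},
            "std": {short[m]: v for m, v in self.std.items()},
        }


def build_pair_features(embeddings: np.ndarray, dataset: PairDataset) -> PairFeatureMatrix:
    """Concatenate the two proteins' embeddings for every pair in the dataset.

    Pairs are stored canonically as (min_index, max_index), so the left half
    of each row is the lower-index protein.
    """
    emb = np.asarray(embeddings, dtype=float)
    n, d = emb.shape
    if len(dataset) == 0:
        return PairFeatureMatrix(features=np.empty((0, 2 * d)), labels=np.empty(0, dtype=np.int64))
    if dataset.pairs.max() >= n:
        raise IndexError("pair index out of range for embedding matrix")
    feats = np.concatenate([emb[dataset.pairs[:, 0]], emb[dataset.pairs[:, 1]]], axis=1)
    return PairFeatureMatrix(features=feats, labels=dataset.labels.copy())


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> FoldMetrics:
    """Scalar confusion-matrix metrics.

    Ratios with zero denominators are reported as 0 with ``undefined_rates``
    set, so aggregate means stay defined.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("at least one count must be positive")
    accuracy = (tp + tn) / total
    precision, u1 = _safe_ratio(tp, tp + fp)
    sensitivity, u2 = _safe_ratio(tp, tp + fn)
    f1, u3 = _safe_ratio(2 * precision * sensitivity, precision + sensitivity)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc, u4 = _safe_ratio(float(tp) * tn - float(fp) * fn, mcc_den)
    undefined = u1 or u2 or u3 or u4
    if undefined:
        warnings.warn("metric with zero denominator reported as 0", RuntimeWarning, stacklevel=2)
    return FoldMetrics(
        tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
        accuracy=accuracy, precision=precision, sensitivity=sensitivity,
        f1=f1, mcc=mcc, undefined_rates=undefined,
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep over the scores, AUC by trapezoid rule.

    Equal scores are grouped into one threshold step, so the AUC equals the
    Mann-Whitney concordance statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


def make_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn/xgboost estimator for a ClassifierSpec."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm_rbf":
        return SVC(
            kernel="rbf",
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            cache_size=hp.get("cache_size", 500),
        )
    if spec.kind == "xgboost":
        return XGBClassifier(
            random_state=spec.seed, n_jobs=1, verbosity=0,
            eval_metric="logloss", **hp,
        )
    if spec.kind == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.kind == "naive_bayes":
        return GaussianNB(**hp)
    raise ValueError(spec.kind)


def _continuous_scores(model, x: np.ndarray) -> np.ndarray:
    # SVM: signed decision value (monotone in any calibrated probability,
    # hence AUC-identical and cheaper than probability calibration).
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(x), dtype=float)
    return np.asarray(model.predict_proba(x)[:, 1], dtype=float)


def evaluate_fold(model, x_test: np.ndarray, y_test: np.ndarray) -> FoldMetrics:
    """Confusion + ROC metrics of a fitted model on one held-out fold."""
    y_pred = np.asarray(model.predict(x_test), dtype=np.int64)
    tp = int(np.sum((y_pred == 1) & (y_test == 1)))
    tn = int(np.sum((y_pred == 0) & (y_test == 0)))
    fp = int(np.sum((y_pred == 1) & (y_test == 0)))
    fn = int(np.sum((y_pred == 0) & (y_test == 1)))
    scalar = confusion_metrics(tp, tn, fp, fn)
    points, auc_value = roc_auc(_continuous_scores(model, x_test), y_test)
    return FoldMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=scalar.accuracy, precision=scalar.precision,
        sensitivity=scalar.sensitivity, f1=scalar.f1, mcc=scalar.mcc,
        auc=auc_value, roc_points=points, undefined_rates=scalar.undefined_rates,
    )


def _aggregate(folds: list[FoldMetrics], k: int, spec: ClassifierSpec | None,
               alpha: float | None) -> CVReport:
    mean = {m: float(np.mean([getattr(f, m) for f in folds])) for m in METRIC_NAMES}
    std = {m: float(np.std([getattr(f, m) for f in folds])) for m in METRIC_NAMES}
    return CVReport(k=k, folds=folds, mean=mean, std=std, classifier=spec, alpha=alpha)


def cv_splitter(k: int, seed: int, stratify: bool = True):
    cls = StratifiedKFold if stratify else KFold
    return cls(n_splits=k, shuffle=True, random_state=seed)


def swap_orientation(features: np.ndarray) -> np.ndarray:
    """Exchange the two embedding halves of concatenated pair features."""
    d2 = features.shape[1]
    if d2 % 2:
        raise ValueError("pair features must have even width")
    half = d2 // 2
    return np.concatenate([features[:, half:], features[:, :half]], axis=1)


def run_cv(
    features: PairFeatureMatrix,
    spec: ClassifierSpec | None = None,
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
    augment_orientations: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation of one classifier on pair features.

    With ``augment_orientations`` each training fold additionally contains
    every pair with its embedding halves swapped, making the fitted decision
    function insensitive to pair orientation; test folds keep the canonical
    orientation.
    """
    spec = spec or ClassifierSpec()
    if k < 2:
        raise ValueError("k must be at least 2")
    x, y = features.features, features.labels
    folds: list[FoldMetrics] = []
    for train_idx, test_idx in cv_splitter(k, seed, stratify).split(x, y):
        x_train, y_train = x[train_idx], y[train_idx]
        if augment_orientations:
            x_train = np.concatenate([x_train, swap_orientation(x_train)])
            y_train = np.concatenate([y_train, y_train])
        model = make_classifier(spec)
        model.fit(x_train, y_train)
        folds.append(evaluate_fold(model, x[test_idx], y[test_idx]))
    return _aggregate(folds, k, spec, alpha=None)


def embed_and_evaluate(
    s_net: SimilarityMatrix,
    s_seq: SimilarityMatrix,
    dataset: PairDataset,
    alpha: float,
    sae_config: SAEConfig | None = None,
    spec: ClassifierSpec | None = None,
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
) -> CVReport:
    """fuse -> train SAE -> embed -> pair features -> run_cv for one alpha."""
    fused = fuse(s_net, s_seq, alpha)
    encoder, _ = train_sae(fused, sae_config)
    embeddings = encode(encoder, fused.values)
    features = build_pair_features(embeddings, dataset)
    report = run_cv(features, spec, k=k, seed=seed, stratify=stratify)
    report.alpha = float(alpha)
    return report


def grid_search_alpha(
    s_net: SimilarityMatrix,
    s_seq: SimilarityMatrix,
    dataset: PairDataset,
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    sae_config: SAEConfig | None = None,
    spec: ClassifierSpec | None = None,
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[dict[float, CVReport], float]:
    """Sweep the fusion weight; return per-alpha reports and the selected alpha.

    Selection maximises mean accuracy; ties break toward the smaller alpha.
    """
    alphas = tuple(float(a) for a in alphas)
    if not alphas:
        raise ValueError("alpha grid must be non-empty")
    if any(not 0.0 <= a <= 1.0 for a in alphas):
        raise ValueError("alphas must lie in [0, 1]")
    reports: dict[float, CVReport] = {}
    for alpha in alphas:
        reports[alpha] = embed_and_evaluate(
            s_net, s_seq, dataset, alpha, sae_config, spec, k=k, seed=seed,
            stratify=stratify,
        )
    selected = min(sorted(reports), key=lambda a: (-reports[a].mean["accuracy"], a))
    return reports, selected
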