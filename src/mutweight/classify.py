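"""Classification-evaluation harness.

Protocol: the labeled cohort is split, stratified by class, into 80%
training and 20% held-out test data.  Hyperparameters are tuned by 10-fold
cross-validation on the training portion.  Testing is then repeated 10
times: the tuned model is retrained on each of the 10 cross-validation
training partitions of the 80% and evaluated every time on the same 20%,
so the reported mean +/- std reflects sensitivity to minor changes of the
training data while the test samples never enter tuning or training.

Metrics: accuracy; f-score, precision and recall under micro, macro and
class-weighted averaging (for single-label multiclass data micro
precision = micro recall = micro F1 = accuracy, so the macro and weighted
variants are what distinguish per-class behaviour); a scalar false
positive rate (class-weighted mean of the per-class one-vs-rest
FP / (FP + TN)); and one-vs-rest macro ROC-AUC from predicted class
probabilities (softmax-normalised decision scores for SVMs).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .corpus_io import MutationMatrix
from .nn import FeedForwardNN
from .weighting import RepresentationMatrix, WeightingConfig
from .weighting import fit as fit_weighter
from .weighting import transform as apply_weighter

__all__ = [
    "ALGORITHMS",
    "EvaluationProtocol",
    "Split",
    "MetricsReport",
    "ExperimentResult",
    "make_estimator",
    "split_and_fold",
    "tune",
    "evaluate",
    "fpr_per_class",
    "compute_fold_metrics",
    "weighted_features",
    "run_experiment",
]

#: Supported algorithm names.
ALGORITHMS = (
    "nb",
    "knn",
    "svm_linear",
    "svm_poly",
    "svm_rbf",
    "lr",
    "perceptron",
    "nn",
)


@dataclass(frozen=True)
class EvaluationProtocol:
    """Split / fold layout of one evaluation run."""

    test_fraction: float = 0.20
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class Split:
    """Indices of one stratified split: held-out test set plus CV folds.

    ``folds`` holds ``n_folds`` pairs of absolute index arrays
    ``(fold_train, fold_val)`` partitioning ``train_idx``.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]


def make_estimator(algorithm: str, params: Mapping | None = None, seed: int = 0):
    """Instantiate a classifier by name.

    ``params`` are algorithm-native keyword arguments (e.g. ``n_neighbors``
    for knn, ``C``/``gamma`` for SVMs, ``first_layer_units`` for nn).
    """
    params = dict(params or {})
    if algorithm == "nb":
        return MultinomialNB(**params)
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm in ("svm_linear", "svm_poly", "svm_rbf"):
        kernel = {"svm_linear": "linear", "svm_poly": "poly", "svm_rbf": "rbf"}[algorithm]
        params.setdefault("random_state", seed)
        return SVC(kernel=kernel, **params)
    if algorithm == "lr":
        params.setdefault("max_iter", 1000)
        params.setdefault("random_state", seed)
        return LogisticRegression(**params)
    if algorithm == "perceptron":
        # single-hidden-layer network; width/optimiser/activation tunable
        hidden = params.pop("hidden_layer_size", 100)
        params.setdefault("max_iter", 200)
        params.setdefault("random_state", seed)
        return MLPClassifier(hidden_layer_sizes=(hidden,), **params)
    if algorithm == "nn":
        params.setdefault("random_state", seed)
        return FeedForwardNN(**params)
    raise ValueError(
        f"unknown algorithm {algorithm!r}; supported algorithms: {', '.join(ALGORITHMS)}"
    )


def _as_X(matrix) -> np.ndarray:
    if isinstance(matrix, RepresentationMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=np.float64)


def split_and_fold(matrix, labels: Sequence, protocol: EvaluationProtocol) -> Split:
    """Stratified 80/20 split plus stratified K-fold layout of the 80%.

    Deterministic given ``protocol.seed``.  Raises if any class has fewer
    training samples than folds.
    """
    X = _as_X(matrix)
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels length does not match number of samples")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=protocol.test_fraction,
        stratify=y,
        random_state=protocol.seed,
    )
    classes, counts = np.unique(y[train_idx], return_counts=True)
    thin = classes[counts < protocol.n_folds]
    if thin.size:
        raise ValueError(
            f"classes {list(thin)} have fewer than {protocol.n_folds} training samples; "
            f"use fewer folds"
        )
    skf = StratifiedKFold(n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed)
    folds = [
        (train_idx[tr], train_idx[va]) for tr, va in skf.split(train_idx, y[train_idx])
    ]
    return Split(np.sort(train_idx), np.sort(test_idx), folds)


def _expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    """Cartesian product of a name -> values grid, in listed order."""
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def tune(
    algorithm: str,
    grid: Mapping[str, Sequence] | Sequence[Mapping],
    matrix,
    labels: Sequence,
    split: Split,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Grid search by mean cross-validation accuracy over the split's folds.

    ``grid`` is either a mapping of parameter name -> candidate values or
    an explicit sequence of parameter dicts.  Ties are broken by grid
    order (first listed wins).  Returns (best params, per-point results).
    """
    X = _as_X(matrix)
    y = np.asarray(labels)
    points = list(grid) if not isinstance(grid, Mapping) else _expand_grid(grid)
    if not points:
        raise ValueError("parameter grid is empty")
    rows = []
    best_params, best_acc = None, -np.inf
    for pi, params in enumerate(points):
        accs = []
        try:
            for fi, (tr, va) in enumerate(split.folds):
                model = make_estimator(algorithm, params, seed=seed + fi)
                model.fit(X[tr], y[tr])
                accs.append(accuracy_score(y[va], model.predict(X[va])))
            mean_acc = float(np.mean(accs))
            std_acc = float(np.std(accs))
        except ValueError as exc:
            # infeasible grid point (e.g. more neighbours than fold samples):
            # recorded but never selected
            warnings.warn(f"grid point {params} is infeasible: {exc}", stacklevel=2)
            mean_acc, std_acc = float("nan"), float("nan")
        rows.append({**params, "mean_cv_accuracy": mean_acc, "std_cv_accuracy": std_acc})
        if mean_acc > best_acc:  # strict: ties keep the earlier grid point
            best_acc, best_params = mean_acc, dict(params)
    if best_params is None:
        raise ValueError("no feasible grid point; every candidate failed to fit")
    return best_params, pd.DataFrame(rows)


def fpr_per_class(y_true, y_pred, classes) -> np.ndarray:
    """One-vs-rest false positive rate FP / (FP + TN) for each class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = np.empty(len(classes))
    for i, c in enumerate(classes):
        fp = np.sum((y_pred == c) & (y_true != c))
        tn = np.sum((y_pred != c) & (y_true != c))
        out[i] = fp / (fp + tn) if fp + tn else 0.0
    return out


def _proba_scores(model, X: np.ndarray) -> np.ndarray | None:
    """Class-probability scores for ROC-AUC; softmaxed decision scores as fallback."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))
    if hasattr(model, "decision_function"):
        scores = np.asarray(model.decision_function(X))
        if scores.ndim == 1:  # binary decision function
            scores = np.column_stack([-scores, scores])
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)
    return None


def compute_fold_metrics(y_true, y_pred, proba=None, classes=None) -> dict:
    """Metric suite for one test repetition.

    Returns accuracy, {micro, macro, weighted} x {f_score, precision,
    recall}, the class-weighted FPR, and macro one-vs-rest ROC-AUC (NaN,
    with a warning, when probabilities are unavailable or a class is
    absent from the truth).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    out = {"accuracy": float(accuracy_score(y_true, y_pred))}
    for avg in ("micro", "macro", "weighted"):
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average=avg, zero_division=0
        )
        out[f"precision_{avg}"] = float(p)
        out[f"recall_{avg}"] = float(r)
        out[f"f_score_{avg}"] = float(f)
    fprs = fpr_per_class(y_true, y_pred, classes)
    weights = np.array([(y_true == c).sum() for c in classes], dtype=float)
    weights = weights / weights.sum() if weights.sum() else weights
    out["fpr"] = float(fprs @ weights)
    out["roc_auc"] = float("nan")
    if proba is not None:
        present = np.isin(classes, np.unique(y_true))
        if not present.all():
            warnings.warn(
                f"classes {list(classes[~present])} absent from the test truth; "
                f"roc_auc is undefined and reported as NaN",
                stacklevel=2,
            )
        else:
            try:
                if len(classes) == 2:
                    out["roc_auc"] = float(roc_auc_score(y_true, proba[:, 1]))
                else:
                    out["roc_auc"] = float(
                        roc_auc_score(y_true, proba, multi_class="ovr", average="macro", labels=classes)
                    )
            except ValueError as exc:
                warnings.warn(f"roc_auc undefined: {exc}", stacklevel=2)
    return out


@dataclass
class MetricsReport:
    """Mean +/- std of every metric over the test repetitions, plus a
    pooled per-class table (f-score, precision, recall, FPR)."""

    algorithm: str
    params: dict
    per_fold: pd.DataFrame
    per_class: pd.DataFrame
    classes: list

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold.std(ddof=0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "std": self.std})

    def to_json_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "params": {k: v for k, v in self.params.items()},
            "metrics": {
                col: {"mean": float(self.mean[col]), "std": float(self.std[col])}
                for col in self.per_fold.columns
            },
            "per_class": self.per_class.reset_index().to_dict(orient="records"),
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        acc = self.mean.get("accuracy", float("nan"))
        return f"MetricsReport({self.algorithm}, accuracy={acc:.4f}, n_models={len(self.per_fold)})"


def _audit_no_leakage(split: Split) -> None:
    test = set(split.test_idx.tolist())
    for tr, va in split.folds:
        overlap = test.intersection(tr.tolist()).union(test.intersection(va.tolist()))
        if overlap:
            raise AssertionError(f"test samples leaked into tuning/training folds: {sorted(overlap)[:10]}")


def evaluate(
    algorithm: str,
    params: Mapping | None,
    matrix,
    labels: Sequence,
    split: Split,
    seed: int = 0,
    return_models: bool = False,
):
    """Run the repeated-test protocol for one tuned model.

    One model per fold is trained on that fold's training partition of the
    80% and evaluated on the common held-out 20%; a leakage audit asserts
    the test indices never intersect any fold.  Per-class metrics are
    computed one-vs-rest on the pooled predictions of all repetitions.
    """
    X = _as_X(matrix)
    y = np.asarray(labels)
    _audit_no_leakage(split)
    classes = np.unique(y)
    X_test, y_test = X[split.test_idx], y[split.test_idx]
    rows, pooled_pred, models = [], [], []
    for fi, (tr, _va) in enumerate(split.folds):
        model = make_estimator(algorithm, params, seed=seed + fi)
        model.fit(X[tr], y[tr])
        y_pred = model.predict(X_test)
        proba = _proba_scores(model, X_test)
        rows.append(compute_fold_metrics(y_test, y_pred, proba, classes))
        pooled_pred.append(y_pred)
        models.append(model)

    per_fold = pd.DataFrame(rows)
    pooled = np.concatenate(pooled_pred)
    pooled_true = np.tile(y_test, len(split.folds))
    p, r, f, _ = precision_recall_fscore_support(
        pooled_true, pooled, labels=classes, average=None, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "f_score": f,
            "precision": p,
            "recall": r,
            "fpr": fpr_per_class(pooled_true, pooled, classes),
        },
        index=pd.Index(classes, name="class"),
    )
    report = MetricsReport(algorithm, dict(params or {}), per_fold, per_class, list(classes))
    if return_models:
        return report, models
    return report


def _subset_matrix(m: MutationMatrix, idx: np.ndarray, keep_labels: bool = True) -> MutationMatrix:
    labels = [m.labels[i] for i in idx] if (keep_labels and m.labels is not None) else None
    score_sums = m.score_sums[idx] if m.score_sums is not None else None
    return MutationMatrix(
        m.counts[idx], list(m.genes), [m.sample_ids[i] for i in idx], labels, score_sums
    )


def weighted_features(
    m: MutationMatrix, config: WeightingConfig, split: Split | None = None
) -> RepresentationMatrix:
    """Featurize a mutation matrix for an evaluation split.

    With ``statistics_source='fit_corpus'`` and a split, the df/rf
    statistics come from the 80% training portion only; training rows are
    weighted with their true class, test rows per ``rf_test_policy``.
    With ``'transductive'`` (or no split) the weighter is fitted on, and
    applied to, the whole corpus with true labels throughout — closer to
    a whole-corpus preprocessing pipeline, but a leakage trade-off that
    should be stated with any reported score.
    """
    whole_corpus = (
        split is None
        or config.statistics_source == "transductive"
        or config.scheme in ("binary", "cscore")
    )
    if whole_corpus:
        w = fit_weighter(m, config)
        return apply_weighter(w, m)

    m_train = _subset_matrix(m, split.train_idx)
    w = fit_weighter(m_train, config)
    values = np.zeros((m.n_samples, m.n_genes))
    values[split.train_idx] = apply_weighter(w, m_train).values
    use_true = config.supervised and config.rf_test_policy == "true_label"
    m_test = _subset_matrix(m, split.test_idx, keep_labels=use_true)
    values[split.test_idx] = apply_weighter(w, m_test).values
    return RepresentationMatrix(values, list(m.genes), list(m.sample_ids), config.scheme)


@dataclass
class ExperimentResult:
    """Everything produced by one scheme x algorithm evaluation run."""

    config: WeightingConfig
    protocol: EvaluationProtocol
    split: Split
    features: RepresentationMatrix
    params: dict
    report: MetricsReport
    models: list
    tuning: pd.DataFrame | None = None


def run_experiment(
    m: MutationMatrix,
    config: WeightingConfig,
    protocol: EvaluationProtocol,
    algorithm: str,
    params: Mapping | None = None,
    grid: Mapping | None = None,
) -> ExperimentResult:
    """Full pipeline: split, featurize, (optionally) tune, repeated test.

    ``grid`` triggers cross-validated tuning on the training folds; its
    winner is merged over ``params``.  Requires ``m.labels``.
    """
    if m.labels is None:
        raise ValueError("evaluation requires a labeled mutation matrix")
    split = split_and_fold(m.counts, m.labels, protocol)
    features = weighted_features(m, config, split)
    params = dict(params or {})
    tuning = None
    if grid:
        best, tuning = tune(algorithm, grid, features, m.labels, split, seed=protocol.seed)
        params.update(best)
    report, models = evaluate(
        algorithm, params, features, m.labels, split, seed=protocol.seed, return_models=True
    )
    return ExperimentResult(config, protocol, split, features, params, report, models, tuning)
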