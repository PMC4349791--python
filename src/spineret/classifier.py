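"""The retrieval-gating classifier (PMCVNN).

A one-hidden-layer perceptron trained under stratified 5-fold cross
validation: for each fold the network is fitted on the other four folds
and scored (accuracy, macro one-vs-rest AUC) on the held-out fold; the
fold with the best held-out AUC supplies the deployed model.  Features
are min-max normalized with statistics from the training folds only.

Training uses scikit-learn's MLP; prediction runs through the stored
weights directly (logistic hidden layer, softmax or sigmoid output), so
a serialized model is a self-contained JSON document.

AUC is computed by the rank (Mann-Whitney) formulation with ties
counted one half, which agrees exactly with exhaustive pairwise
comparison; the multiclass value is the macro average over one-vs-rest
problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

__all__ = [
    "NormalizationParams",
    "PMCVNNModel",
    "ROCResult",
    "fit_normalizer",
    "apply_normalizer",
    "train_pmcvnn",
    "predict_class",
    "roc_auc",
    "roc_auc_multiclass",
]

DEFAULT_FOLDS = 5
DEFAULT_HIDDEN = 20
MAX_EPOCHS = 500
PATIENCE = 25


@dataclass
class NormalizationParams:
    """Per-dimension min-max statistics from training data."""

    mins: np.ndarray
    maxs: np.ndarray


def fit_normalizer(features: np.ndarray) -> NormalizationParams:
    """Min-max statistics per dimension (>= 1 training vector)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.size == 0:
        raise ValueError("cannot fit a normalizer on no data")
    return NormalizationParams(x.min(axis=0), x.max(axis=0))


def apply_normalizer(params: NormalizationParams, features: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; constant dimensions map to 0, test values clipped."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != params.mins.size:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match normalizer "
            f"({params.mins.size})"
        )
    span = params.maxs - params.mins
    out = np.zeros_like(x)
    ok = span > 1e-300
    out[:, ok] = (x[:, ok] - params.mins[ok]) / span[ok]
    out = np.clip(out, 0.0, 1.0)
    return out if np.asarray(features).ndim > 1 else out[0]


def denormalize(params: NormalizationParams, features: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    out = x * (params.maxs - params.mins) + params.mins
    return out if np.asarray(features).ndim > 1 else out[0]


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    averaging: str = "binary"


@dataclass
class PMCVNNModel:
    """Trained gating classifier: weights, normalizer, fold metrics."""

    weights: list  # [W_hidden (d, h), W_out (h, c or 1)]
    biases: list
    classes: list
    normalizer: NormalizationParams
    hidden: int
    seed: int
    fold_metrics: list = field(default_factory=list)  # dicts: fold, accuracy, auc
    selected_fold: int = 0

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Per-class probabilities for raw (unnormalized) features."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        xn = apply_normalizer(self.normalizer, x)
        h = 1.0 / (1.0 + np.exp(-(xn @ self.weights[0] + self.biases[0])))
        o = h @ self.weights[1] + self.biases[1]
        if o.shape[1] == 1:  # binary net: sigmoid output for the second class
            p1 = 1.0 / (1.0 + np.exp(-o[:, 0]))
            probs = np.column_stack([1.0 - p1, p1])
        else:
            e = np.exp(o - o.max(axis=1, keepdims=True))
            probs = e / e.sum(axis=1, keepdims=True)
        return probs if np.asarray(features).ndim > 1 else probs[0]

    def predict(self, features: np.ndarray):
        """Predicted labels (argmax, index-order tie-break)."""
        probs = np.atleast_2d(self.scores(features))
        labels = np.asarray(self.classes, dtype=object)[probs.argmax(axis=1)]
        return labels if np.asarray(features).ndim > 1 else labels[0]


def roc_auc(scores, labels) -> ROCResult:
    """Binary ROC curve and rank-based AUC (ties counted 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # keep only the last point of each threshold plateau
    last = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    return ROCResult(fpr, tpr, float(auc))


def roc_auc_multiclass(score_matrix: np.ndarray, labels, classes) -> float:
    """Macro one-vs-rest AUC over the columns of a score matrix."""
    score_matrix = np.asarray(score_matrix, dtype=float)
    labels = np.asarray(labels)
    aucs = []
    for ci, cls in enumerate(classes):
        binary = labels == cls
        if binary.any() and not binary.all():
            aucs.append(roc_auc(score_matrix[:, ci], binary).auc)
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def _fit_mlp(x, y, hidden, seed):
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="adam",
        learning_rate_init=0.01,  # full-batch steps on small datasets
        max_iter=MAX_EPOCHS,
        n_iter_no_change=PATIENCE,
        tol=1e-6,
        random_state=seed,
    )
    import warnings as _w
    from sklearn.exceptions import ConvergenceWarning

    with _w.catch_warnings():
        _w.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, y)
    return clf


def train_pmcvnn(
    X,
    y,
    k: int = DEFAULT_FOLDS,
    hidden: int = DEFAULT_HIDDEN,
    seed: int = 0,
    invert_folds: bool = False,
) -> PMCVNNModel:
    """Stratified k-fold cross-validated perceptron training.

    Standard semantics: train on k-1 folds, evaluate on the held-out
    fold; the fold with the best held-out macro AUC supplies the model
    (lowest fold index on ties).  ``invert_folds=True`` swaps the roles
    (train on one fold, test on the rest).  Deterministic given the
    seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    counts = {c: int((y == c).sum()) for c in classes}
    bad = [c for c, n in counts.items() if n < k]
    if bad:
        raise ValueError(f"classes with fewer than {k} samples: {bad}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    best = None
    fold_metrics = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        if invert_folds:
            train_idx, test_idx = test_idx, train_idx
        norm = fit_normalizer(X[train_idx])
        x_train = apply_normalizer(norm, X[train_idx])
        x_test = apply_normalizer(norm, X[test_idx])
        clf = _fit_mlp(x_train, y[train_idx], hidden, seed)
        probs = clf.predict_proba(x_test)
        # align probability columns with the sorted global class list
        col = {c: i for i, c in enumerate(clf.classes_.tolist())}
        full = np.zeros((len(test_idx), len(classes)))
        for ci, c in enumerate(classes):
            if c in col:
                full[:, ci] = probs[:, col[c]]
        if len(set(y[test_idx].tolist())) > 1:
            auc = roc_auc_multiclass(full, y[test_idx], classes)
        else:
            auc = float("nan")
        acc = float((clf.predict(x_test) == y[test_idx]).mean())
        fold_metrics.append({"fold": fold, "accuracy": acc, "auc": auc})
        if best is None or (np.isfinite(auc) and auc > best[0] + 1e-12):
            best = (auc if np.isfinite(auc) else -1.0, fold, clf, norm)

    _, sel_fold, clf, norm = best
    weights = [np.asarray(w) for w in clf.coefs_]
    biases = [np.asarray(b) for b in clf.intercepts_]
    model = PMCVNNModel(
        weights=weights,
        biases=biases,
        classes=[c for c in clf.classes_.tolist()],
        normalizer=norm,
        hidden=hidden,
        seed=seed,
        fold_metrics=fold_metrics,
        selected_fold=sel_fold,
    )
    model._sklearn = clf  # kept for cross-checks; not serialized
    return model


def predict_class(model: PMCVNNModel, feature: np.ndarray):
    """Predicted label and per-class scores for one raw feature vector.

    The model's own normalizer is applied internally; scores sum to 1
    and the label is the argmax with index-order tie-break.
    """
    scores = model.scores(np.asarray(feature, dtype=float))
    label = model.classes[int(np.argmax(scores))]
    return label, scores


def save_model(model: PMCVNNModel, path: str | Path) -> None:
    payload = {
        "format_version": 1,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "classes": list(model.classes),
        "normalizer": {"mins": model.normalizer.mins.tolist(),
                       "maxs": model.normalizer.maxs.tolist()},
        "hidden": model.hidden,
        "seed": model.seed,
        "fold_metrics": model.fold_metrics,
        "selected_fold": model.selected_fold,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PMCVNNModel:
    p = json.loads(Path(path).read_text())
    return PMCVNNModel(
        weights=[np.array(w) for w in p["weights"]],
        biases=[np.array(b) for b in p["biases"]],
        classes=p["classes"],
        normalizer=NormalizationParams(np.array(p["normalizer"]["mins"]),
                                       np.array(p["normalizer"]["maxs"])),
        hidden=p["hidden"],
        seed=p["seed"],
        fold_metrics=p["fold_metrics"],
        selected_fold=p["selected_fold"],
    )
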