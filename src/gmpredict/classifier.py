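"""Linear maximum-margin classification with nested selection of C.

The decision function is f(x) = w.x + b, fit by minimising
0.5 ||w||^2 + C * sum_i hinge(y_i f(x_i)) — the soft-margin linear SVM.
The solver is delegated to libsvm (through scikit-learn's SVC), the same
family of implementation used in classical VBM classification studies; the
contract tested here is the optimisation problem itself (hard-margin
geometry on separable toys, objective invariances, determinism), not the
solver internals.

Gray-matter probabilities already live on a common [0, 1] scale, so
features are not rescaled by default; an optional per-feature
standardisation (fit on training data only) is available for other inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import sklearn
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: Candidate penalty values scanned by the nested inner loop.
DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)

DEFAULT_INNER_FOLDS = 5

#: libsvm stopping tolerance; tight enough for 1e-6 agreement with a
#: quadratic-program oracle on small problems.
SOLVER_TOL = 1e-8


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class LinearModel:
    """Trained linear decision function w.x + b.

    ``class_labels`` is the ordered (negative, positive) pair; decision
    values >= 0 predict the positive class (the tie at exactly 0 is pinned
    to positive so confusion counts are reproducible).
    """

    weights: np.ndarray
    bias: float
    C: float
    class_labels: tuple[str, str]
    #: optional provenance: which voxel mask the weights refer to, and the
    #: hash of the experiment configuration that produced the model
    mask_ref: str | None = None
    config_hash: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64).ravel()
        object.__setattr__(self, "weights", w)
        if self.C <= 0:
            raise ClassifierError(f"C must be positive, got {self.C}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "C": self.C,
                "class_labels": list(self.class_labels),
                "mask_ref": self.mask_ref,
                "config_hash": self.config_hash,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"]),
            bias=float(d["bias"]),
            C=float(d["C"]),
            class_labels=(d["class_labels"][0], d["class_labels"][1]),
            mask_ref=d.get("mask_ref"),
            config_hash=d.get("config_hash"),
        )


def _as_matrix(features) -> np.ndarray:
    values = getattr(features, "values", features)
    return np.asarray(values, dtype=np.float64)


def _signed_labels(labels, class_labels: tuple[str, str] | None) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    present = sorted(set(labels.tolist()))
    if class_labels is None:
        if len(present) != 2:
            raise ClassifierError(f"need exactly two classes, got {present}")
        class_labels = (present[0], present[1])
    neg, pos = class_labels
    unknown = [v for v in present if v not in (neg, pos)]
    if unknown:
        raise ClassifierError(f"labels {unknown} not in class_labels {class_labels}")
    if len(present) < 2:
        raise ClassifierError(f"training labels contain a single class: {present}")
    y = np.where(labels == pos, 1.0, -1.0)
    return y, (neg, pos)


def train(
    features,
    labels,
    C: float = 1.0,
    class_labels: tuple[str, str] | None = None,
    standardize: bool = False,
    tol: float = SOLVER_TOL,
) -> LinearModel:
    """Fit the soft-margin linear SVM at penalty ``C``.

    Deterministic for fixed input.  ``class_labels`` orders the classes as
    (negative, positive); by default the sorted label values are used.
    With ``standardize`` the weights are expressed back on the original
    feature scale.
    """
    X = _as_matrix(features)
    if not np.all(np.isfinite(X)):
        raise ClassifierError("features contain non-finite values")
    y, class_labels = _signed_labels(labels, class_labels)
    if len(y) != X.shape[0]:
        raise ClassifierError(f"{len(y)} labels for {X.shape[0]} rows")
    mu = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    clf = SVC(kernel="linear", C=C, tol=tol, shrinking=False, cache_size=64)
    clf.fit(X, y)
    # classes_ is [-1, 1]; decision_function > 0 means class +1 == positive.
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    if standardize:
        w = w / sd
        b = b - float(np.dot(w, mu))
    return LinearModel(weights=w, bias=b, C=C, class_labels=class_labels)


def decision_values(model: LinearModel, features) -> np.ndarray:
    """Signed distances-like scores w.x + b, one per subject."""
    X = _as_matrix(features)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.weights.shape[0]:
        raise ClassifierError(
            f"feature count {X.shape[1]} does not match model ({model.weights.shape[0]})"
        )
    return X @ model.weights + model.bias


def predict(model: LinearModel, features) -> np.ndarray:
    d = decision_values(model, features)
    neg, pos = model.class_labels
    return np.where(d >= 0, pos, neg)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    accs = []
    for cls in (-1.0, 1.0):
        m = y_true == cls
        if m.any():
            accs.append(float(np.mean(y_pred[m] == cls)))
    return float(np.mean(accs))


def select_C(
    features,
    labels,
    grid=DEFAULT_C_GRID,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
    class_labels: tuple[str, str] | None = None,
) -> float:
    """Pick C from ``grid`` by stratified inner cross-validation.

    The winner maximises mean balanced accuracy over the inner folds; ties
    break toward the smallest C (prefer the stronger-regularised model).
    A single-value grid is returned as-is without any fold computation.
    """
    grid = tuple(float(c) for c in grid)
    if len(grid) == 0 or any(c <= 0 for c in grid):
        raise ClassifierError(f"C grid must be nonempty and positive: {grid}")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ClassifierError(f"C grid must be strictly increasing: {grid}")
    if len(grid) == 1:
        return grid[0]
    X = _as_matrix(features)
    y, _ = _signed_labels(labels, class_labels)
    counts = [int(np.sum(y == c)) for c in (-1.0, 1.0)]
    if inner_folds < 2 or inner_folds > min(counts):
        raise ClassifierError(
            f"inner_folds={inner_folds} incompatible with class counts {counts}"
        )
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=int(seed) % (2**31))
    splits = list(skf.split(X, y))
    best_c, best_score = grid[0], -np.inf
    with sklearn.config_context(assume_finite=True):
        for c in grid:
            fold_scores = []
            for tr, te in splits:
                clf = SVC(kernel="linear", C=c, shrinking=False, cache_size=64)
                clf.fit(X[tr], y[tr])
                d = clf.decision_function(X[te])
                fold_scores.append(_balanced_accuracy(y[te], np.where(d >= 0, 1.0, -1.0)))
            score = float(np.mean(fold_scores))
            if score > best_score + 1e-12:
                best_score, best_c = score, c
    return best_c
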