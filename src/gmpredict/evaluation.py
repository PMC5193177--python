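"""Resampling and inference for site-matched classification models.

This module implements the evaluation protocol used for pooled
multi-center gray-matter models:

* **balanced subsampling** — within each acquisition site, keep every
  member of the (globally) smaller class and a random equally-sized subset
  of the larger class, so pooled models are trained on balanced groups
  matched for site;
* **leave-two-out cross-validation (L2O)** — each fold holds out one
  subject of each class, and the held-out pair always comes from the same
  site; the penalty C is chosen per fold by nested stratified inner CV on
  the training subjects only;
* **bootstrap ensembles** — the subsample + L2O cycle is repeated (100
  times by default) with fresh random selections, and predictive values
  are averaged over repetitions;
* **permutation testing** — class labels are shuffled (within site) and
  the full pipeline re-run; the p-value is the fraction of null metrics at
  least as large as the observed one.

Per-class accuracies are sensitivity/specificity-style (correct members of
a class over all members of that class); PPA/NPA are the predictive
accuracies TP/(TP+FP) and TN/(TN+FN).  Undefined ratios (zero denominator)
propagate as missing rather than zero.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .classifier import DEFAULT_C_GRID, DEFAULT_INNER_FOLDS
from .cohort import Cohort
from .imaging import FeatureMatrix

logger = logging.getLogger("gmpredict")

#: Conventional positive class per classification task, fixing the
#: orientation of PPA/NPA and of reported per-class accuracies.
POSITIVE_CLASS = {"sex": "male", "course_label": "continuous"}


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    """PPA/NPA and per-class accuracies; ``None`` marks undefined ratios."""

    ppa: Optional[float]
    npa: Optional[float]
    pos_class_accuracy: Optional[float]
    neg_class_accuracy: Optional[float]

    @property
    def balanced_accuracy(self) -> Optional[float]:
        defined = [a for a in (self.pos_class_accuracy, self.neg_class_accuracy) if a is not None]
        return float(np.mean(defined)) if defined else None

    def as_dict(self) -> dict:
        return {
            "ppa": self.ppa,
            "npa": self.npa,
            "pos_class_accuracy": self.pos_class_accuracy,
            "neg_class_accuracy": self.neg_class_accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(confusion: ConfusionCounts) -> Metrics:
    """PPA = TP/(TP+FP), NPA = TN/(TN+FN); per-class accuracies are
    TP/(TP+FN) for the positive class and TN/(TN+FP) for the negative one
    (e.g. correctly classified males over all males)."""
    return Metrics(
        ppa=_ratio(confusion.tp, confusion.tp + confusion.fp),
        npa=_ratio(confusion.tn, confusion.tn + confusion.fn),
        pos_class_accuracy=_ratio(confusion.tp, confusion.tp + confusion.fn),
        neg_class_accuracy=_ratio(confusion.tn, confusion.tn + confusion.fp),
    )


# ---------------------------------------------------------------------------
# Result containers


@dataclass(frozen=True)
class CVResult:
    """Outcome of one leave-two-out cross-validation run."""

    per_subject: pd.DataFrame  # subject_id, site, true_label, decision_value,
    # predicted_label, times_tested
    confusion: ConfusionCounts
    metrics: Metrics
    class_labels: tuple[str, str]  # (negative, positive)
    selected_C: tuple[float, ...] = ()

    def recount_confusion(self) -> ConfusionCounts:
        """Brute-force recount from the per-subject records."""
        neg, pos = self.class_labels
        tested = self.per_subject[self.per_subject.times_tested > 0]
        tp = int(((tested.true_label == pos) & (tested.predicted_label == pos)).sum())
        fn = int(((tested.true_label == pos) & (tested.predicted_label == neg)).sum())
        tn = int(((tested.true_label == neg) & (tested.predicted_label == neg)).sum())
        fp = int(((tested.true_label == neg) & (tested.predicted_label == pos)).sum())
        return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class EnsembleResult:
    n_bootstraps: int
    per_bootstrap: tuple[CVResult, ...]
    mean_metrics: dict
    per_site: dict  # site -> dict of mean metrics; "overall" key included
    class_labels: tuple[str, str]


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_values: tuple[float, ...]
    p_value: float
    metric: str


def permutation_p(observed: float, null_values: Sequence[float], smoothed: bool = False) -> float:
    """Fraction of null metric values >= the observed one (inclusive).

    The plain estimator can return exactly 0; ``smoothed`` applies the
    (k+1)/(N+1) correction instead.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise EvaluationError("need at least one permutation")
    k = int(np.sum(null_values >= observed))
    if smoothed:
        return (k + 1) / (null_values.size + 1)
    return k / null_values.size


# ---------------------------------------------------------------------------
# Seed derivation (counter-based, order-independent)


def _derive_seed(*parts: int) -> int:
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0])


def _site_key(site: str) -> int:
    return zlib.crc32(site.encode("utf-8"))


def _resolve_classes(
    values: Sequence[str], class_field: str, pos_label: Optional[str]
) -> tuple[str, str]:
    present = sorted(set(values))
    if len(present) != 2:
        raise EvaluationError(f"need exactly two classes in {class_field!r}, got {present}")
    if pos_label is None:
        pos_label = POSITIVE_CLASS.get(class_field)
        if pos_label not in present:
            pos_label = present[-1]
    if pos_label not in present:
        raise EvaluationError(f"positive label {pos_label!r} not among {present}")
    neg = [c for c in present if c != pos_label][0]
    return neg, pos_label


# ---------------------------------------------------------------------------
# Balanced subsampling


def balanced_subsample(cohort: Cohort, class_field: str, seed: int) -> Cohort:
    """Site-matched balanced selection.

    Within each site every member of the (globally) minority class is kept
    together with an equally-sized uniformly-random subset of the majority
    class.  If a site holds fewer majority members than minority members,
    the shortfall is drawn at random from the unselected majority members
    of the other sites, so the overall class counts come out equal.
    Input order is preserved.
    """
    values = [getattr(s, class_field) for s in cohort]
    neg, pos = _resolve_classes(values, class_field, None)
    counts = {c: values.count(c) for c in (neg, pos)}
    minority = neg if counts[neg] <= counts[pos] else pos
    majority = pos if minority == neg else neg
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    leftover_majority: list[int] = []
    n_majority_selected = 0
    for site in cohort.sites:
        min_idx = [i for i, s in enumerate(cohort) if s.site == site and values[i] == minority]
        maj_idx = [i for i, s in enumerate(cohort) if s.site == site and values[i] == majority]
        selected.extend(min_idx)
        take = min(len(min_idx), len(maj_idx))
        perm = rng.permutation(len(maj_idx))
        chosen = [maj_idx[j] for j in perm[:take]]
        leftover_majority.extend(maj_idx[j] for j in perm[take:])
        selected.extend(chosen)
        n_majority_selected += take
    deficit = counts[minority] - n_majority_selected
    if deficit > 0 and leftover_majority:
        pool = sorted(leftover_majority)
        extra = rng.choice(len(pool), size=min(deficit, len(pool)), replace=False)
        selected.extend(pool[j] for j in extra)
    return cohort.subset(sorted(selected))


# ---------------------------------------------------------------------------
# Leave-two-out cross-validation on a precomputed Gram matrix

# All SVM fits inside the CV engine go through the linear kernel in its
# precomputed form: the Gram matrix of the (few) subjects is computed once
# and every fold solves its dual problem on a submatrix, which is orders of
# magnitude cheaper than refitting in the (huge) voxel space while being
# numerically the same optimisation problem.


def _fit_decision(
    G: np.ndarray, y: np.ndarray, train: np.ndarray, test: np.ndarray, C: float
) -> np.ndarray:
    clf = SVC(kernel="precomputed", C=C, shrinking=False, cache_size=8)
    clf.fit(G[np.ix_(train, train)], y[train])
    return clf.decision_function(G[np.ix_(test, train)])


def _select_c_gram(
    G: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    c_grid: Sequence[float],
    inner_folds: int,
    seed: int,
) -> float:
    if len(c_grid) == 1:
        return float(c_grid[0])
    y_tr = y[train]
    k = min(inner_folds, int(np.sum(y_tr > 0)), int(np.sum(y_tr < 0)))
    if k < 2:
        return float(min(c_grid))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    splits = list(skf.split(np.zeros(len(train)), y_tr))
    best_c, best_score = float(min(c_grid)), -np.inf
    for c in c_grid:
        scores = []
        for tr_pos, te_pos in splits:
            tr, te = train[tr_pos], train[te_pos]
            d = _fit_decision(G, y, tr, te, float(c))
            pred = np.where(d >= 0, 1.0, -1.0)
            accs = [
                float(np.mean(pred[y[te] == cls] == cls))
                for cls in (-1.0, 1.0)
                if np.any(y[te] == cls)
            ]
            scores.append(float(np.mean(accs)))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best_c = score, float(c)
    return best_c


def leave_two_out_cv(
    cohort: Cohort,
    features: FeatureMatrix,
    class_field: str,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    pos_label: Optional[str] = None,
) -> CVResult:
    """Site-matched leave-two-out cross-validation.

    Within each site, subjects of the two classes are matched into random
    disjoint pairs (seeded per site, so one site's fold composition does
    not depend on which other sites are present).  For each pair, C is
    selected by nested inner CV on the remaining subjects, the model is
    trained on everything except the pair, and the pair's decision values
    and predictions are recorded.  Subjects a site cannot pair (class
    imbalance, or a single-class site) are never tested but stay in every
    training set; their rows carry ``times_tested == 0``.
    """
    if len(cohort) == 0:
        raise EvaluationError("empty cohort")
    rows = features.rows_for(cohort)
    X = features.values[rows]
    values = [getattr(s, class_field) for s in cohort]
    neg, pos = _resolve_classes(values, class_field, pos_label)
    y = np.where(np.asarray(values) == pos, 1.0, -1.0)
    G = np.ascontiguousarray(X @ X.T)

    pairs: list[tuple[int, int]] = []
    for site in cohort.sites:
        pos_idx = [i for i, s in enumerate(cohort) if s.site == site and y[i] > 0]
        neg_idx = [i for i, s in enumerate(cohort) if s.site == site and y[i] < 0]
        if not pos_idx or not neg_idx:
            logger.warning(
                "site %s has subjects of only one class; %d subjects routed to training only",
                site,
                len(pos_idx) + len(neg_idx),
            )
        rng = np.random.default_rng(_derive_seed(seed, _site_key(site)))
        pp = rng.permutation(len(pos_idx))
        np_ = rng.permutation(len(neg_idx))
        m = min(len(pos_idx), len(neg_idx))
        pairs.extend((pos_idx[pp[j]], neg_idx[np_[j]]) for j in range(m))

    n = len(cohort)
    decision = np.full(n, np.nan)
    predicted = np.array([""] * n, dtype=object)
    times_tested = np.zeros(n, dtype=int)
    chosen_cs: list[float] = []
    all_idx = np.arange(n)
    with sklearn.config_context(assume_finite=True):
        for fold, (i, j) in enumerate(pairs):
            train_idx = np.delete(all_idx, [i, j])
            c = _select_c_gram(G, y, train_idx, c_grid, inner_folds, _derive_seed(seed, 7, fold))
            chosen_cs.append(c)
            d = _fit_decision(G, y, train_idx, np.array([i, j]), c)
            for k, subj in zip((i, j), d):
                decision[k] = subj
                predicted[k] = pos if subj >= 0 else neg
                times_tested[k] += 1

    per_subject = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "site": [s.site for s in cohort],
            "true_label": values,
            "decision_value": decision,
            "predicted_label": predicted,
            "times_tested": times_tested,
        }
    )
    confusion = _count_confusion(per_subject, neg, pos)
    return CVResult(
        per_subject=per_subject,
        confusion=confusion,
        metrics=compute_metrics(confusion),
        class_labels=(neg, pos),
        selected_C=tuple(chosen_cs),
    )


def _count_confusion(per_subject: pd.DataFrame, neg: str, pos: str) -> ConfusionCounts:
    t = per_subject[per_subject.times_tested > 0]
    return ConfusionCounts(
        tp=int(((t.true_label == pos) & (t.predicted_label == pos)).sum()),
        fp=int(((t.true_label == neg) & (t.predicted_label == pos)).sum()),
        tn=int(((t.true_label == neg) & (t.predicted_label == neg)).sum()),
        fn=int(((t.true_label == pos) & (t.predicted_label == neg)).sum()),
    )


# ---------------------------------------------------------------------------
# Bootstrap ensemble


def _mean_defined(values: Sequence[Optional[float]]) -> Optional[float]:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def bootstrap_ensemble(
    cohort: Cohort,
    features: FeatureMatrix,
    class_field: str,
    n_bootstraps: int = 100,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    pos_label: Optional[str] = None,
) -> EnsembleResult:
    """Repeat (balanced subsample -> site-matched L2O) and average.

    Each repetition draws an independent balanced subsample and an
    independent pairing, with seeds derived from ``seed`` by a counter
    scheme; mean metrics are arithmetic means over repetitions where the
    metric is defined.  The per-site breakdown restricts the confusion
    counts of each repetition to one site before computing metrics.
    """
    if n_bootstraps < 1:
        raise EvaluationError("n_bootstraps must be >= 1")
    runs: list[CVResult] = []
    for b in range(n_bootstraps):
        sub = balanced_subsample(cohort, class_field, _derive_seed(seed, 11, b))
        runs.append(
            leave_two_out_cv(
                sub,
                features,
                class_field,
                c_grid=c_grid,
                seed=_derive_seed(seed, 13, b),
                inner_folds=inner_folds,
                pos_label=pos_label,
            )
        )
    class_labels = runs[0].class_labels
    mean_metrics = {
        key: _mean_defined([r.metrics.as_dict()[key] for r in runs])
        for key in ("ppa", "npa", "pos_class_accuracy", "neg_class_accuracy", "balanced_accuracy")
    }
    per_site: dict[str, dict] = {}
    for site in list(cohort.sites) + ["overall"]:
        site_metrics: dict[str, list] = {k: [] for k in mean_metrics}
        for r in runs:
            ps = r.per_subject
            part = ps if site == "overall" else ps[ps.site == site]
            if not (part.times_tested > 0).any():
                continue
            m = compute_metrics(_count_confusion(part, *r.class_labels)).as_dict()
            for k in site_metrics:
                site_metrics[k].append(m[k])
        per_site[site] = {k: _mean_defined(v) for k, v in site_metrics.items()}
    return EnsembleResult(
        n_bootstraps=n_bootstraps,
        per_bootstrap=tuple(runs),
        mean_metrics=mean_metrics,
        per_site=per_site,
        class_labels=class_labels,
    )


# ---------------------------------------------------------------------------
# Permutation test


def _permute_within_site(cohort: Cohort, class_field: str, rng: np.random.Generator) -> Cohort:
    new_values = np.array([getattr(s, class_field) for s in cohort], dtype=object)
    for site in cohort.sites:
        idx = [i for i, s in enumerate(cohort) if s.site == site]
        perm = rng.permutation(len(idx))
        new_values[idx] = new_values[[idx[j] for j in perm]]
    subjects = [replace(s, **{class_field: new_values[i]}) for i, s in enumerate(cohort)]
    return Cohort(tuple(subjects))


def permutation_test(
    cohort: Cohort,
    features: FeatureMatrix,
    class_field: str,
    n_permutations: int = 1000,
    seed: int = 0,
    metric: str = "balanced_accuracy",
    n_bootstraps: int = 1,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    pos_label: Optional[str] = None,
    smoothed: bool = False,
) -> PermutationResult:
    """Significance of the observed metric by label permutation.

    Class labels are shuffled within site (preserving the site structure
    the site-matched CV assumes) and the full subsample + L2O pipeline is
    re-run with the same internal seed stream as the observed run, so only
    the label assignment differs.  ``p = #(null >= observed) / n_permutations``
    (inclusive at ties, and 0 is representable; ``smoothed`` switches to
    the (k+1)/(N+1) estimator).
    """
    if n_permutations < 1:
        raise EvaluationError("n_permutations must be >= 1")
    pipeline_seed = _derive_seed(seed, 0)

    def run(c: Cohort) -> Optional[float]:
        ens = bootstrap_ensemble(
            c,
            features,
            class_field,
            n_bootstraps=n_bootstraps,
            seed=pipeline_seed,
            c_grid=c_grid,
            inner_folds=inner_folds,
            pos_label=pos_label,
        )
        return ens.mean_metrics[metric]

    observed = run(cohort)
    if observed is None:
        raise EvaluationError(f"observed metric {metric!r} is undefined")
    null_values = []
    for p in range(n_permutations):
        rng = np.random.default_rng(_derive_seed(seed, 1, p))
        permuted = _permute_within_site(cohort, class_field, rng)
        v = run(permuted)
        null_values.append(np.nan if v is None else v)
    null_arr = [v for v in null_values if np.isfinite(v)]
    return PermutationResult(
        observed=float(observed),
        null_values=tuple(float(v) for v in null_values),
        p_value=permutation_p(float(observed), null_arr, smoothed=smoothed),
        metric=metric,
    )
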