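"""Fisher-discriminant-ratio ranking and classification-guided forward
feature selection under leave-one-out cross-validation.

Per outer LOOCV fold (one held-out subject): features are ranked on the
training rows by the Fisher discriminant ratio

    FDR(x) = |mean_h - mean_s|^2 / (var_h + var_s)

(healthy = -1, schizophrenia = +1; population variances), then added in rank
order while an inner LOOCV on the training rows scores each subset size with
the chosen classifier (linear soft-margin SVM or 1-NN with Euclidean
distance); the smallest subset attaining the maximal inner accuracy trains
the fold's model, which predicts the held-out subject. This keeps the
held-out subject out of both ranking and subset choice. A documented
``literal_selection`` mode instead picks, per fold, the smallest subset that
classifies the held-out subject correctly — a leaky per-test-sample rule
kept only for comparison; a test demonstrates its optimistic bias.

Classifier fits are delegated to scikit-learn. The inner-LOOCV traces use
two exact fast paths: for 1-NN, a cumulative distance matrix over ranked
features; for the SVM, the Karush-Kuhn-Tucker shortcut that a training point
with zero dual coefficient has a leave-one-out prediction identical to the
full model's, so only support vectors are refit. Both are asserted equal to
brute-force refitting in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .region_features import FeatureMatrix

logger = logging.getLogger(__name__)

#: canonical cost sweep: 0.01 to 1000 in powers of 10
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
#: default operating point of the linear SVM
DEFAULT_C = 1.09


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier contract: linear C-SVC or k-nearest-neighbour.

    Defaults: C = 1.09 for the linear SVM; k = 1 with Euclidean distance
    for the neighbour classifier.
    """

    kind: str = "linear_svm"            # "linear_svm" | "knn"
    C: float = DEFAULT_C
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    k: int = 1
    metric: str = "euclidean"

    def __post_init__(self):
        if self.kind not in ("linear_svm", "knn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def build(self):
        if self.kind == "linear_svm":
            return SVC(kernel="linear", C=self.C)
        return KNeighborsClassifier(n_neighbors=self.k, metric=self.metric)


@dataclass
class FdrRanking:
    """Per-feature FDR scores and the descending-score feature order."""

    scores: np.ndarray
    order: np.ndarray    # rank 1 first; ties broken by ascending feature index


@dataclass
class FoldRecord:
    subject_id: str
    true_label: int
    predicted_label: int
    chosen: tuple[int, ...]       # original column indices
    inner_trace: np.ndarray       # inner accuracy (%) per subset size 1..M
    ranking_order: np.ndarray


@dataclass
class SelectionOutcome:
    """Aggregate LOOCV result: per-fold records and accuracy per repeat."""

    classifier: ClassifierSpec
    folds: list[list[FoldRecord]]      # [repeat][fold]
    accuracies_pct: np.ndarray         # one accuracy per repeat

    @property
    def mean_accuracy_pct(self) -> float:
        return float(np.mean(self.accuracies_pct))

    @property
    def spread_accuracy_pct(self) -> float:
        return float(np.std(self.accuracies_pct))

    def chosen_subsets(self) -> list[tuple[int, ...]]:
        """Chosen feature subsets over all folds and repeats."""
        return [f.chosen for rep in self.folds for f in rep]

    def union_chosen(self) -> set[int]:
        return set().union(*[set(c) for c in self.chosen_subsets()])

    def intersection_chosen(self) -> set[int]:
        subsets = [set(c) for c in self.chosen_subsets()]
        return set.intersection(*subsets) if subsets else set()


# ---------------------------------------------------------------------------
# FDR scoring and ranking
# ---------------------------------------------------------------------------

def _class_split(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    h = labels == -1
    s = labels == 1
    if not h.any() or not s.any():
        raise ValueError("both classes (+1 and -1) must be present")
    return h, s


def fdr_score(x: np.ndarray, labels: np.ndarray) -> float:
    """Fisher discriminant ratio of one feature between the two groups.

    ``|mean_h - mean_s|^2 / (var_h + var_s)`` with population variances. A
    zero denominator scores +inf when the means differ (perfect separation
    by a constant-within-class feature) and 0 when they agree.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    h, s = _class_split(labels)
    mh, ms = x[h].mean(), x[s].mean()
    vh, vs = x[h].var(), x[s].var()
    num = (mh - ms) ** 2
    den = vh + vs
    if den == 0.0:
        return float("inf") if num > 0 else 0.0
    return float(num / den)


def fdr_scores(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized FDR scores for every column of X."""
    X = np.asarray(X, dtype=float)
    h, s = _class_split(labels)
    mh = X[h].mean(axis=0)
    ms = X[s].mean(axis=0)
    vh = X[h].var(axis=0)
    vs = X[s].var(axis=0)
    num = (mh - ms) ** 2
    den = vh + vs
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[(den == 0) & (num > 0)] = np.inf
    out[(den == 0) & (num == 0)] = 0.0
    return out


def rank_features(X: np.ndarray, labels: np.ndarray) -> FdrRanking:
    """Rank features by descending FDR score; ties by ascending column index."""
    scores = fdr_scores(X, labels)
    if not np.all(np.isfinite(X)):
        bad = int(np.argwhere(~np.isfinite(X))[0, 1])
        raise ValueError(f"non-finite values in feature column {bad}")
    order = np.argsort(-scores, kind="stable")
    return FdrRanking(scores=scores, order=order)


# ---------------------------------------------------------------------------
# inner-LOOCV accuracy traces (exact fast paths)
# ---------------------------------------------------------------------------

def _knn_loo_trace(Xr: np.ndarray, y: np.ndarray, max_subset: int) -> np.ndarray:
    """1-NN leave-one-out accuracy for each prefix size of ranked features.

    Squared Euclidean distances accumulate over features, so the trace costs
    O(max_subset * n^2).
    """
    n = Xr.shape[0]
    d2 = np.zeros((n, n))
    acc = np.empty(max_subset)
    for m in range(max_subset):
        diff = Xr[:, m][:, None] - Xr[:, m][None, :]
        d2 += diff * diff
        work = d2.copy()
        np.fill_diagonal(work, np.inf)
        pred = y[np.argmin(work, axis=1)]
        acc[m] = 100.0 * np.mean(pred == y)
    return acc


def _svm_loo_accuracy(K: np.ndarray, y: np.ndarray, C: float) -> float:
    """Exact leave-one-out accuracy of a C-SVC with precomputed kernel K.

    Removing a training point whose dual coefficient is zero leaves the KKT
    solution — hence its own prediction — unchanged, so only support vectors
    need a refit.
    """
    n = len(y)
    full = SVC(kernel="precomputed", C=C).fit(K, y)
    pred = full.predict(K)
    correct = pred == y
    for i in full.support_:
        keep = np.arange(n) != i
        sub = SVC(kernel="precomputed", C=C).fit(K[np.ix_(keep, keep)], y[keep])
        p_i = sub.predict(K[i, keep][None, :])[0]
        correct[i] = p_i == y[i]
    return 100.0 * np.mean(correct)


def _svm_loo_trace(
    Xr: np.ndarray, y: np.ndarray, max_subset: int, C: float
) -> np.ndarray:
    """Linear-SVM LOO accuracy per prefix size, with an incremental Gram matrix."""
    n = Xr.shape[0]
    K = np.zeros((n, n))
    acc = np.empty(max_subset)
    for m in range(max_subset):
        K += np.outer(Xr[:, m], Xr[:, m])
        acc[m] = _svm_loo_accuracy(K, y, C)
    return acc


def inner_loocv_trace(
    X_ranked: np.ndarray, y: np.ndarray, clf: ClassifierSpec, max_subset: int
) -> np.ndarray:
    """Inner-LOOCV accuracy (%) of ``clf`` for each ranked-feature prefix."""
    if clf.kind == "knn" and clf.k == 1 and clf.metric == "euclidean":
        return _knn_loo_trace(X_ranked, y, max_subset)
    if clf.kind == "linear_svm":
        return _svm_loo_trace(X_ranked, y, max_subset, clf.C)
    # generic (slow) path for non-default neighbour settings
    n = len(y)
    acc = np.empty(max_subset)
    for m in range(1, max_subset + 1):
        correct = 0
        for i in range(n):
            keep = np.arange(n) != i
            model = clf.build().fit(X_ranked[keep, :m], y[keep])
            correct += model.predict(X_ranked[i, :m][None])[0] == y[i]
        acc[m - 1] = 100.0 * correct / n
    return acc


# ---------------------------------------------------------------------------
# forward selection and the outer LOOCV pipeline
# ---------------------------------------------------------------------------

def forward_select(
    X_train: np.ndarray,
    labels_train: np.ndarray,
    ranking: FdrRanking,
    clf: ClassifierSpec,
    max_subset: int,
) -> tuple[tuple[int, ...], np.ndarray]:
    """Choose the smallest ranked-feature prefix maximizing inner-LOOCV accuracy.

    Returns the chosen subset as original column indices plus the full
    accuracy trace over subset sizes 1..max_subset.
    """
    if max_subset > X_train.shape[1]:
        raise ValueError(
            f"max_subset={max_subset} exceeds feature count {X_train.shape[1]}"
        )
    Xr = X_train[:, ranking.order[:max_subset]]
    trace = inner_loocv_trace(Xr, np.asarray(labels_train), clf, max_subset)
    m_star = int(np.argmax(trace)) + 1  # argmax returns the first (smallest) max
    chosen = tuple(int(i) for i in ranking.order[:m_star])
    return chosen, trace


def loocv_pipeline(
    X: FeatureMatrix,
    clf: ClassifierSpec,
    max_subset: int | None = None,
    n_repeats: int = 1,
    seed: int = 0,
    literal_selection: bool = False,
    standardize: bool = True,
) -> SelectionOutcome:
    """Leave-one-subject-out evaluation with per-fold feature selection.

    Every fold re-ranks and re-selects features on its training rows only,
    then predicts the held-out subject; accuracy is the percentage of correct
    held-out predictions. With ``standardize`` (the usual practice for
    C-SVC) each fold z-scores the feature columns using its training rows'
    mean and standard deviation, so the cost parameter C operates on a
    common scale; the held-out row is transformed with the training
    statistics, never its own. FDR ranking is scale-invariant, so
    standardization leaves the ranking unchanged. Repeats shuffle the fold
    evaluation order under the seed; with the deterministic default protocol
    the accuracy is identical across repeats (spread 0), and the repeats
    exist to expose any order-dependence.
    """
    values = np.asarray(X.values, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values))[0, 1])
        raise ValueError(
            f"non-finite values in feature column {X.column_descriptors[bad]}"
        )
    y = np.asarray(X.group_labels)
    n, p = values.shape
    m_max = min(50, p) if max_subset is None else min(max_subset, p)
    rng = np.random.default_rng([int(seed), 909])

    all_folds: list[list[FoldRecord]] = []
    accs = []
    for _rep in range(n_repeats):
        fold_order = rng.permutation(n)
        records = []
        correct = 0
        for i in fold_order:
            keep = np.arange(n) != i
            X_tr, y_tr = values[keep], y[keep]
            x_te = values[i]
            if standardize:
                mu = X_tr.mean(axis=0)
                sd = X_tr.std(axis=0)
                sd[sd == 0] = 1.0
                X_tr = (X_tr - mu) / sd
                x_te = (x_te - mu) / sd
            ranking = rank_features(X_tr, y_tr)
            if literal_selection:
                chosen, trace, pred = _literal_fold(
                    X_tr, y_tr, x_te, y[i], ranking, clf, m_max
                )
            else:
                chosen, trace = forward_select(X_tr, y_tr, ranking, clf, m_max)
                model = clf.build().fit(X_tr[:, chosen], y_tr)
                pred = int(model.predict(x_te[list(chosen)][None])[0])
            correct += pred == y[i]
            records.append(
                FoldRecord(
                    subject_id=X.subject_ids[i],
                    true_label=int(y[i]),
                    predicted_label=pred,
                    chosen=chosen,
                    inner_trace=trace,
                    ranking_order=ranking.order.copy(),
                )
            )
        records.sort(key=lambda r: X.subject_ids.index(r.subject_id))
        all_folds.append(records)
        accs.append(100.0 * correct / n)
    return SelectionOutcome(
        classifier=clf, folds=all_folds, accuracies_pct=np.asarray(accs)
    )


def _literal_fold(X_tr, y_tr, x_te, y_te, ranking, clf, m_max):
    """Literal per-test-sample subset choice (leaks the test label; see module doc)."""
    trace = np.empty(m_max)
    chosen_m = None
    for m in range(1, m_max + 1):
        cols = ranking.order[:m]
        model = clf.build().fit(X_tr[:, cols], y_tr)
        pred_m = int(model.predict(x_te[cols][None])[0])
        trace[m - 1] = 100.0 * (pred_m == y_te)
        if chosen_m is None and pred_m == y_te:
            chosen_m = m
    if chosen_m is None:
        chosen_m = 1
    chosen = tuple(int(i) for i in ranking.order[:chosen_m])
    cols = list(chosen)
    model = clf.build().fit(X_tr[:, cols], y_tr)
    pred = int(model.predict(x_te[cols][None])[0])
    return chosen, trace, pred
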