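"""Feature selection strategies over unit feature tensors.

Three filter strategies map per-subject feature tensors plus training labels
to a selected feature set:

- ``svfs_select`` (single-view): choose the one feature *order* whose whole
  matrix performs best under a view-level criterion, then threshold within it.
- ``cfs_select`` (concatenation): pool every (unit, order) feature into one
  long vector and threshold globally; a unit may contribute several picks or
  none.
- ``upffs_select`` (unit-based personalized fingerprint): for every ROI-pair
  unit independently, keep the single best-scoring order — its fingerprint
  feature — then drop units whose winning score misses the threshold.

All strategies operate on training subjects only; ``apply_selection`` reads
the picked entries out of any subject's tensor without re-evaluation, so test
subjects never influence the selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .feature_eval import is_lower_better, passes_threshold, score_matrix
from .moments import FeatureTensor, stack_feature_tensors

__all__ = [
    "Pick",
    "SelectedFeatureSet",
    "FingerprintMatrix",
    "upffs_select",
    "svfs_select",
    "cfs_select",
    "apply_selection",
    "score_all_units",
    "picks_from_scores",
    "unit_index_pairs",
]


class Pick(NamedTuple):
    """One selected feature: ROI pair (0-based, i < j), order d (1-based), score."""

    i: int
    j: int
    d: int
    score: float


@dataclass
class SelectedFeatureSet:
    strategy: str
    method: str
    threshold: float
    picks: list[Pick]
    svfs_chosen_view: int | None = None  # d-hat, only for svfs

    def __len__(self) -> int:
        return len(self.picks)


@dataclass
class FingerprintMatrix:
    """Per-unit winning order (1-based d) and its score; symmetric, diagonal 0."""

    best_order: np.ndarray
    best_score: np.ndarray


def unit_index_pairs(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i < j) index arrays in row-major unit order."""
    return np.triu_indices(m, k=1)


def _stacked(tensors) -> np.ndarray:
    if isinstance(tensors, np.ndarray):
        if tensors.ndim != 4:
            raise ValueError("stacked tensors must have shape (n, D, M, M)")
        return tensors
    return stack_feature_tensors(list(tensors))


def _check_labels(labels: np.ndarray, n: int) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != n:
        raise ValueError("labels length does not match subject count")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need both classes in training labels, got {classes.tolist()}")
    if counts.min() < 2:
        raise ValueError("need at least 2 training subjects per class")
    return labels


def score_all_units(tensors, labels, method: str = "ttest") -> np.ndarray:
    """Evaluate every (order, unit) feature across training subjects.

    Returns a (D, U) array of scores, U = M(M-1)/2, units in row-major
    upper-triangle order.
    """
    x = _stacked(tensors)
    n, n_orders, m, _ = x.shape
    labels = _check_labels(labels, n)
    iu, ju = unit_index_pairs(m)
    feats = x[:, :, iu, ju].reshape(n, n_orders * len(iu))
    return score_matrix(feats, labels, method).reshape(n_orders, len(iu))


def picks_from_scores(
    strategy: str,
    scores: np.ndarray,
    method: str,
    threshold: float,
    m: int,
    svfs_view: int | None = None,
) -> list[Pick]:
    """Turn a precomputed (D, U) score array into a pick list.

    Shared by the public selectors and the cross-validation driver (which
    caches scores across the threshold grid). Ties on the best order go to
    the lowest d.
    """
    iu, ju = unit_index_pairs(m)
    lower = is_lower_better(method)
    if strategy == "upffs":
        best_d = scores.argmin(axis=0) if lower else scores.argmax(axis=0)
        best = scores[best_d, np.arange(scores.shape[1])]
        keep = passes_threshold(best, method, threshold)
        return [
            Pick(int(iu[u]), int(ju[u]), int(best_d[u]) + 1, float(best[u]))
            for u in np.flatnonzero(keep)
        ]
    if strategy == "cfs":
        keep = passes_threshold(scores, method, threshold)  # (D, U)
        return [
            Pick(int(iu[u]), int(ju[u]), int(d) + 1, float(scores[d, u]))
            for d, u in zip(*np.nonzero(keep))
        ]
    if strategy == "svfs":
        if svfs_view is None:
            raise ValueError("svfs picks need the chosen view d-hat")
        row = scores[svfs_view - 1]
        keep = passes_threshold(row, method, threshold)
        return [
            Pick(int(iu[u]), int(ju[u]), svfs_view, float(row[u]))
            for u in np.flatnonzero(keep)
        ]
    raise ValueError(f"unknown strategy {strategy!r}")


def upffs_select(
    tensors, labels, method: str = "ttest", threshold: float = 0.05
) -> tuple[FingerprintMatrix, SelectedFeatureSet]:
    """Unit-based personalized fingerprint selection.

    For each unit the D orders are scored across training subjects and the
    best-oriented one wins (argmin p, or argmax Fisher score); the winners
    form the fingerprint matrix. Units whose winning score fails the
    threshold are dropped from the returned feature set.
    """
    x = _stacked(tensors)
    m = x.shape[2]
    scores = score_all_units(x, labels, method)
    lower = is_lower_better(method)
    best_d = scores.argmin(axis=0) if lower else scores.argmax(axis=0)
    best = scores[best_d, np.arange(scores.shape[1])]

    iu, ju = unit_index_pairs(m)
    order_mat = np.zeros((m, m), dtype=int)
    score_mat = np.zeros((m, m))
    order_mat[iu, ju] = order_mat[ju, iu] = best_d + 1
    score_mat[iu, ju] = score_mat[ju, iu] = best

    picks = picks_from_scores("upffs", scores, method, threshold, m)
    fm = FingerprintMatrix(best_order=order_mat, best_score=score_mat)
    return fm, SelectedFeatureSet("upffs", method, threshold, picks)


def svfs_view_criterion(
    tensors, labels, n_folds: int = 5, c: float = 1.0, seed: int = 0
) -> tuple[int, np.ndarray]:
    """Pick the best feature order by inner-CV accuracy of a linear SVM.

    Each order's full unit-feature matrix is a candidate view; stratified
    k-fold accuracy (standardized features, linear SVM at fixed C) ranks the
    views. Returns (1-based d-hat, per-view accuracies); ties go to lowest d.
    """
    x = _stacked(tensors)
    n, n_orders, m, _ = x.shape
    labels = _check_labels(labels, n)
    iu, ju = unit_index_pairs(m)
    n_folds = min(n_folds, int(np.bincount(labels).min()))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(np.zeros(n), labels))
    accs = np.empty(n_orders)
    for d in range(n_orders):
        feats = x[:, d, iu, ju]
        correct = 0
        for tr, va in splits:
            clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))
            clf.fit(feats[tr], labels[tr])
            correct += int((clf.predict(feats[va]) == labels[va]).sum())
        accs[d] = correct / n
    return int(np.argmax(accs)) + 1, accs


def svfs_select(
    tensors,
    labels,
    method: str = "ttest",
    threshold: float = 0.05,
    view_folds: int = 5,
    view_c: float = 1.0,
    seed: int = 0,
) -> SelectedFeatureSet:
    """Single-view selection: choose one order globally, then threshold in it."""
    x = _stacked(tensors)
    m = x.shape[2]
    d_hat, _ = svfs_view_criterion(x, labels, n_folds=view_folds, c=view_c, seed=seed)
    scores = score_all_units(x, labels, method)
    picks = picks_from_scores("svfs", scores, method, threshold, m, svfs_view=d_hat)
    return SelectedFeatureSet("svfs", method, threshold, picks, svfs_chosen_view=d_hat)


def cfs_select(
    tensors, labels, method: str = "ttest", threshold: float = 0.05
) -> SelectedFeatureSet:
    """Concatenation selection: threshold every (unit, order) feature globally.

    The concatenation order is fixed (order-major, then i, then j) so results
    are reproducible bit-for-bit.
    """
    x = _stacked(tensors)
    m = x.shape[2]
    scores = score_all_units(x, labels, method)
    picks = picks_from_scores("cfs", scores, method, threshold, m)
    return SelectedFeatureSet("cfs", method, threshold, picks)


def apply_selection(sel: SelectedFeatureSet, tensors) -> np.ndarray:
    """Design matrix (subjects x picks) read straight out of the tensors.

    No statistic is recomputed here, so the same picks can be applied to
    held-out subjects without leakage.
    """
    if not sel.picks:
        raise ValueError("no features selected: empty pick list")
    x = _stacked(tensors)
    rows = np.array([p.i for p in sel.picks])
    cols = np.array([p.j for p in sel.picks])
    orders = np.array([p.d for p in sel.picks]) - 1
    return x[:, orders, rows, cols]
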