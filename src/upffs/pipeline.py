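"""Nested cross-validated linear-SVM classification and decision-score fusion.

The evaluation protocol mirrors the filter-selection literature: stratified
outer folds (default 6) repeated with fresh partitions (default 10 repeats);
inside every outer-training set a stratified inner CV (default 5 folds)
grid-searches the evaluation threshold and the SVM regularization parameter
C; selection, standardization and tuning all see training subjects only.
Outer-fold predictions are pooled per repeat, the six binary metrics are
computed once per repeat, and mean +/- SD over repeats is reported.

Lo- and Ho-network classifiers are fused by a weighted average of their SVM
decision scores, alpha * s_lo + (1 - alpha) * s_ho, with alpha tuned on
out-of-fold inner decision scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .feature_eval import THRESHOLD_GRIDS
from .selection import (
    SelectedFeatureSet,
    _stacked,
    picks_from_scores,
    score_all_units,
    svfs_view_criterion,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "FoldRecord",
    "ClassificationReport",
    "train_linear_svm",
    "compute_metrics",
    "fuse_scores",
    "run_fold",
    "nested_cv",
    "nested_cv_fused",
    "feature_frequency",
]

METRIC_NAMES = ("ACC", "TPR", "TNR", "PPV", "NPV", "F1")


@dataclass
class CVConfig:
    """Cross-validation protocol and hyperparameter grids."""

    outer_folds: int = 6
    inner_folds: int = 5
    repeats: int = 10
    seed: int = 0
    thresholds: np.ndarray | None = None  # None -> method's standard grid
    c_grid: np.ndarray = field(default_factory=lambda: 2.0 ** np.arange(-5, 6))
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.1, 0.91, 0.1), 10)
    )
    svfs_view_folds: int = 5
    ho_from_lo: bool = True

    def thresholds_for(self, method: str) -> np.ndarray:
        if self.thresholds is not None:
            return np.asarray(self.thresholds, dtype=float)
        return THRESHOLD_GRIDS[method]

    def repeat_seed(self, repeat: int) -> int:
        return int((self.seed * 1_000_003 + 7_919 * repeat + 1) % (2**31 - 1))


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    threshold: float
    c: float
    selection: SelectedFeatureSet
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    decision_scores: np.ndarray
    y_pred: np.ndarray
    y_true: np.ndarray
    alpha: float | None = None
    selection_ho: SelectedFeatureSet | None = None
    hypers_ho: tuple[float, float] | None = None
    scores_lo: np.ndarray | None = None
    scores_ho: np.ndarray | None = None


@dataclass
class ClassificationReport:
    """Mean +/- SD of the six metrics over repeats, plus per-fold detail."""

    network: str
    strategy: str
    method: str
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    per_repeat: list[dict[str, float]]
    fold_records: list[FoldRecord]
    n_subjects: int

    def summary(self) -> str:
        lines = [
            f"Nested-CV classification report  [network={self.network}, "
            f"strategy={self.strategy}, eval={self.method}, n={self.n_subjects}]",
            f"{'metric':>8}  {'mean':>8}  {'sd':>8}",
        ]
        for name in METRIC_NAMES:
            lines.append(
                f"{name:>8}  {self.metrics_mean[name]:>8.4f}  {self.metrics_sd[name]:>8.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "strategy": self.strategy,
            "method": self.method,
            "n_subjects": self.n_subjects,
            "metrics_mean": self.metrics_mean,
            "metrics_sd": self.metrics_sd,
            "per_repeat": self.per_repeat,
            "fold_hyperparameters": [
                {
                    "repeat": r.repeat,
                    "fold": r.fold,
                    "threshold": r.threshold,
                    "C": r.c,
                    "alpha": r.alpha,
                    "n_picks": len(r.selection.picks),
                }
                for r in self.fold_records
            ],
        }


def train_linear_svm(x: np.ndarray, y: np.ndarray, c: float) -> Pipeline:
    """Standardize (training statistics) and fit a linear SVM.

    Returns a fitted pipeline whose ``decision_function`` gives the signed
    score per subject; the sign carries the predicted class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("design matrix must be 2-D with at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))
    clf.fit(x, y)
    return clf


def compute_metrics(y_true, y_pred) -> dict[str, float]:
    """ACC, TPR, TNR, PPV, NPV, F1 with patients (label 1) as positives.

    Ratios with a zero denominator are reported as 0.0 and listed in the
    ``undefined`` entry.
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("need non-empty, equal-length label vectors")
    for arr in (y_true, y_pred):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    out = {
        "ACC": (tp + tn) / len(y_true),
        "TPR": ratio(tp, tp + fn, "TPR"),
        "TNR": ratio(tn, tn + fp, "TNR"),
        "PPV": ratio(tp, tp + fp, "PPV"),
        "NPV": ratio(tn, tn + fn, "NPV"),
    }
    f1_den = out["PPV"] + out["TPR"]
    out["F1"] = 0.0 if f1_den == 0 else 2 * out["PPV"] * out["TPR"] / f1_den
    if f1_den == 0:
        undefined.append("F1")
    out["undefined"] = undefined
    return out


def fuse_scores(score_lo, score_ho, alpha: float) -> np.ndarray:
    """Weighted average alpha * lo + (1 - alpha) * ho of decision scores."""
    score_lo = np.asarray(score_lo, dtype=float)
    score_ho = np.asarray(score_ho, dtype=float)
    if score_lo.shape != score_ho.shape:
        raise ValueError("decision score vectors must be aligned (equal length)")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("fusion weight must lie in [0, 1]")
    return alpha * score_lo + (1.0 - alpha) * score_ho


# ---------------------------------------------------------------------------
# inner-CV grid search machinery
# ---------------------------------------------------------------------------

def _inner_grid_search(
    x: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    strategy: str,
    method: str,
    config: CVConfig,
    fold_seed: int,
):
    """Grid-search (threshold, C) by inner-CV accuracy on the training subset.

    Evaluation scores are computed once per inner split and reused across the
    threshold grid. Grid points whose selection is empty in any inner split —
    or on the full training subset, where the winner must be refit — are
    skipped; if every point is empty the fold fails loudly.

    Returns (best_threshold, best_C, oof_scores, refit_scores, refit_d_hat)
    where ``oof_scores`` are out-of-fold decision scores of the winning
    configuration aligned with ``train_idx`` (used for fusion tuning), and
    the refit entries are the training-subset evaluation scores and chosen
    view, reused by the caller to build the final selection.
    """
    y_tr = labels[train_idx]
    m = x.shape[2]
    thresholds = config.thresholds_for(method)
    c_grid = np.asarray(config.c_grid, dtype=float)

    refit_scores = score_all_units(x[train_idx], labels[train_idx], method)
    refit_d_hat = None
    if strategy == "svfs":
        refit_d_hat, _ = svfs_view_criterion(
            x[train_idx], labels[train_idx],
            n_folds=config.svfs_view_folds, seed=fold_seed,
        )

    n_inner = min(config.inner_folds, int(np.bincount(y_tr).min()))
    if n_inner < 2:
        raise ValueError("not enough training subjects per class for inner CV")
    inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=fold_seed % (2**31 - 1))
    splits = list(inner.split(np.zeros(len(train_idx)), y_tr))

    correct = np.zeros((len(thresholds), len(c_grid)))
    valid = np.ones((len(thresholds), len(c_grid)), dtype=bool)
    for ti, thr in enumerate(thresholds):
        if not picks_from_scores(strategy, refit_scores, method, thr, m, svfs_view=refit_d_hat):
            valid[ti, :] = False  # winner could not be refit on this training set
    # per (threshold, C): out-of-fold decision scores on the training subset
    oof = np.zeros((len(thresholds), len(c_grid), len(train_idx)))

    for tr_in, va_in in splits:
        tr_abs = train_idx[tr_in]
        va_abs = train_idx[va_in]
        scores = score_all_units(x[tr_abs], labels[tr_abs], method)
        d_hat = None
        if strategy == "svfs":
            d_hat, _ = svfs_view_criterion(
                x[tr_abs], labels[tr_abs],
                n_folds=config.svfs_view_folds, seed=fold_seed,
            )
        for ti, thr in enumerate(thresholds):
            picks = picks_from_scores(strategy, scores, method, thr, m, svfs_view=d_hat)
            if not picks:
                valid[ti, :] = False
                continue
            sel = SelectedFeatureSet(strategy, method, float(thr), picks, d_hat)
            feats_tr = _design(sel, x, tr_abs)
            feats_va = _design(sel, x, va_abs)
            for ci, c in enumerate(c_grid):
                clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))
                clf.fit(feats_tr, labels[tr_abs])
                pred = clf.predict(feats_va)
                correct[ti, ci] += int((pred == labels[va_abs]).sum())
                oof[ti, ci, va_in] = clf.decision_function(feats_va)

    if not valid.any():
        raise RuntimeError(
            "all (threshold, C) grid points produced empty selections; "
            "cannot train this fold"
        )
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("inner grid: skipped %d grid point(s) with empty selections", n_skipped)
    acc = np.where(valid, correct, -1.0)
    best_flat = int(np.argmax(acc))  # ties -> first in grid order
    ti, ci = np.unravel_index(best_flat, acc.shape)
    return float(thresholds[ti]), float(c_grid[ci]), oof[ti, ci], refit_scores, refit_d_hat


def _design(sel: SelectedFeatureSet, x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    rows = np.array([p.i for p in sel.picks])
    cols = np.array([p.j for p in sel.picks])
    orders = np.array([p.d for p in sel.picks]) - 1
    return x[np.ix_(idx)][:, orders, rows, cols]


def _refit_selection(
    m: int,
    strategy: str,
    method: str,
    threshold: float,
    scores: np.ndarray,
    d_hat: int | None,
) -> SelectedFeatureSet:
    picks = picks_from_scores(strategy, scores, method, threshold, m, svfs_view=d_hat)
    if not picks:
        raise RuntimeError("refit selection is empty at the tuned threshold")
    return SelectedFeatureSet(strategy, method, threshold, picks, d_hat)


def run_fold(
    tensors,
    labels,
    train_idx,
    test_idx,
    strategy: str = "upffs",
    method: str = "ttest",
    config: CVConfig | None = None,
    fold_seed: int = 0,
    repeat: int = 0,
    fold: int = 0,
) -> FoldRecord:
    """One outer fold: tune on the training subset, refit, score the test set.

    Everything derived from data — evaluation scores, the chosen view,
    standardization statistics, hyperparameters — is computed on
    ``train_idx`` subjects only.
    """
    config = config or CVConfig()
    x = _stacked(tensors)
    labels = np.asarray(labels).ravel()
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)

    thr, c, _, rscores, d_hat = _inner_grid_search(
        x, labels, train_idx, strategy, method, config, fold_seed
    )
    sel = _refit_selection(x.shape[2], strategy, method, thr, rscores, d_hat)
    feats_tr = _design(sel, x, train_idx)
    clf = train_linear_svm(feats_tr, labels[train_idx], c)
    feats_te = _design(sel, x, test_idx)
    scores = clf.decision_function(feats_te)
    pred = clf.predict(feats_te)
    scaler: StandardScaler = clf.named_steps["standardscaler"]
    return FoldRecord(
        repeat=repeat,
        fold=fold,
        train_idx=train_idx,
        test_idx=test_idx,
        threshold=thr,
        c=c,
        selection=sel,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        decision_scores=scores,
        y_pred=pred,
        y_true=labels[test_idx],
    )


def _aggregate(records_by_repeat, network, strategy, method, n_subjects) -> ClassificationReport:
    per_repeat = []
    all_records = []
    for records in records_by_repeat:
        y_true = np.concatenate([r.y_true for r in records])
        y_pred = np.concatenate([r.y_pred for r in records])
        mets = compute_metrics(y_true, y_pred)
        per_repeat.append({k: mets[k] for k in METRIC_NAMES})
        all_records.extend(records)
    mean = {k: float(np.mean([m[k] for m in per_repeat])) for k in METRIC_NAMES}
    sd = {
        k: float(np.std([m[k] for m in per_repeat], ddof=1)) if len(per_repeat) > 1 else 0.0
        for k in METRIC_NAMES
    }
    return ClassificationReport(
        network=network,
        strategy=strategy,
        method=method,
        metrics_mean=mean,
        metrics_sd=sd,
        per_repeat=per_repeat,
        fold_records=all_records,
        n_subjects=n_subjects,
    )


def _outer_splits(labels: np.ndarray, config: CVConfig, repeat: int):
    n_outer = min(config.outer_folds, int(np.bincount(labels).min()))
    if n_outer < 2:
        raise ValueError("not enough subjects per class for outer CV")
    cv = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=config.repeat_seed(repeat))
    return list(cv.split(np.zeros(len(labels)), labels))


def nested_cv(
    tensors,
    labels,
    strategy: str = "upffs",
    method: str = "ttest",
    config: CVConfig | None = None,
    network: str = "lo",
) -> ClassificationReport:
    """Repeated stratified nested cross-validation for one network."""
    config = config or CVConfig()
    x = _stacked(tensors)
    labels = np.asarray(labels).ravel()
    records_by_repeat = []
    for rep in range(config.repeats):
        records = []
        for fold, (tr, te) in enumerate(_outer_splits(labels, config, rep)):
            fold_seed = config.repeat_seed(rep) + 131 * fold
            records.append(
                run_fold(
                    x, labels, tr, te, strategy, method, config,
                    fold_seed=fold_seed, repeat=rep, fold=fold,
                )
            )
        records_by_repeat.append(records)
        logger.info(
            "repeat %d/%d done (%s/%s/%s)", rep + 1, config.repeats, network, strategy, method
        )
    return _aggregate(records_by_repeat, network, strategy, method, len(labels))


def nested_cv_fused(
    tensors_lo,
    tensors_ho,
    labels,
    strategy: str = "upffs",
    method: str = "ttest",
    config: CVConfig | None = None,
) -> ClassificationReport:
    """Repeated nested CV with Lo + Ho decision-score fusion.

    The two networks share the outer and inner fold partitions so their
    decision scores align subject-by-subject. Per network, (threshold, C) is
    tuned by inner accuracy; the fusion weight alpha is then tuned on the
    winners' out-of-fold inner decision scores.
    """
    config = config or CVConfig()
    x_lo = _stacked(tensors_lo)
    x_ho = _stacked(tensors_ho)
    labels = np.asarray(labels).ravel()
    if x_lo.shape[0] != x_ho.shape[0] or x_lo.shape[0] != len(labels):
        raise ValueError("Lo and Ho tensors and labels disagree on subject count")
    alpha_grid = np.asarray(config.alpha_grid, dtype=float)

    records_by_repeat = []
    for rep in range(config.repeats):
        records = []
        for fold, (tr, te) in enumerate(_outer_splits(labels, config, rep)):
            fold_seed = config.repeat_seed(rep) + 131 * fold
            thr_lo, c_lo, oof_lo, rs_lo, dh_lo = _inner_grid_search(
                x_lo, labels, tr, strategy, method, config, fold_seed
            )
            thr_ho, c_ho, oof_ho, rs_ho, dh_ho = _inner_grid_search(
                x_ho, labels, tr, strategy, method, config, fold_seed
            )
            y_tr = labels[tr]
            accs = [
                (fuse_scores(oof_lo, oof_ho, a) > 0).astype(int) == y_tr
                for a in alpha_grid
            ]
            alpha = float(alpha_grid[int(np.argmax([a.mean() for a in accs]))])

            m_lo, m_ho = x_lo.shape[2], x_ho.shape[2]
            sel_lo = _refit_selection(m_lo, strategy, method, thr_lo, rs_lo, dh_lo)
            sel_ho = _refit_selection(m_ho, strategy, method, thr_ho, rs_ho, dh_ho)
            clf_lo = train_linear_svm(_design(sel_lo, x_lo, tr), y_tr, c_lo)
            clf_ho = train_linear_svm(_design(sel_ho, x_ho, tr), y_tr, c_ho)
            s_lo = clf_lo.decision_function(_design(sel_lo, x_lo, te))
            s_ho = clf_ho.decision_function(_design(sel_ho, x_ho, te))
            fused = fuse_scores(s_lo, s_ho, alpha)
            pred = (fused > 0).astype(int)
            scaler = clf_lo.named_steps["standardscaler"]
            records.append(
                FoldRecord(
                    repeat=rep,
                    fold=fold,
                    train_idx=np.asarray(tr),
                    test_idx=np.asarray(te),
                    threshold=thr_lo,
                    c=c_lo,
                    selection=sel_lo,
                    scaler_mean=scaler.mean_.copy(),
                    scaler_scale=scaler.scale_.copy(),
                    decision_scores=fused,
                    y_pred=pred,
                    y_true=labels[te],
                    alpha=alpha,
                    selection_ho=sel_ho,
                    hypers_ho=(thr_ho, c_ho),
                    scores_lo=s_lo,
                    scores_ho=s_ho,
                )
            )
        records_by_repeat.append(records)
        logger.info("repeat %d/%d done (fused/%s/%s)", rep + 1, config.repeats, strategy, method)
    return _aggregate(records_by_repeat, "fused", strategy, method, len(labels))


def feature_frequency(
    reports: Iterable[ClassificationReport] | ClassificationReport,
    top_n: int | None = None,
    which: str = "lo",
) -> list[tuple[tuple[int, int], int, int]]:
    """Selection-frequency ranking of (unit, order) features over all folds.

    Counts how often each (unit, d) appears in the per-fold selections across
    every outer fold and repeat; returns [((i, j), d, count), ...] sorted by
    descending count, ties broken by (i, j, d). Never-selected features are
    absent.
    """
    if isinstance(reports, ClassificationReport):
        reports = [reports]
    counts: dict[tuple[int, int, int], int] = {}
    for report in reports:
        for record in report.fold_records:
            sel = record.selection_ho if which == "ho" and record.selection_ho else record.selection
            for p in sel.picks:
                key = (p.i, p.j, p.d)
                counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        ranked = ranked[:top_n]
    return [((i, j), d, c) for (i, j, d), c in ranked]
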