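"""Two-sample feature evaluation: t-test, chi-square, Fisher score.

Every method returns an :class:`EvalScore` with an explicit orientation so
the selection strategies can compare "better" uniformly: p-value methods
(t-test, chi-square) are lower-is-better; the Fisher score is
higher-is-better. Vectorized variants score whole feature matrices at once
and are the workhorses of the selection module; the scalar functions are the
reference API.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EvalScore",
    "THRESHOLD_GRIDS",
    "ttest_score",
    "chi2_score",
    "fisher_score",
    "evaluate_feature",
    "score_matrix",
    "passes_threshold",
    "is_lower_better",
]

FISHER_CAP = 1e12

#: Threshold grids searched by the nested cross-validation, per method.
THRESHOLD_GRIDS: dict[str, np.ndarray] = {
    "ttest": np.round(np.arange(0.01, 0.101, 0.01), 10),
    "chi2": np.round(np.arange(0.1, 1.01, 0.1), 10),
    "fisher": np.round(np.arange(0.01, 0.0501, 0.005), 10),
}

_ORIENTATION = {"ttest": "lower_better", "chi2": "lower_better", "fisher": "higher_better"}


@dataclass(frozen=True)
class EvalScore:
    method: str
    score: float
    orientation: str

    def better_than(self, other: "EvalScore") -> bool:
        if self.orientation != other.orientation:
            raise ValueError("cannot compare scores with different orientations")
        if self.orientation == "lower_better":
            return self.score < other.score
        return self.score > other.score


def is_lower_better(method: str) -> bool:
    try:
        return _ORIENTATION[method] == "lower_better"
    except KeyError:
        raise ValueError(f"unknown evaluation method {method!r}") from None


def _as_groups(g1, g2) -> tuple[np.ndarray, np.ndarray]:
    g1 = np.asarray(g1, dtype=float).ravel()
    g2 = np.asarray(g2, dtype=float).ravel()
    return g1, g2


# ---------------------------------------------------------------------------
# vectorized cores: X has shape (n_subjects, P); returns length-P score vector
# ---------------------------------------------------------------------------

def _ttest_p(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled-variance (Student) two-sample two-sided p-values per column."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate convention: both groups constant -> p=1 if equal, p=0 if not
    degenerate = se == 0.0
    if np.any(degenerate):
        p = np.where(degenerate & (diff == 0.0), 1.0, np.where(degenerate, 0.0, p))
    return p


def _chi2_p(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Chi-square p-values after pooled-median binarization, per column.

    Each continuous feature is split at its pooled median (> median vs <=),
    and a 2x2 group-by-bin contingency chi-square statistic (no continuity
    correction) is evaluated. Constant features (no split) give p = 1.
    """
    n1, n2 = x1.shape[0], x2.shape[0]
    n = n1 + n2
    pooled = np.concatenate([x1, x2], axis=0)
    med = np.median(pooled, axis=0)
    a1 = (x1 > med).sum(axis=0).astype(float)  # group 1, high bin
    a2 = (x2 > med).sum(axis=0).astype(float)
    c_hi = a1 + a2
    c_lo = n - c_hi
    r1, r2 = float(n1), float(n2)
    # chi2 for a 2x2 table via the cross-product form
    num = n * (a1 * (r2 - a2) - a2 * (r1 - a1)) ** 2
    den = r1 * r2 * c_hi * c_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = num / den
    p = stats.chi2.sf(chi2, df=1)
    return np.where((c_hi == 0) | (c_lo == 0), 1.0, p)


def _fisher(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Two-class Fisher scores (population variances), per column."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    mu = (n1 * m1 + n2 * m2) / (n1 + n2)
    num = n1 * (m1 - mu) ** 2 + n2 * (m2 - mu) ** 2
    den = n1 * x1.var(axis=0, ddof=0) + n2 * x2.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / den
    score = np.where(den == 0.0, np.where(num == 0.0, 0.0, FISHER_CAP), score)
    return np.minimum(score, FISHER_CAP)


_VECTOR_CORES = {"ttest": _ttest_p, "chi2": _chi2_p, "fisher": _fisher}


def score_matrix(features: np.ndarray, labels: np.ndarray, method: str) -> np.ndarray:
    """Score every column of an (n_subjects, P) feature matrix.

    Returns a length-P vector of p-values (ttest/chi2) or Fisher scores.
    """
    if method not in _VECTOR_CORES:
        raise ValueError(f"unknown evaluation method {method!r}")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree on subject count")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    x1 = features[labels == classes[1]]  # positives first (patients)
    x2 = features[labels == classes[0]]
    return _VECTOR_CORES[method](x1, x2)


def passes_threshold(scores: np.ndarray, method: str, cutoff: float) -> np.ndarray:
    """Boolean mask of features kept at a cutoff (p < cutoff, fisher >= cutoff)."""
    scores = np.asarray(scores)
    if is_lower_better(method):
        return scores < cutoff
    return scores >= cutoff


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def ttest_score(g1, g2) -> EvalScore:
    """Two-sided pooled-variance two-sample t-test p-value (lower is better)."""
    g1, g2 = _as_groups(g1, g2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    p = float(_ttest_p(g1[:, None], g2[:, None])[0])
    if p in (0.0,) and g1.var() == 0 and g2.var() == 0:
        logger.info("degenerate t-test: both groups constant and different; p=0")
    return EvalScore("ttest", p, "lower_better")


def chi2_score(g1, g2) -> EvalScore:
    """Median-split 2x2 chi-square p-value (lower is better)."""
    g1, g2 = _as_groups(g1, g2)
    if len(g1) + len(g2) < 4:
        raise ValueError("need at least 4 observations in total")
    p = float(_chi2_p(g1[:, None], g2[:, None])[0])
    return EvalScore("chi2", p, "lower_better")


def fisher_score(g1, g2) -> EvalScore:
    """Two-class Fisher discriminability score (higher is better)."""
    g1, g2 = _as_groups(g1, g2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    s = float(_fisher(g1[:, None], g2[:, None])[0])
    if s >= FISHER_CAP:
        logger.warning("Fisher score capped at %g (zero within-class variance)", FISHER_CAP)
    return EvalScore("fisher", s, "higher_better")


def evaluate_feature(values, labels, method: str) -> EvalScore:
    """Split one feature's values by binary label and score it."""
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need both classes present, got {classes.tolist()}")
    dispatch = {"ttest": ttest_score, "chi2": chi2_score, "fisher": fisher_score}
    if method not in dispatch:
        raise ValueError(f"unknown evaluation method {method!r}")
    g_pos = values[labels == classes[1]]
    g_neg = values[labels == classes[0]]
    return dispatch[method](g_pos, g_neg)
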