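"""Central-moment features of FC sequences.

Each ROI-pair unit yields D scalar features per subject: order 1 is the
sequence mean, order d >= 2 the d-th central moment with population
normalization (divide by K). These quantify where an FC sequence sits
(mean) and how it fluctuates (variance, skew-type and tail-type moments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dfcn import DFCN, FCSequence

__all__ = [
    "FeatureTensor",
    "UnitFeatureVector",
    "central_moment_feature",
    "extract_feature_tensor",
    "unit_feature_vector",
    "stack_feature_tensors",
]

DEFAULT_N_ORDERS = 7


@dataclass
class FeatureTensor:
    """D symmetric M x M feature matrices; diagonal stored as 0 and ignored."""

    values: np.ndarray  # (D, M, M)
    kind: str = "lo"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("feature tensor must have shape (D, M, M)")

    @property
    def n_orders(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class UnitFeatureVector:
    unit: tuple[int, int]
    values: np.ndarray


def central_moment_feature(
    seq: FCSequence | np.ndarray, d: int, root_scale: bool = False
) -> float:
    """Order-d feature of one FC sequence.

    d = 1 is the arithmetic mean; d >= 2 is the d-th central moment
    (1/K) * sum((x - mean)^d). With ``root_scale``, orders >= 2 are mapped
    through the sign-preserving d-th root sgn(m) * |m|^(1/d), which puts all
    orders on the scale of the data.
    """
    values = seq.values if isinstance(seq, FCSequence) else np.asarray(seq, dtype=float)
    if values.ndim != 1:
        raise ValueError("FC sequence must be 1-D")
    if len(values) < 2:
        raise ValueError(f"need at least 2 windows, got {len(values)}")
    if d < 1:
        raise ValueError(f"feature order must be >= 1, got {d}")
    if d == 1:
        return float(values.mean())
    m = float(np.mean((values - values.mean()) ** d))
    if root_scale:
        m = float(np.sign(m) * np.abs(m) ** (1.0 / d))
    return m


def extract_feature_tensor(
    dfcn: DFCN, n_orders: int = DEFAULT_N_ORDERS, root_scale: bool = False
) -> FeatureTensor:
    """All per-unit moment features of a D-FCN, as D stacked M x M matrices."""
    if dfcn.n_windows < 2:
        raise ValueError("need at least 2 windows to extract moment features")
    x = dfcn.tensor  # (K, M, M)
    mean = x.mean(axis=0)
    dev = x - mean
    out = np.empty((n_orders, dfcn.n_rois, dfcn.n_rois))
    out[0] = mean
    for d in range(2, n_orders + 1):
        md = np.mean(dev**d, axis=0)
        if root_scale:
            md = np.sign(md) * np.abs(md) ** (1.0 / d)
        out[d - 1] = md
    # symmetrize exactly and blank the diagonal
    out = 0.5 * (out + out.transpose(0, 2, 1))
    for d in range(n_orders):
        np.fill_diagonal(out[d], 0.0)
    return FeatureTensor(values=out, kind=dfcn.kind)


def unit_feature_vector(tensor: FeatureTensor, i: int, j: int) -> UnitFeatureVector:
    """The D features of one unit, read across orders at entry (i, j)."""
    if i == j:
        raise ValueError("diagonal entries are not units; need i != j")
    if i > j:
        i, j = j, i
    return UnitFeatureVector(unit=(i, j), values=tensor.values[:, i, j].copy())


def stack_feature_tensors(tensors: list[FeatureTensor]) -> np.ndarray:
    """Stack per-subject tensors into one (n_subjects, D, M, M) array."""
    if not tensors:
        raise ValueError("no feature tensors given")
    shapes = {t.values.shape for t in tensors}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent feature tensor shapes: {sorted(shapes)}")
    return np.stack([t.values for t in tensors])
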