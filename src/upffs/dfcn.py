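"""Dynamic functional connectivity network (D-FCN) construction.

Low-order networks (Lo-D-FCN) stack per-window Pearson correlation matrices
of ROI time series; high-order networks (Ho-D-FCN) correlate, within each
window, the connectivity *profiles* of two ROIs ("correlation's correlation").
The time series of one edge's weight across windows is the FC sequence — the
unit on which all downstream feature extraction operates.

Conventions: windows are 0-based half-open index intervals; ROI indices are
0-based throughout the Python API and converted to 1-based only in file
output and reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RoiTimeSeries",
    "SlidingWindowSpec",
    "DFCN",
    "FCSequence",
    "sliding_windows",
    "build_lo_dfcn",
    "build_ho_dfcn",
    "fc_sequence",
]


@dataclass
class RoiTimeSeries:
    """A subject's ROI signal matrix: T time points by M regions."""

    subject_id: str
    data: np.ndarray
    label: int | None = None
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D (T x M) array")
        t, m = self.data.shape
        if t < 2 or m < 2:
            raise ValueError(f"need T >= 2 and M >= 2, got T={t}, M={m}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in time series")
        if self.roi_names is not None and len(self.roi_names) != m:
            raise ValueError("roi_names length does not match number of columns")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 (control) or 1 (patient)")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Rectangular sliding window: length ``width`` points, advanced by ``step``."""

    width: int = 60
    step: int = 2

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError(f"window width must be >= 2, got {self.width}")
        if self.step < 1:
            raise ValueError(f"window step must be >= 1, got {self.step}")

    def n_windows(self, n_timepoints: int) -> int:
        if n_timepoints < self.width:
            raise ValueError(
                f"series shorter than window: T={n_timepoints} < W={self.width}"
            )
        return (n_timepoints - self.width) // self.step + 1


#: Default windowing used for low-order networks.
LO_WINDOW = SlidingWindowSpec(width=60, step=2)
#: Default windowing used for high-order networks.
HO_WINDOW = SlidingWindowSpec(width=60, step=10)


@dataclass
class DFCN:
    """A stack of K symmetric M x M per-window connectivity matrices."""

    kind: str
    tensor: np.ndarray
    window_spec: SlidingWindowSpec

    def __post_init__(self) -> None:
        if self.kind not in ("lo", "ho"):
            raise ValueError(f"kind must be 'lo' or 'ho', got {self.kind!r}")
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3 or self.tensor.shape[1] != self.tensor.shape[2]:
            raise ValueError("tensor must have shape (K, M, M)")

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_rois(self) -> int:
        return self.tensor.shape[1]


@dataclass(frozen=True)
class FCSequence:
    """One ROI pair's connectivity across all windows (the selection unit)."""

    unit: tuple[int, int]
    values: np.ndarray = field(compare=False)

    def __len__(self) -> int:
        return len(self.values)


def sliding_windows(n_timepoints: int, spec: SlidingWindowSpec) -> list[tuple[int, int]]:
    """Half-open index intervals [m*S, m*S + W) covering the series.

    Trailing points that do not fill a whole window are dropped, so the
    number of windows is K = floor((T - W) / S) + 1.
    """
    k = spec.n_windows(n_timepoints)
    return [(m * spec.step, m * spec.step + spec.width) for m in range(k)]


def _window_corr(segment: np.ndarray, window_index: int) -> np.ndarray:
    """Pearson correlation matrix of one window, with strict variance checks."""
    sd = segment.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ValueError(
            f"zero-variance ROI column(s) {bad.tolist()} in window {window_index}; "
            "Pearson correlation undefined"
        )
    r = np.corrcoef(segment, rowvar=False)
    r = 0.5 * (r + r.T)  # corrcoef is symmetric only to rounding
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def build_lo_dfcn(
    ts: RoiTimeSeries,
    spec: SlidingWindowSpec = LO_WINDOW,
    fisher_z: bool = False,
) -> DFCN:
    """Low-order D-FCN: per-window Pearson correlation of ROI signals.

    Parameters
    ----------
    ts : RoiTimeSeries
    spec : SlidingWindowSpec
        Window length and step, in time points.
    fisher_z : bool
        Apply the Fisher z-transform (arctanh) to off-diagonal entries.
        Off by default; raw correlations are the standard representation here.
    """
    windows = sliding_windows(ts.n_timepoints, spec)
    slices = np.empty((len(windows), ts.n_rois, ts.n_rois))
    for k, (a, b) in enumerate(windows):
        slices[k] = _window_corr(ts.data[a:b], k)
    if fisher_z:
        off = ~np.eye(ts.n_rois, dtype=bool)
        # clip to avoid +/-inf at |r| = 1
        slices[:, off] = np.arctanh(np.clip(slices[:, off], -1 + 1e-12, 1 - 1e-12))
    return DFCN(kind="lo", tensor=slices, window_spec=spec)


def build_ho_dfcn(lo: DFCN, profile: str = "exclude_both") -> DFCN:
    """High-order D-FCN from a low-order one ("correlation's correlation").

    Within each window k, ROI i's connectivity profile is its vector of
    correlations with the other ROIs; entry (i, j) of the high-order slice is
    the Pearson correlation of i's and j's profiles.

    ``profile`` controls which entries form the profile vectors:

    - ``"exclude_both"`` (default): both indices i and j are dropped from both
      profiles, so the two vectors are index-aligned over the remaining M - 2
      ROIs.
    - ``"off_diagonal"``: only each ROI's own diagonal entry is dropped
      (vectors of length M - 1, aligned over all ROIs but each contains one
      correlation with the other member of the pair).

    Zero-variance profiles (e.g. constant profiles) yield an entry of 0 with
    a logged warning rather than an error.
    """
    if lo.kind != "lo":
        raise ValueError("high-order construction requires a low-order D-FCN")
    m = lo.n_rois
    if m < 5:
        raise ValueError(f"high-order construction needs M >= 5 ROIs, got {m}")
    if profile not in ("exclude_both", "off_diagonal"):
        raise ValueError(f"unknown profile mode {profile!r}")

    out = np.ones((lo.n_windows, m, m))
    n_degenerate = 0
    idx = np.arange(m)
    for k in range(lo.n_windows):
        r = lo.tensor[k]
        for i in range(m):
            for j in range(i + 1, m):
                if profile == "exclude_both":
                    mask = (idx != i) & (idx != j)
                    a, b = r[i, mask], r[j, mask]
                else:
                    a = r[i, idx != i]
                    b = r[j, idx != j]
                ac = a - a.mean()
                bc = b - b.mean()
                na, nb = np.sqrt(ac @ ac), np.sqrt(bc @ bc)
                if na == 0.0 or nb == 0.0:
                    n_degenerate += 1
                    val = 0.0
                else:
                    val = float(np.clip((ac @ bc) / (na * nb), -1.0, 1.0))
                out[k, i, j] = out[k, j, i] = val
    if n_degenerate:
        logger.warning(
            "high-order construction: %d zero-variance profile pair(s) set to 0",
            n_degenerate,
        )
    return DFCN(kind="ho", tensor=out, window_spec=lo.window_spec)


def fc_sequence(dfcn: DFCN, i: int, j: int) -> FCSequence:
    """The FC sequence of pair (i, j): tensor[:, i, j], stored with i < j."""
    m = dfcn.n_rois
    if i == j:
        raise ValueError("diagonal entries are not units; need i != j")
    if not (0 <= i < m and 0 <= j < m):
        raise ValueError(f"ROI index out of range for M={m}: ({i}, {j})")
    if i > j:
        i, j = j, i
    return FCSequence(unit=(i, j), values=dfcn.tensor[:, i, j].copy())
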