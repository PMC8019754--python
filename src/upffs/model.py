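"""Model/Results facade over the full pipeline.

``FCClassificationModel`` holds the data (per-subject feature tensors for
one or both networks plus labels) and the modelling choices (strategy,
evaluation method, network); ``fit`` runs the repeated nested CV and returns
an ``FCClassificationResults`` carrying the metric estimates with their
spread, per-fold diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dfcn import (
    HO_WINDOW,
    LO_WINDOW,
    RoiTimeSeries,
    SlidingWindowSpec,
    build_ho_dfcn,
    build_lo_dfcn,
)
from .io import Manifest, read_manifest, read_timeseries_csv
from .moments import extract_feature_tensor
from .pipeline import (
    ClassificationReport,
    CVConfig,
    feature_frequency,
    nested_cv,
    nested_cv_fused,
)

__all__ = ["FCClassificationModel", "FCClassificationResults", "tensors_from_timeseries"]


def tensors_from_timeseries(
    subjects: list[RoiTimeSeries],
    network: str = "lo",
    lo_window: SlidingWindowSpec = LO_WINDOW,
    ho_window: SlidingWindowSpec = HO_WINDOW,
    n_orders: int = 7,
) -> np.ndarray:
    """Build per-subject feature tensors for one network from raw time series.

    The high-order network is derived from a low-order network built with its
    own (typically coarser-stepped) window.
    """
    out = []
    for ts in subjects:
        if network == "lo":
            dfcn = build_lo_dfcn(ts, lo_window)
        elif network == "ho":
            dfcn = build_ho_dfcn(build_lo_dfcn(ts, ho_window))
        else:
            raise ValueError(f"network must be 'lo' or 'ho', got {network!r}")
        out.append(extract_feature_tensor(dfcn, n_orders=n_orders).values)
    return np.stack(out)


@dataclass
class FCClassificationModel:
    """Two-group classification model over dynamic-FCN moment features.

    Parameters
    ----------
    tensors_lo, tensors_ho : (n, D, M, M) arrays or None
        Per-subject feature tensors; supply one for a single-network model,
        both for a fused model.
    labels : array of 0/1
        0 = control (negative), 1 = patient (positive).
    network : {"lo", "ho", "fused"}
    strategy : {"upffs", "svfs", "cfs"}
    eval_method : {"ttest", "chi2", "fisher"}
    """

    labels: np.ndarray
    tensors_lo: np.ndarray | None = None
    tensors_ho: np.ndarray | None = None
    network: str = "lo"
    strategy: str = "upffs"
    eval_method: str = "ttest"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).ravel()
        if self.network not in ("lo", "ho", "fused"):
            raise ValueError(f"unknown network {self.network!r}")
        if self.network in ("lo", "fused") and self.tensors_lo is None:
            raise ValueError(f"network {self.network!r} needs tensors_lo")
        if self.network in ("ho", "fused") and self.tensors_ho is None:
            raise ValueError(f"network {self.network!r} needs tensors_ho")

    @classmethod
    def from_timeseries(
        cls,
        subjects: list[RoiTimeSeries],
        labels=None,
        network: str = "lo",
        lo_window: SlidingWindowSpec = LO_WINDOW,
        ho_window: SlidingWindowSpec = HO_WINDOW,
        n_orders: int = 7,
        **kwargs,
    ) -> "FCClassificationModel":
        if labels is None:
            labels = np.array([ts.label for ts in subjects])
            if any(l is None for l in labels):
                raise ValueError("labels missing: supply them or set them on the time series")
        t_lo = (
            tensors_from_timeseries(subjects, "lo", lo_window, ho_window, n_orders)
            if network in ("lo", "fused")
            else None
        )
        t_ho = (
            tensors_from_timeseries(subjects, "ho", lo_window, ho_window, n_orders)
            if network in ("ho", "fused")
            else None
        )
        return cls(
            labels=np.asarray(labels, dtype=int),
            tensors_lo=t_lo,
            tensors_ho=t_ho,
            network=network,
            **kwargs,
        )

    @classmethod
    def from_manifest(cls, manifest: str | Path | Manifest, **kwargs) -> "FCClassificationModel":
        if not isinstance(manifest, Manifest):
            manifest = read_manifest(manifest)
        subjects = [
            read_timeseries_csv(p, subject_id=sid, label=int(lab))
            for sid, p, lab in zip(manifest.subjects, manifest.paths, manifest.labels)
        ]
        return cls.from_timeseries(subjects, labels=manifest.labels, **kwargs)

    def fit(self, config: CVConfig | None = None) -> "FCClassificationResults":
        config = config or CVConfig()
        if self.network == "fused":
            report = nested_cv_fused(
                self.tensors_lo, self.tensors_ho, self.labels,
                strategy=self.strategy, method=self.eval_method, config=config,
            )
        else:
            tensors = self.tensors_lo if self.network == "lo" else self.tensors_ho
            report = nested_cv(
                tensors, self.labels,
                strategy=self.strategy, method=self.eval_method,
                config=config, network=self.network,
            )
        return FCClassificationResults(model=self, config=config, report=report)


@dataclass
class FCClassificationResults:
    """Fitted results: metric estimates, spread, and per-fold diagnostics."""

    model: FCClassificationModel
    config: CVConfig
    report: ClassificationReport

    @property
    def metrics(self) -> dict[str, float]:
        return self.report.metrics_mean

    @property
    def metrics_sd(self) -> dict[str, float]:
        return self.report.metrics_sd

    def top_features(self, n: int = 10):
        return feature_frequency(self.report, top_n=n)

    def summary(self) -> str:
        lines = [self.report.summary(), ""]
        lines.append("Top selected features (roi_i, roi_j, order, count; 1-based ROIs):")
        for (i, j), d, c in self.top_features(10):
            lines.append(f"  ({i + 1:>3}, {j + 1:>3})  d={d}  count={c}")
        return "\n".join(lines)
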