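"""File formats: subject manifests, ROI time-series CSVs, report artifacts.

Time series are plain CSV (rows = time points, columns = ROIs, optional
header of ROI names). The manifest is a TSV with columns ``subject_id``,
``path``, ``label``; relative paths resolve against the manifest's own
directory. Reports are JSON; selections and feature rankings are TSV with
1-based ROI indices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dfcn import RoiTimeSeries
from .pipeline import ClassificationReport, feature_frequency

__all__ = [
    "Manifest",
    "read_manifest",
    "read_timeseries_csv",
    "write_fc_dataset_csvs",
    "write_report_json",
    "write_selections_tsv",
    "write_top_features_tsv",
    "config_hash",
]


@dataclass
class Manifest:
    subjects: list[str]
    paths: list[Path]
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.subjects)


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a subject manifest TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing column(s) {sorted(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"manifest {path}: duplicate subject_id {dup.iloc[0]!r}")
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"manifest {path}: labels must be 0 or 1")
    if len(np.unique(labels)) < 2:
        raise ValueError(f"manifest {path}: single class present; need both labels")
    paths = [(path.parent / p).resolve() if not Path(p).is_absolute() else Path(p)
             for p in df["path"]]
    for sid, p in zip(df["subject_id"], paths):
        if not p.is_file():
            raise FileNotFoundError(f"manifest {path}: file for subject {sid!r} not found: {p}")
    return Manifest(subjects=df["subject_id"].tolist(), paths=paths, labels=labels.astype(int))


def read_timeseries_csv(
    path: str | Path,
    subject_id: str | None = None,
    label: int | None = None,
    expected_m: int | None = None,
) -> RoiTimeSeries:
    """Read one subject's T x M time-series CSV (optional header of ROI names)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    tokens = first.split(",")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens)
    try:
        df = pd.read_csv(path, header=0 if has_header else None)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from None
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing/ragged value around data row {row + 1}")
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    if expected_m is not None and data.shape[1] != expected_m:
        raise ValueError(f"{path}: expected {expected_m} ROI columns, found {data.shape[1]}")
    names = [str(c) for c in df.columns] if has_header else None
    return RoiTimeSeries(
        subject_id=subject_id or path.stem, data=data, label=label, roi_names=names
    )


def write_fc_dataset_csvs(subjects: list[RoiTimeSeries], out_dir: str | Path) -> Path:
    """Write per-subject CSVs plus a manifest TSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in subjects:
        fname = f"{ts.subject_id}.csv"
        np.savetxt(out_dir / fname, ts.data, delimiter=",", fmt="%.10g")
        rows.append({"subject_id": ts.subject_id, "path": fname, "label": ts.label})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report_json(report: ClassificationReport, path: str | Path, config: dict) -> None:
    payload = report.to_dict()
    payload["config"] = config
    payload["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def write_selections_tsv(report: ClassificationReport, path: str | Path, config: dict) -> None:
    """Per-fold selections: strategy, 1-based ROI pair, order, score."""
    rows = []
    for rec in report.fold_records:
        for p in rec.selection.picks:
            rows.append(
                {
                    "repeat": rec.repeat,
                    "fold": rec.fold,
                    "strategy": rec.selection.strategy,
                    "roi_i": p.i + 1,
                    "roi_j": p.j + 1,
                    "order": p.d,
                    "score": p.score,
                    "threshold": rec.threshold,
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_top_features_tsv(
    report: ClassificationReport, path: str | Path, config: dict, top_n: int = 10
) -> None:
    """Ranked (unit, order, count) selection-frequency table (1-based ROIs)."""
    ranked = feature_frequency(report, top_n=top_n)
    rows = [
        {"rank": r + 1, "roi_i": i + 1, "roi_j": j + 1, "order": d, "count": c}
        for r, ((i, j), d, c) in enumerate(ranked)
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)
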