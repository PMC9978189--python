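"""Readers, writers and run configuration.

All artifacts are plain text: ROI time series and networks are TSV with a
header row of ROI names; each network carries a JSON sidecar recording the
estimator, its hyperparameters and the observed module count; cohort
manifests are CSV; run configurations round-trip through YAML.  Matrices
are written with 10 significant digits, below every tolerance used in the
analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .estimators import TimeSeries
from .graph import connected_components, validate_adjacency

__all__ = [
    "DataError",
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "write_network",
    "read_network",
    "read_manifest",
    "parse_grid",
]

_FLOAT_FMT = "%.10g"


class DataError(ValueError):
    """Malformed input data (distinct from usage errors for CLI exit codes)."""


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep=sep, engine="python", header=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise DataError(f"{path}: cannot parse delimited text ({exc})") from exc
    if df.shape[0] == 0:
        raise DataError(f"{path}: no data rows (header only?)")
    return df


def _numeric_body(df: pd.DataFrame, path: Path) -> np.ndarray:
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        rows, cols = np.nonzero(body.isna().to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise DataError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at data row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    return body.to_numpy(dtype=float)


def read_timeseries(
    path: str | Path, *, sep: str | None = None, on_constant: str = "error"
) -> TimeSeries:
    """Read one scan's ROI time series (rows = time points, columns = ROIs).

    The header row names the ROIs; the matrix is column-standardized on
    load (mean-centered, unit Euclidean norm) so downstream estimators see
    correlation-ready data.  The delimiter is sniffed unless given.
    """
    path = Path(path)
    df = _read_table(path, sep)
    raw = _numeric_body(df, path)
    try:
        return TimeSeries.from_raw(raw, list(df.columns.astype(str)), on_constant=on_constant)
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    """Write a (standardized) time-series matrix as TSV with ROI header."""
    path = Path(path)
    header = "\t".join(ts.roi_names)
    np.savetxt(path, ts.data, fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")


def write_network(
    W: np.ndarray,
    roi_names: list[str] | tuple[str, ...],
    path: str | Path,
    meta: dict[str, Any] | None = None,
) -> None:
    """Write a network as TSV (ROI header) plus a JSON metadata sidecar.

    The sidecar (``<path>.json``) records whatever ``meta`` carries —
    estimator name, hyperparameters, convergence diagnostics — plus the
    observed connected-component count of the written matrix.
    """
    W = validate_adjacency(W)
    if len(roi_names) != W.shape[0]:
        raise ValueError(f"{len(roi_names)} ROI names for a {W.shape[0]}-node network")
    path = Path(path)
    header = "\t".join(str(n) for n in roi_names)
    np.savetxt(path, W, fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")
    sidecar = dict(meta or {})
    if W.size and W.min() >= 0:
        sidecar.setdefault("k_observed", connected_components(W).k_observed)
    sidecar.setdefault("n_rois", int(W.shape[0]))
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str) + "\n")


def read_network(path: str | Path) -> tuple[np.ndarray, list[str], dict[str, Any]]:
    """Read a network TSV (+ sidecar if present); returns (W, roi_names, meta)."""
    path = Path(path)
    df = _read_table(path, "\t")
    W = _numeric_body(df, path)
    if W.shape[0] != W.shape[1]:
        raise DataError(f"{path}: network matrix is {W.shape[0]} x {W.shape[1]}, not square")
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return W, list(df.columns.astype(str)), meta


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (scan_id, subject_id, label, path).

    Validates uniqueness of scan ids, binary labels, label consistency
    within subject, and presence of both classes.
    """
    path = Path(path)
    df = _read_table(path, ",")
    required = {"scan_id", "subject_id", "label", "path"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: manifest missing column(s) {sorted(missing)}")
    if df["scan_id"].duplicated().any():
        dupes = df.loc[df["scan_id"].duplicated(), "scan_id"].tolist()
        raise DataError(f"{path}: duplicate scan_id(s) {dupes}")
    labels = set(df["label"].unique().tolist())
    if not labels <= {0, 1}:
        raise DataError(f"{path}: labels must be 0/1, found {sorted(labels)}")
    if labels != {0, 1}:
        raise DataError(f"{path}: both classes must be present, found {sorted(labels)}")
    per = df.groupby("subject_id")["label"].nunique()
    bad = per[per > 1]
    if len(bad):
        raise DataError(f"{path}: subject(s) with inconsistent labels: {list(bad.index)}")
    return df


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run; YAML round-trippable.

    Every run writes its resolved config next to its outputs so results are
    reproducible from (config, seed) alone.
    """

    method: str = "am-pc"
    k: int = 8
    lam: float = 0.0
    lam1: float = 0.0
    lam2: float = 0.0
    alpha0: float = 0.1
    normalized_laplacian: bool = True
    folds: int = 5
    repeats: int = 100
    p_threshold: float = 0.05
    C: float = 1.0
    seed: int = 0
    grid: list[float] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = {k: v for k, v in data.items() if k not in known}
        kwargs = {k: v for k, v in data.items() if k in known}
        cfg = cls(**kwargs)
        cfg.extra.update(unknown)
        return cfg


def parse_grid(spec: str) -> list[float]:
    """Parse a penalty grid.

    Accepts the power-of-two range syntax ``2^a..2^b`` (inclusive integer
    exponents, e.g. ``2^-5..2^5`` for the usual 11-point grid) or a
    comma-separated list of floats.
    """
    spec = spec.strip()
    if ".." in spec:
        lo_s, hi_s = spec.split("..", 1)
        def _exp(s: str) -> int:
            s = s.strip()
            if not s.startswith("2^"):
                raise ValueError(f"range grid must use 2^a..2^b syntax, got {spec!r}")
            return int(s[2:])
        lo, hi = _exp(lo_s), _exp(hi_s)
        if hi < lo:
            raise ValueError(f"empty grid range {spec!r}")
        return [float(2.0**e) for e in range(lo, hi + 1)]
    return [float(x) for x in spec.split(",") if x.strip()]
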