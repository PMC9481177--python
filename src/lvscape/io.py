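"""File formats and run configuration.

Canonical tabular dialect: comma-separated UTF-8 with a header row and '.'
decimals; tab-separated input is accepted on read.  Network order is fixed
by the header labels, not by column position; when a file carries no header
the canonical 7-network order is assumed with a warning.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .transform import (
    AlphaTrajectory,
    G_DEFAULT,
    H_BASE,
    TR_BASE_MS,
    TimeSeries,
    YEO7_LABELS,
)


class DataFormatError(ValueError):
    """Malformed or unparseable input file."""


class LabelMismatchError(ValueError):
    """Network labels disagree between inputs that must share an ordering."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults are the standard operating point."""

    g: float = G_DEFAULT
    h_base: float = H_BASE
    tr_ms: float = TR_BASE_MS
    norm_lo: float = 0.05
    norm_hi: float = 1.0
    learner: str = "rule"
    selector: str = "correlation"
    n_features: int = 5
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - message path
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc


def _first_row_is_numeric(path) -> bool:
    try:
        peek = pd.read_csv(path, sep=None, engine="python", header=None, nrows=1)
    except Exception as exc:
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    return all(_is_number(v) for v in peek.iloc[0])


def read_timeseries(path, tr_ms: float = TR_BASE_MS) -> TimeSeries:
    """Timeseries CSV/TSV: header of network labels, one row per TR."""
    if _first_row_is_numeric(path):
        warnings.warn(
            f"{path}: no header labels found, assuming canonical network order"
        )
        frame = pd.read_csv(path, sep=None, engine="python", header=None)
        labels = YEO7_LABELS[: frame.shape[1]]
    else:
        frame = _read_table(path)
        labels = tuple(frame.columns)
    if frame.shape[0] < 2 or frame.shape[1] < 1:
        raise DataFormatError(f"{path}: need >= 2 rows and >= 1 network column")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{path}: non-numeric entries in timeseries") from exc
    if not np.all(np.isfinite(values)):
        raise DataFormatError(f"{path}: non-finite values in timeseries")
    return TimeSeries(values=values, tr_ms=tr_ms, labels=labels)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_timeseries(ts: TimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.labels)).to_csv(path, index=False)


def read_sc(path, labels=None) -> tuple[np.ndarray, tuple]:
    """Square connectivity CSV, optional header; returns (matrix, labels).

    If both the file and the caller provide labels they must agree as sets;
    rows/columns are reordered to the caller's ordering.
    """
    if _first_row_is_numeric(path):
        frame = pd.read_csv(path, sep=None, engine="python", header=None)
        mat = frame.to_numpy(dtype=float)
        file_labels = None
    else:
        frame = _read_table(path)
        mat = frame.to_numpy(dtype=float)
        file_labels = tuple(frame.columns)
    if mat.shape[0] != mat.shape[1]:
        raise DataFormatError(f"{path}: connectivity matrix must be square, got {mat.shape}")
    if file_labels is None:
        out_labels = tuple(labels) if labels else YEO7_LABELS[: mat.shape[0]]
        return mat, out_labels
    if labels is not None:
        if set(labels) != set(file_labels):
            raise LabelMismatchError(
                f"{path}: connectivity labels {file_labels} do not match {tuple(labels)}"
            )
        order = [file_labels.index(l) for l in labels]
        mat = mat[np.ix_(order, order)]
        return mat, tuple(labels)
    return mat, file_labels


def write_sc(sc: np.ndarray, path, labels=None) -> None:
    labels = list(labels) if labels else list(YEO7_LABELS[: sc.shape[0]])
    pd.DataFrame(sc, columns=labels).to_csv(path, index=False)


def write_alphas(alphas: AlphaTrajectory, path, source: str | None = None) -> None:
    """Alpha CSV plus a JSON sidecar recording h, g and provenance."""
    path = Path(path)
    pd.DataFrame(alphas.alphas, columns=list(alphas.labels)).to_csv(path, index=False)
    sidecar = {
        "h": alphas.h,
        "g": alphas.g,
        "n_transitions": int(alphas.n_transitions),
        "labels": list(alphas.labels),
        "source": source,
    }
    if source and Path(source).exists():
        sidecar["source_sha256"] = hashlib.sha256(
            Path(source).read_bytes()
        ).hexdigest()
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_alphas(path, sc: np.ndarray) -> AlphaTrajectory:
    frame = _read_table(path)
    sidecar_path = Path(str(path) + ".json")
    h, g = H_BASE, G_DEFAULT
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        h, g = float(meta.get("h", h)), float(meta.get("g", g))
    return AlphaTrajectory(
        alphas=frame.to_numpy(dtype=float),
        h=h,
        g=g,
        sc=sc,
        labels=tuple(frame.columns),
    )


def read_labels(path) -> pd.DataFrame:
    """Subject labels CSV with at least (id, label); optional site column."""
    frame = _read_table(path)
    cols = {c.lower(): c for c in frame.columns}
    if "id" not in cols or "label" not in cols:
        raise DataFormatError(f"{path}: labels file needs 'id' and 'label' columns")
    return frame.rename(columns={cols["id"]: "id", cols["label"]: "label"})


def write_measures_jsonl(frame: pd.DataFrame, supports, path) -> None:
    """Per-timepoint measure stream, one JSON object per line."""
    with open(path, "w") as fh:
        for (_, row), support in zip(frame.iterrows(), supports):
            doc = {k: (v if np.isfinite(v) else None) for k, v in row.items()}
            doc["gass_support"] = sorted(support)
            fh.write(json.dumps(doc) + "\n")
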