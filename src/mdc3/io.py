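"""Delimited-text readers/writers for time series and connectivity matrices.

Time-series files are channels x samples, one row per channel, comma- or
tab-separated, with an optional header row and an optional first column of
channel labels. Matrices are written as labeled square CSV. Values are
formatted with 17 significant digits so write -> read round-trips are exact
for double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .network import FCMatrix

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: file is empty")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def read_timeseries(path, delimiter: str | None = None):
    """Read a channels x samples delimited-text file.

    Returns ``(values, labels)`` where ``values`` is a 2-D float array and
    ``labels`` the first-column channel names when present (else generated
    ``ch0, ch1, ...``). Header rows are detected by non-numeric cells in the
    data columns. The delimiter is auto-detected among comma/tab unless given.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    sep = delimiter or _sniff_delimiter(path)
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                          skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from None

    raw = raw.map(lambda v: v.strip() if isinstance(v, str) else v)
    # a fully non-numeric first row is a header; then a non-numeric first
    # column provides channel labels
    if len(raw) > 1 and not raw.iloc[0].map(_is_number).any():
        raw = raw.iloc[1:].reset_index(drop=True)
    has_labels = not raw.iloc[:, 0].map(_is_number).all()
    data_cols = raw.iloc[:, 1:] if has_labels else raw
    if raw.empty or data_cols.shape[1] == 0:
        raise FormatError(f"{path}: no numeric data found")

    labels = (
        tuple(raw.iloc[:, 0].astype(str))
        if has_labels else tuple(f"ch{i}" for i in range(raw.shape[0]))
    )
    values = np.empty(data_cols.shape)
    for i in range(data_cols.shape[0]):
        for j in range(data_cols.shape[1]):
            cell = data_cols.iat[i, j]
            if not _is_number(cell) or not np.isfinite(float(cell)):
                raise FormatError(
                    f"{path}: non-numeric or non-finite value {cell!r} at "
                    f"row {i + 1}, column {j + 1}"
                )
            values[i, j] = float(cell)
    return values, labels


def write_timeseries(values, path, labels=None, delimiter: str = ",") -> None:
    """Write a channels x samples array as delimited text (no header)."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    path = Path(path)
    with open(path, "w") as fh:
        for i, row in enumerate(arr):
            cells = [(_FLOAT_FMT % v) for v in row]
            if labels is not None:
                cells.insert(0, str(labels[i]))
            fh.write(delimiter.join(cells) + "\n")


def write_matrix(fc: FCMatrix, path) -> None:
    """Write a connectivity matrix as labeled square CSV."""
    frame = pd.DataFrame(fc.weights, index=fc.labels, columns=fc.labels)
    frame.to_csv(path, float_format=_FLOAT_FMT)


def read_matrix(path, estimator_name: str = "", directed: bool = False) -> FCMatrix:
    """Read a labeled square CSV written by :func:`write_matrix`."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"{path}: missing or empty file")
    try:
        frame = pd.read_csv(path, index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    if frame.shape[0] != frame.shape[1]:
        raise FormatError(
            f"{path}: matrix must be square, got shape {frame.shape}"
        )
    values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: matrix contains non-finite values")
    return FCMatrix(labels=tuple(str(c) for c in frame.columns), weights=values,
                    estimator_name=estimator_name, directed=directed)


def write_manifest(path, payload: dict) -> None:
    """Write a JSON provenance manifest (configs, seeds, library versions)."""
    import scipy

    meta = {
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump({**payload, **meta}, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
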