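"""Reading and writing delimited-text artifacts.

Residual data files are delimited text with header columns ``time,event``
(event in {0,1}); all curve/table outputs are delimited text with a ``#``
provenance header (seed, config hash, package version) so that every file
can be traced to the exact invocation that produced it.  Numeric columns
are written with 17 significant digits and round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResidualData",
    "read_residual_data",
    "write_curve",
    "read_curve",
    "write_weights",
    "provenance_header",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class ResidualData:
    """Right-censored residual lifetimes: times ``v`` and indicators ``delta``."""

    v: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        delta = np.asarray(self.delta, dtype=int)
        if v.ndim != 1 or v.shape != delta.shape:
            raise ValueError("time and event arrays must be equal-length vectors")
        if v.size == 0:
            raise ValueError("no observations")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "delta", delta)

    @property
    def n(self) -> int:
        return self.v.size

    @property
    def censoring_fraction(self) -> float:
        return float(1.0 - self.delta.mean())


def read_residual_data(path) -> ResidualData:
    """Read and validate a ``time,event`` delimited-text file.

    Errors name the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    if "time" not in cols or "event" not in cols:
        raise ValueError(f"{path}: header must contain 'time' and 'event' columns")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    time = pd.to_numeric(df[cols["time"]], errors="coerce")
    event = pd.to_numeric(df[cols["event"]], errors="coerce")
    for row, (t, e) in enumerate(zip(time, event), start=1):
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"{path}: row {row}: invalid time {df[cols['time']][row-1]!r}")
        if e not in (0, 1):
            raise ValueError(f"{path}: row {row}: event must be 0 or 1, got {df[cols['event']][row-1]!r}")
    return ResidualData(time.to_numpy(dtype=float), event.to_numpy(dtype=int))


def provenance_header(seed, config: dict, version: str) -> list[str]:
    blob = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return [
        f"# reslife {version}",
        f"# seed: {seed}",
        f"# config: {digest}",
    ]


def _write_table(path, columns: dict, header_lines: list[str] | None) -> None:
    path = Path(path)
    names = list(columns)
    arrays = [np.asarray(columns[c], dtype=float) for c in names]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all columns must have equal length")
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line + "\n")
        fh.write(",".join(names) + "\n")
        for i in range(n):
            fh.write(",".join(_FLOAT_FMT % a[i] for a in arrays) + "\n")


def write_curve(path, time_grid, survival, lower=None, upper=None,
                header_lines: list[str] | None = None) -> None:
    """Write a survival curve (optionally with pointwise bands).

    The grid must be increasing; survival values must be a monotone
    non-increasing probability curve — violated contracts fail loudly here
    rather than producing a quietly invalid artifact.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    survival = np.asarray(survival, dtype=float)
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if np.any(survival < -1e-12) or np.any(survival > 1 + 1e-12):
        raise ValueError("survival values must lie in [0,1]")
    if np.any(np.diff(survival) > 1e-9):
        raise ValueError("survival values must be non-increasing")
    columns = {"time": time_grid, "survival": survival}
    if lower is not None or upper is not None:
        if lower is None or upper is None:
            raise ValueError("provide both lower and upper bands or neither")
        columns["lower"] = np.asarray(lower, dtype=float)
        columns["upper"] = np.asarray(upper, dtype=float)
    _write_table(path, columns, header_lines)


def read_curve(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_weights(path, weights: dict, header_lines: list[str] | None = None) -> None:
    """Write a submodel weight table as ``model,weight`` delimited text."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line + "\n")
        fh.write("model,weight\n")
        for name, w in weights.items():
            fh.write(f"{name},{_FLOAT_FMT % w}\n")
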