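"""Readers and writers for every on-disk artifact.

Plain text throughout: traces as 2-column CSV (time_s, conductance_uS),
ratings and features as TSV, layouts / ground truth / statistical results
as JSON.  Readers validate strictly and raise typed errors with row
context instead of coercing; every writer/reader pair round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ParseError, RangeViolationError
from .trace import Interval, RawTrace, SessionLayout

__all__ = [
    "read_trace",
    "write_trace",
    "read_ratings",
    "write_ratings",
    "read_layout",
    "write_layout",
    "write_results",
    "read_results",
]

RATING_BOUNDS = {"pleasure": (-5, 5), "arousal": (0, 10), "familiarity": (0, 10)}
RATINGS_COLUMNS = [
    "subject", "run", "trial", "excerpt", "exposure",
    "pleasure", "arousal", "familiarity",
]

# Relative tolerance on the sample grid: 1 part per million.
_GRID_TOL = 1e-6


def write_trace(trace: RawTrace, path: str | Path) -> None:
    # Fixed-decimal time keeps the uniform grid exact through the text
    # round-trip for any rate whose step has <= 8 decimal places (256 Hz etc).
    t = trace.times()
    np.savetxt(
        path,
        np.column_stack([t, trace.samples]),
        fmt=["%.8f", "%.17g"],  # 17 significant digits: exact float round-trip
        delimiter=",",
        header="time_s,conductance_uS",
        comments="",
    )


def read_trace(path: str | Path) -> RawTrace:
    """Parse a 2-column CSV trace; sampling rate inferred from the grid.

    Rejects empty files, non-numeric rows (naming the line) and sampling
    grids that deviate from uniform by more than 1 ppm.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as typed parse error
        raise ParseError(f"{path}: unreadable CSV ({exc})") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no data rows")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns (time_s, conductance_uS)")
    for col in df.columns[:2]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())
        allbad = np.flatnonzero(coerced.isna().to_numpy())
        if allbad.size:
            # +2: header line and 1-based numbering
            line = int((bad[0] if bad.size else allbad[0]) + 2)
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size == 1:
        raise ParseError(f"{path}: need at least 2 samples to infer the sampling rate")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise ParseError(f"{path}: time column must be strictly increasing")
    # 1 ppm relative tolerance plus an absolute floor for 8-decimal text times.
    tol = max(_GRID_TOL * step, 2.5e-8)
    offgrid = np.abs(dt - step) > tol
    if np.any(offgrid):
        line = int(np.argmax(offgrid)) + 3  # header + 1-based + diff offset
        raise ParseError(f"{path}: non-uniform sampling grid near line {line}")
    return RawTrace(x, sampling_rate=1.0 / step, start_time=float(t[0]))


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in RATINGS_COLUMNS if c in ratings.columns]
    ratings.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Parse and validate a ratings TSV (one row per trial)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t")
    required = ["run", "trial", "pleasure", "arousal", "familiarity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col, (lo, hi) in RATING_BOUNDS.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ParseError(f"{path}: non-numeric {col} in row {row}")
        out = (vals < lo) | (vals > hi)
        if out.any():
            row = int(out.idxmax())
            raise RangeViolationError(
                f"{path}: {col}={vals[row]} out of range [{lo}, {hi}] in row {row}"
            )
        df[col] = vals.astype(int)
    return df


def write_layout(layout: SessionLayout, path: str | Path) -> None:
    payload = {"intervals": [iv.to_dict() for iv in layout.intervals]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_layout(path: str | Path) -> SessionLayout:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        payload = json.loads(path.read_text())
        intervals = tuple(Interval.from_dict(d) for d in payload["intervals"])
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: invalid layout JSON ({exc})") from exc
    return SessionLayout(intervals)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and (np.isnan(obj)):
        return None
    if hasattr(obj, "to_dict") and not isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def write_results(
    results: dict[str, Any],
    path: str | Path,
    cell_tables: dict[str, pd.DataFrame] | None = None,
) -> list[Path]:
    """Write test statistics as JSON and cell-mean tables as TSV.

    ``path`` names the JSON file; each table in ``cell_tables`` goes to a
    sibling ``<stem>_<table>.tsv``.  Field ordering is deterministic
    (sorted keys) so re-serialization is byte-stable.
    """
    path = Path(path)
    written = [path]
    path.write_text(json.dumps(_jsonable(results), indent=1, sort_keys=True) + "\n")
    if cell_tables:
        for name, table in sorted(cell_tables.items()):
            tsv = path.with_name(f"{path.stem}_{name}.tsv")
            table.to_csv(tsv, sep="\t", float_format="%.9g")
            written.append(tsv)
    return written


def read_results(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid results JSON ({exc})") from exc
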