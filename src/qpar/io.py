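"""Plain-text serialisation of every pipeline artefact.

All formats are CSV or JSON: a one-column grid file (minutes), an intensity
matrix CSV (samples x points, header = grid), metadata and activity CSVs
keyed by sample_id, and JSON for models, splits, reports and truth records.
Floats round-trip at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ActivitySeries, FingerprintMatrix

__all__ = ["write_matrix", "read_matrix", "write_activities", "read_activities",
           "write_metadata", "write_json", "read_json", "join_activities"]


def write_matrix(fm: FingerprintMatrix, matrix_path, grid_path=None) -> None:
    """Write the intensity matrix (and optionally a one-column grid file).

    The matrix CSV has a ``sample_id`` column, a ``batch`` column, then one
    column per grid point headed by its retention time.  The preprocessing
    log goes to ``<matrix>.log.json`` alongside.
    """
    matrix_path = Path(matrix_path)
    df = pd.DataFrame(fm.X, columns=[f"{g:.17g}" for g in fm.grid])
    df.insert(0, "batch", fm.batch_ids)
    df.insert(0, "sample_id", fm.sample_ids)
    df.to_csv(matrix_path, index=False, float_format="%.17g")
    if grid_path is not None:
        np.savetxt(grid_path, fm.grid, fmt="%.17g", header="rt_minutes", comments="# ")
    log_path = matrix_path.with_suffix(matrix_path.suffix + ".log.json")
    log_path.write_text(json.dumps(fm.preprocessing_log, indent=1))


def read_matrix(matrix_path) -> FingerprintMatrix:
    matrix_path = Path(matrix_path)
    try:
        df = pd.read_csv(matrix_path)
    except (pd.errors.ParserError, ValueError) as e:
        raise ValueError(f"malformed matrix CSV {matrix_path}: {e}") from e
    if df.columns[0] != "sample_id" or df.columns[1] != "batch":
        raise ValueError(f"{matrix_path}: expected leading sample_id,batch columns, "
                         f"got {list(df.columns[:2])}")
    try:
        grid = np.array([float(c) for c in df.columns[2:]])
    except ValueError as e:
        raise ValueError(f"{matrix_path}: non-numeric grid header: {e}") from e
    vals = df.iloc[:, 2:].to_numpy(dtype=float)
    log_path = matrix_path.with_suffix(matrix_path.suffix + ".log.json")
    log = json.loads(log_path.read_text()) if log_path.exists() else [{"step": "loaded"}]
    return FingerprintMatrix(grid=grid, X=vals,
                             sample_ids=list(df["sample_id"].astype(str)),
                             batch_ids=list(df["batch"].astype(str)),
                             preprocessing_log=log)


def write_activities(activities: ActivitySeries, path) -> None:
    df = pd.DataFrame({"sample_id": activities.sample_ids,
                       "activity": activities.values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_activities(path, offset: float = 100.0) -> ActivitySeries:
    df = pd.read_csv(path)
    for col in ("sample_id", "activity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return ActivitySeries(sample_ids=list(df["sample_id"].astype(str)),
                          values=df["activity"].to_numpy(dtype=float),
                          offset=offset)


def write_metadata(chroms: list, path) -> None:
    rows = [{"sample_id": c.sample_id, "batch": c.batch_id,
             "reflux_hours": c.extraction[0] if c.extraction else "",
             "solvent_mL": c.extraction[1] if c.extraction else ""}
            for c in chroms]
    pd.DataFrame(rows).to_csv(path, index=False)


def join_activities(fm: FingerprintMatrix, activities: ActivitySeries) -> np.ndarray:
    """Activity vector ordered like the matrix rows; missing samples error."""
    lookup = {sid: v for sid, v in zip(activities.sample_ids, activities.values)}
    missing = [sid for sid in fm.sample_ids if sid not in lookup]
    if missing:
        raise ValueError(f"activities missing for samples: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    return np.array([lookup[sid] for sid in fm.sample_ids])


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder))


def read_json(path):
    return json.loads(Path(path).read_text())
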