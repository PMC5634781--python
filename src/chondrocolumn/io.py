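"""Readers and writers for the pipeline's file formats.

Cell tables and track tables are comma-delimited text with one header
row; image stacks are multi-page TIFF (one page per time point); ROIs
and configuration round-trip through JSON. Readers validate schema and
finiteness and name the offending column/row in errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import CELL_TABLE_COLUMNS, SisterTrack

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_track_table",
    "write_track_table",
    "read_stack",
    "write_stack",
    "read_roi",
    "write_roi",
]

TRACK_COLUMNS = ["pair_id", "t_h", "x1_um", "y1_um", "x2_um", "y2_um"]


class SchemaError(ValueError):
    """A table failed schema validation."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _require_finite(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: non-finite value in column {c!r} at row {row}")


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a per-cell observation table (CSV)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CELL_TABLE_COLUMNS, path)
    _require_finite(df, ["t_h", "x_um", "y_um",
                         "minor_axis_dx", "minor_axis_dy"], path)
    norms = np.hypot(df["minor_axis_dx"], df["minor_axis_dy"])
    bad = norms < 1e-12
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"{path}: zero-length minor axis at row {row}")
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_track_table(path) -> list[SisterTrack]:
    """Read a sister-track table (CSV) into one SisterTrack per pair_id."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACK_COLUMNS, path)
    _require_finite(df, TRACK_COLUMNS[1:], path)
    tracks = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        grp = grp.sort_values("t_h")
        t = grp["t_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise SchemaError(
                f"{path}: pair {pair_id!r} has duplicated or non-monotone t_h")
        tracks.append(SisterTrack(
            pair_id=str(pair_id), t_h=t,
            p1=grp[["x1_um", "y1_um"]].to_numpy(dtype=float),
            p2=grp[["x2_um", "y2_um"]].to_numpy(dtype=float),
            condition=(str(grp["condition"].iloc[0])
                       if "condition" in grp.columns else None)))
    return tracks


def write_track_table(tracks, path) -> None:
    frames = []
    for tr in tracks:
        df = tr.to_frame()
        if tr.condition is not None:
            df["condition"] = tr.condition
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stack(path) -> np.ndarray:
    """Read a (T, H, W) image stack from a multi-page TIFF."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise SchemaError(f"{path}: expected a 2D or 3D grayscale stack, "
                          f"got shape {arr.shape}")
    return arr


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_roi(path):
    """Read ROI JSON: {"waypoints": [[x,y],...]} and/or polygon regions."""
    with open(path) as fh:
        data = json.load(fh)
    return data


def write_roi(data, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
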