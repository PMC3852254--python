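"""Reading point clouds and writing region polygons.

Points come in as delimited text (CSV or TSV, two numeric columns, header
optional); regions go out as a CSV of ordered vertices or a WKT POLYGON.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ConvexRegion, GeometryError, PointSet

__all__ = ["read_points", "write_region", "read_region"]


def _sniff_delimiter(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_points(path: str | Path, delimiter: str | None = None) -> PointSet:
    """Read an (x, y) point cloud from a CSV/TSV file.

    The delimiter is sniffed when not given and a header row is
    auto-detected (a first row that does not parse as two numbers).  Rows
    with non-numeric cells are rejected with their line numbers.

    Raises
    ------
    GeometryError
        Fewer than 3 valid rows, or malformed rows.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise GeometryError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    df = pd.read_csv(_io.StringIO(text), sep=delimiter, header=None,
                     comment="#", skip_blank_lines=True, dtype=str)
    if df.shape[1] < 2:
        raise GeometryError(
            f"{path}: expected >= 2 columns with delimiter {delimiter!r}; "
            "got 1 (mixed delimiters? pass delimiter= explicitly)"
        )
    vals = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1)
    start = 0
    if bad.iloc[0]:  # header row
        start = 1
    bad_rows = np.flatnonzero(bad.values[start:]) + start
    if bad_rows.size:
        lines = ", ".join(str(i + 1) for i in bad_rows[:10])
        raise GeometryError(f"{path}: non-numeric cells on line(s) {lines}")
    pts = vals.values[start:]
    if pts.shape[0] < 3:
        raise GeometryError(f"{path}: need at least 3 valid rows, got {pts.shape[0]}")
    return PointSet(pts)


def write_region(
    region: ConvexRegion, path: str | Path, format: str = "csv"
) -> None:
    """Write a region polygon as vertex CSV or WKT POLYGON text.

    The CSV has columns ``vertex_index, x, y`` in counter-clockwise order;
    the WKT ring repeats the first vertex to close, per the WKT standard.
    """
    path = Path(path)
    v = region.vertices
    if format == "csv":
        df = pd.DataFrame(
            {"vertex_index": np.arange(v.shape[0]), "x": v[:, 0], "y": v[:, 1]}
        )
        df.to_csv(path, index=False, float_format="%.17g")
    elif format == "wkt":
        from shapely.geometry import Polygon

        path.write_text(Polygon(v).wkt + "\n")
    else:
        raise GeometryError(f"unknown format {format!r}; use 'csv' or 'wkt'")


def read_region(path: str | Path) -> ConvexRegion:
    """Read back a vertex CSV written by :func:`write_region`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"x", "y"} <= set(df.columns):
        raise GeometryError(f"{path}: expected columns x, y")
    return ConvexRegion(vertices=df[["x", "y"]].values)
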