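"""File formats: trace CSV / point-text, geometry TSV, annotations, reports.

Trace CSV dialect: header ``fibril_id,point_index,x_nm,y_nm,z_nm``, points
grouped by fibril and ordered by point_index. Point-text dialect: the
whitespace-separated ``object contour x y z`` coordinate export of
tomogram models, with coordinates in pixels scaled by a pixel size in nm
and fibril_id formed as ``object.contour``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CoreAnnotation
from .traces import FibrilTrace, dedupe_points

__all__ = [
    "read_traces",
    "write_traces",
    "read_geometry",
    "write_geometry",
    "read_annotations",
    "config_hash",
    "write_report",
]

TRACE_CSV_COLUMNS = ["fibril_id", "point_index", "x_nm", "y_nm", "z_nm"]


def _trace_from_points(fibril_id: str, pts: np.ndarray, pixel_size_nm=None):
    """Build a FibrilTrace after dedup; None if fewer than 2 distinct points."""
    pts = dedupe_points(pts, fibril_id)
    if len(pts) < 2:
        warnings.warn(f"trace {fibril_id!r}: fewer than 2 distinct points, skipped")
        return None
    return FibrilTrace(
        fibril_id=fibril_id, points=pts, provenance="imported", pixel_size_nm=pixel_size_nm
    )


def read_traces(
    path, fmt: str = "csv", pixel_size_nm: float | None = None
) -> list[FibrilTrace]:
    """Read fibril traces from a CSV or point-text file.

    Contours with fewer than two distinct points are skipped with a
    warning; consecutive duplicate points are merged.
    """
    path = Path(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = set(TRACE_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for col in ("x_nm", "y_nm", "z_nm"):
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValueError(f"{path}: non-numeric values in column {col}")
        traces = []
        for fid, grp in df.groupby("fibril_id", sort=False):
            idx = np.asarray(grp["point_index"], dtype=int)
            if not np.all(np.diff(idx) > 0):
                raise ValueError(f"{path}: point_index not strictly increasing for {fid!r}")
            trace = _trace_from_points(str(fid), grp[["x_nm", "y_nm", "z_nm"]].to_numpy())
            if trace is not None:
                traces.append(trace)
        return traces
    if fmt == "point_text":
        if pixel_size_nm is None or pixel_size_nm <= 0:
            raise ValueError("point_text format requires a positive pixel_size_nm")
        groups: dict[str, list[list[float]]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 5:
                    raise ValueError(
                        f"{path}:{lineno}: expected 5 fields (object contour x y z), got {len(parts)}"
                    )
                obj, contour = parts[0], parts[1]
                try:
                    xyz = [float(v) * pixel_size_nm for v in parts[2:5]]
                except ValueError as err:
                    raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from err
                groups.setdefault(f"{obj}.{contour}", []).append(xyz)
        traces = []
        for fid, pts in groups.items():
            trace = _trace_from_points(fid, np.asarray(pts), pixel_size_nm=pixel_size_nm)
            if trace is not None:
                traces.append(trace)
        return traces
    raise ValueError(f"unknown trace format {fmt!r}")


def write_traces(traces: list[FibrilTrace], path) -> None:
    rows = []
    for trace in traces:
        for i, (x, y, z) in enumerate(trace.points):
            rows.append((trace.fibril_id, i, x, y, z))
    pd.DataFrame(rows, columns=TRACE_CSV_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def write_geometry(geometry: pd.DataFrame, path) -> None:
    geometry.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_geometry(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"fibril_id", "contour_length_um", "r2_um2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: geometry table missing columns {sorted(missing)}")
    return df


def read_annotations(path) -> list[CoreAnnotation]:
    """Load core annotations from YAML or JSON.

    The document is either one annotation mapping or a list of them; each
    has protein_id, seq_length, ordered_ranges, mutation_positions and an
    optional sequence.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if isinstance(data, dict):
        data = [data]
    return [
        CoreAnnotation(
            protein_id=item["protein_id"],
            seq_length=item["seq_length"],
            ordered_ranges=[tuple(r) for r in item.get("ordered_ranges", [])],
            mutation_positions=frozenset(item.get("mutation_positions", [])),
            sequence=item.get("sequence"),
            metadata=item.get("metadata", {}),
        )
        for item in data
    ]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(payload: dict, path, seed: int | None = None, config: dict | None = None) -> None:
    """Write a JSON report stamped with tool version, seed and config hash."""
    record = {
        "tool": "fibriltools",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        **payload,
    }
    Path(path).write_text(
        json.dumps(record, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8"
    )
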