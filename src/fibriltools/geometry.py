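"""Per-fibril contour length and end-to-end distance.

Stage 1 of the persistence-length pipeline: reduce each polygonal chain
to the pair (L, R) that the worm-like-chain regression consumes. Internal
coordinates are nm; reported lengths are um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import FibrilTrace, InvalidTraceError

__all__ = ["FibrilGeometry", "contour_length", "end_to_end", "measure_all"]

MODES = ("spatial3d", "planar_xy")


@dataclass(frozen=True)
class FibrilGeometry:
    """Contour length L, end-to-end distance R and R^2 for one fibril (um)."""

    fibril_id: str
    contour_length_um: float
    end_to_end_um: float
    r2_um2: float


def contour_length(trace: FibrilTrace) -> float:
    """Sum of the lengths of all line segments of the polygonal chain, in um."""
    trace.validate()
    seg = np.linalg.norm(np.diff(trace.points, axis=0), axis=1)
    return float(seg.sum()) / 1000.0


def end_to_end(trace: FibrilTrace, mode: str = "spatial3d") -> float:
    """Distance between the first and last point of the chain, in um.

    ``planar_xy`` measures the distance in the xy projection (z ignored),
    for traces where only the in-plane excursion is meaningful.
    """
    trace.validate()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    d = trace.points[-1] - trace.points[0]
    if mode == "planar_xy":
        d = d[:2]
    return float(np.linalg.norm(d)) / 1000.0


def measure_all(
    traces: list[FibrilTrace],
    mode: str = "spatial3d",
    min_points: int = 2,
) -> tuple[pd.DataFrame, list[dict]]:
    """Measure (L, R) for every usable trace; log and drop the rest.

    A trace is excluded when it fails its own invariants, has fewer than
    ``min_points`` points, or collapses to zero end-to-end distance in the
    chosen mode (possible under ``planar_xy`` projection). Output rows keep
    the input order.

    Returns
    -------
    geometry : pandas.DataFrame
        Columns ``fibril_id, contour_length_um, end_to_end_um, r2_um2``.
    exclusions : list of dict
        One ``{"fibril_id": ..., "reason": ...}`` record per dropped trace.

    Raises
    ------
    ValueError
        If no traces are supplied or every trace is excluded.
    """
    if not traces:
        raise ValueError("no traces supplied")
    rows = []
    exclusions: list[dict] = []
    for trace in traces:
        try:
            trace.validate()
            if trace.n_points < min_points:
                raise InvalidTraceError(
                    f"trace {trace.fibril_id!r}: {trace.n_points} point(s) < min_points={min_points}"
                )
            L = contour_length(trace)
            R = end_to_end(trace, mode=mode)
            if R <= 0.0:
                raise InvalidTraceError(
                    f"trace {trace.fibril_id!r}: zero end-to-end distance in mode {mode!r}"
                )
        except InvalidTraceError as err:
            exclusions.append({"fibril_id": trace.fibril_id, "reason": str(err)})
            continue
        rows.append(
            {
                "fibril_id": trace.fibril_id,
                "contour_length_um": L,
                "end_to_end_um": R,
                "r2_um2": R * R,
            }
        )
    if not rows:
        raise ValueError(f"all {len(traces)} traces were excluded: {exclusions}")
    return pd.DataFrame(rows), exclusions
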