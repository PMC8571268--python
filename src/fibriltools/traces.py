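"""Polyline representation of traced amyloid fibrils.

A traced fibril is an ordered 3D polygonal chain of points in nanometres,
as produced by tracing filaments through electron-tomography volumes and
exporting the model points as text. All downstream geometry (contour
length, end-to-end distance) operates on this representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FibrilTrace",
    "InvalidTraceError",
    "InvalidParameterError",
    "dedupe_points",
]


class InvalidTraceError(ValueError):
    """A polygonal chain violates the trace invariants."""


class InvalidParameterError(ValueError):
    """A numeric parameter is outside its valid domain."""


def dedupe_points(points: np.ndarray, fibril_id: str = "?") -> np.ndarray:
    """Merge consecutive duplicate points, warning if any were dropped.

    Hand-traced model files occasionally repeat a vertex; duplicates carry
    no geometric information and would violate the strictly-positive
    segment-length invariant.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise InvalidTraceError(f"trace {fibril_id!r}: points must be an (N, 3) array")
    if len(points) < 2:
        return points
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(points[1:] != points[:-1], axis=1)
    if not keep.all():
        warnings.warn(
            f"trace {fibril_id!r}: merged {int((~keep).sum())} consecutive duplicate point(s)",
            stacklevel=2,
        )
    return points[keep]


@dataclass
class FibrilTrace:
    """One traced fibril as an ordered polygonal chain.

    Parameters
    ----------
    fibril_id : str
        Identifier, e.g. ``"12.1"`` (object.contour) for tomogram exports.
    points : (N, 3) ndarray of float
        Vertex coordinates in nm, ordered along the fibril axis.
    provenance : str
        Free-text origin tag, conventionally ``"simulated"`` or ``"imported"``.
    pixel_size_nm : float, optional
        Pixel size applied when the trace was imported from a pixel-unit
        point file; recorded for provenance only.
    """

    fibril_id: str
    points: np.ndarray
    provenance: str = "imported"
    pixel_size_nm: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.validate()

    def validate(self) -> None:
        pts = self.points
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidTraceError(
                f"trace {self.fibril_id!r}: points must be an (N, 3) array, got shape {pts.shape}"
            )
        if len(pts) < 2:
            raise InvalidTraceError(f"trace {self.fibril_id!r}: needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise InvalidTraceError(f"trace {self.fibril_id!r}: non-finite coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0.0):
            bad = int(np.argmax(seg <= 0.0))
            raise InvalidTraceError(
                f"trace {self.fibril_id!r}: zero-length segment at point index {bad}"
            )
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise InvalidTraceError(f"trace {self.fibril_id!r}: pixel_size_nm must be positive")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def reversed(self) -> "FibrilTrace":
        """The same chain traversed end-to-start."""
        return FibrilTrace(
            fibril_id=self.fibril_id,
            points=self.points[::-1].copy(),
            provenance=self.provenance,
            pixel_size_nm=self.pixel_size_nm,
        )
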