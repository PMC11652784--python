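"""Subgranular-zone linear density and laminar dendrite quantification.

Scenes are vector annotations — a polyline tracing the subgranular zone
(SGZ), two reference polylines (mid-GCL and outer-GCL edge), marker-tagged
soma points and dendrite polylines tagged primary/secondary.  Laminar
quantification counts DCX-positive somata (a), primary dendrites crossing
the mid-GCL line (b) and secondary dendrites crossing the outer-GCL edge
(c); b/a is the sprouting ratio and c/b the branching ratio.  A dendrite
that crosses its reference line several times still counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "DendritePath",
    "SgzScene",
    "LaminarCounts",
    "linear_density",
    "laminar_counts",
    "dendrite_ratios",
]


@dataclass
class DendritePath:
    """One traced dendrite: polyline points, order tag, owning soma index."""

    points: np.ndarray  # (n, 2) float, (row, col) pixel coordinates
    order: str  # "primary" | "secondary"
    soma_index: int = -1

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("dendrite path needs at least 2 (row, col) points")
        if self.order not in ("primary", "secondary"):
            raise ValueError(f"order must be 'primary' or 'secondary', got {self.order!r}")
        self.points = pts


@dataclass
class SgzScene:
    """Vector annotation of one SGZ microscopy field (pixel coordinates)."""

    sgz_polyline: np.ndarray
    mid_gcl_line: np.ndarray
    outer_gcl_line: np.ndarray
    pixel_size_um: float
    soma_positions: dict[str, np.ndarray] = field(default_factory=dict)
    dendrites: list[DendritePath] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("sgz_polyline", "mid_gcl_line", "outer_gcl_line"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"{name} needs at least 2 (row, col) points")
            setattr(self, name, arr)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.soma_positions = {
            k: np.asarray(v, dtype=float).reshape(-1, 2) for k, v in self.soma_positions.items()
        }


@dataclass
class LaminarCounts:
    a: int  # DCX+ cell bodies
    b: int  # primary dendrites crossing the mid-GCL line
    c: int  # secondary dendrites crossing the outer-GCL edge

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("counts must be nonnegative")


def arc_length_um(polyline: np.ndarray, pixel_size_um: float) -> float:
    pts = np.asarray(polyline, dtype=float)
    return float(np.hypot(*(np.diff(pts, axis=0).T)).sum()) * pixel_size_um


def linear_density(
    positions: np.ndarray,
    polyline: np.ndarray,
    band_um: float,
    pixel_size_um: float,
) -> float:
    """Cells per millimeter of trace.

    Counts positions within ``band_um`` of the polyline (perpendicular
    distance) and divides by the trace's arc length in mm.  Default band in
    the pipeline configuration is 20 µm.
    """
    length_um = arc_length_um(polyline, pixel_size_um)
    if length_um <= 0:
        raise ValueError("polyline has zero arc length")
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    line = LineString(np.asarray(polyline, dtype=float))
    count = sum(
        1 for p in positions if line.distance(Point(p)) * pixel_size_um <= band_um
    )
    return count / (length_um / 1000.0)


def _crosses(path_pts: np.ndarray, line_pts: np.ndarray) -> bool:
    return LineString(path_pts).intersects(LineString(line_pts))


def laminar_counts(scene: SgzScene, marker: str = "DCX") -> LaminarCounts:
    """Count somata and laminar dendrite crossings for one scene.

    b counts primary paths with at least one crossing of the mid-GCL line;
    c counts secondary paths with at least one crossing of the outer-GCL
    edge.  Multiple crossings by one path count once.
    """
    for name in ("mid_gcl_line", "outer_gcl_line"):
        line = getattr(scene, name)
        if not LineString(line).is_simple:
            raise ValueError(f"{name} is self-intersecting")
    a = int(scene.soma_positions.get(marker, np.empty((0, 2))).shape[0])
    b = sum(
        1 for d in scene.dendrites if d.order == "primary" and _crosses(d.points, scene.mid_gcl_line)
    )
    c = sum(
        1 for d in scene.dendrites if d.order == "secondary" and _crosses(d.points, scene.outer_gcl_line)
    )
    return LaminarCounts(a=a, b=int(b), c=int(c))


def dendrite_ratios(counts: LaminarCounts) -> tuple[float | None, float | None]:
    """(sprouting b/a, branching c/b); ``None`` marks an undefined ratio."""
    sprouting = counts.b / counts.a if counts.a > 0 else None
    branching = counts.c / counts.b if counts.b > 0 else None
    return sprouting, branching
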