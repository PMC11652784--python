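"""Shared fixtures and independent geometry oracles.

The oracles deliberately take different code paths from the package:
hull areas come from shapely's convex hull over the corner cloud, Feret
diameters from brute force over *all* corner points or from a hand-rolled
rotating-calipers sweep, and segment intersections from an orientation-test
routine written here.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from shapely.geometry import MultiPoint

from gliaquant.imaging import ImagePlane, RegionMask

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def mask_to_region(mask: np.ndarray, pixel_size_um: float = 1.0, label: int = 1) -> RegionMask:
    return RegionMask(label=label, pixel_coords=np.argwhere(mask), pixel_size_um=pixel_size_um)


def plane_from(mask_or_vals: np.ndarray, pixel_size_um: float = 1.0, value: int = 200) -> ImagePlane:
    arr = np.asarray(mask_or_vals)
    if arr.dtype == bool:
        arr = np.where(arr, value, 0).astype(np.uint8)
    return ImagePlane(arr.astype(np.uint8), pixel_size_um)


def corner_cloud(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords)
    pts = np.concatenate([coords, coords + [1, 0], coords + [0, 1], coords + [1, 1]])
    return np.unique(pts, axis=0).astype(float)


def oracle_hull_area(coords: np.ndarray) -> float:
    """Convex-hull area of the pixel-corner cloud, via shapely."""
    return MultiPoint([tuple(p) for p in corner_cloud(coords)]).convex_hull.area


def oracle_feret_allpairs(coords: np.ndarray) -> float:
    """Brute-force max pairwise distance over the full corner cloud."""
    pts = corner_cloud(coords)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def oracle_feret_calipers(coords: np.ndarray) -> float:
    """Rotating-calipers diameter of the corner cloud's convex hull."""
    hull = MultiPoint([tuple(p) for p in corner_cloud(coords)]).convex_hull
    verts = np.array(hull.exterior.coords[:-1])  # CCW, closed ring dropped
    n = len(verts)
    if n == 1:
        return 0.0
    if n == 2:
        return float(np.hypot(*(verts[1] - verts[0])))

    def area2(a, b, c):
        u, v = b - a, c - a
        return abs(u[0] * v[1] - u[1] * v[0])

    best = 0.0
    j = 1
    for i in range(n):
        nxt = (i + 1) % n
        while area2(verts[i], verts[nxt], verts[(j + 1) % n]) > area2(verts[i], verts[nxt], verts[j]):
            j = (j + 1) % n
        for k in (i, nxt):
            best = max(best, float(np.hypot(*(verts[j] - verts[k]))))
    return best


def segments_intersect(p1, p2, q1, q2) -> bool:
    """Orientation-test segment intersection, collinear overlaps included."""
    p1, p2, q1, q2 = (np.asarray(x, dtype=float) for x in (p1, p2, q1, q2))

    def orient(a, b, c):
        u, w = b - a, c - a
        v = u[0] * w[1] - u[1] * w[0]
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    def on_seg(a, b, c):
        return min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12 and min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if o1 != o2 and o3 != o4:
        return True
    return (
        (o1 == 0 and on_seg(p1, p2, q1))
        or (o2 == 0 and on_seg(p1, p2, q2))
        or (o3 == 0 and on_seg(q1, q2, p1))
        or (o4 == 0 and on_seg(q1, q2, p2))
    )


def oracle_polyline_cross(path: np.ndarray, line: np.ndarray) -> bool:
    """Brute-force all-segment-pairs polyline intersection."""
    path, line = np.asarray(path), np.asarray(line)
    for i in range(len(path) - 1):
        for j in range(len(line) - 1):
            if segments_intersect(path[i], path[i + 1], line[j], line[j + 1]):
                return True
    return False


def random_blob_coords(rng: np.random.Generator, size: int = 14, p: float = 0.45) -> np.ndarray:
    """Pixel coords of the largest 8-connected component of a random grid."""
    from skimage import measure

    while True:
        grid = rng.random((size, size)) < p
        labeled = measure.label(grid, connectivity=2)
        if labeled.max() == 0:
            continue
        counts = np.bincount(labeled.ravel())[1:]
        return np.argwhere(labeled == 1 + int(counts.argmax()))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
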