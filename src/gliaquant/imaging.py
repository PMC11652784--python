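"""Image I/O, threshold segmentation and geometric primitives.

Conventions used throughout the package:

* Images are single-channel 8-bit planes with a square pixel calibration in
  micrometers (``pixel_size_um``).
* Thresholding keeps pixels whose value lies in the **inclusive** interval
  ``[low, high]``; no shade/flat-field correction is applied beforehand.
* Connected components use 8-connectivity, so thin diagonal processes of
  ramified cells stay connected.
* The convex hull is taken over the cloud of pixel *corners* (each foreground
  pixel contributes its four corner points).  A single pixel therefore has
  hull area exactly 1 px², convex rasterized shapes score a form factor of 1,
  and a 1xN bar has Feret diameter sqrt(N^2 + 1) px — the corner-cloud
  caliper convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "ImagePlane",
    "RegionMask",
    "read_image",
    "write_image",
    "write_mask",
    "segment",
    "regions_to_frame",
]


@dataclass
class ImagePlane:
    """One 8-bit image channel with µm pixel calibration.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities in 0–255.
    pixel_size_um
        Edge length of one pixel in micrometers; must be positive.
    channel_name
        Free-text marker name, e.g. ``"Iba1"``, ``"GFAP"``, ``"ThS"``,
        ``"AmyloGlo"``, ``"DCX"`` or ``"BrdU"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {arr.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities outside [0, 255]; rescale first")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RegionMask:
    """A labeled 8-connected pixel region with hull-derived measures.

    ``pixel_coords`` is an (n, 2) integer array of (row, col) pairs.  Derived
    geometry (hull, convex area, Feret diameter) is computed lazily on the
    corner cloud and cached.
    """

    label: int
    pixel_coords: np.ndarray
    pixel_size_um: float
    _corner_hull: ConvexHull | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.pixel_coords, dtype=np.int64)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] == 0:
            raise ValueError("pixel_coords must be a nonempty (n, 2) array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.pixel_coords = coords

    @property
    def area_px(self) -> int:
        return int(self.pixel_coords.shape[0])

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @property
    def corner_points(self) -> np.ndarray:
        """Unique pixel-corner points of the mask, as float (row, col)."""
        r = self.pixel_coords[:, 0]
        c = self.pixel_coords[:, 1]
        corners = np.concatenate(
            [
                np.stack([r, c], axis=1),
                np.stack([r + 1, c], axis=1),
                np.stack([r, c + 1], axis=1),
                np.stack([r + 1, c + 1], axis=1),
            ]
        )
        return np.unique(corners, axis=0).astype(float)

    def _hull(self) -> ConvexHull:
        if self._corner_hull is None:
            # Pixel corners always span 2-D (a single pixel gives a unit
            # square), so qhull never sees a degenerate input.
            self._corner_hull = ConvexHull(self.corner_points)
        return self._corner_hull

    @property
    def hull_vertices(self) -> np.ndarray:
        """Ordered hull polygon vertices in pixel-corner coordinates."""
        hull = self._hull()
        return hull.points[hull.vertices]

    @property
    def convex_area_um2(self) -> float:
        # qhull's ``volume`` is the polygon area in 2-D (shoelace).
        return float(self._hull().volume) * self.pixel_size_um**2

    @property
    def feret_um(self) -> float:
        """Maximum caliper distance over hull vertices, in µm."""
        verts = self.hull_vertices
        if len(verts) == 1:  # pragma: no cover - corners always >= 4
            return 0.0
        return float(pdist(verts).max()) * self.pixel_size_um

    @cached_property
    def centroid(self) -> tuple[float, float]:
        """Centroid of pixel centers, (row, col) in pixel units."""
        centers = self.pixel_coords + 0.5
        return (float(centers[:, 0].mean()), float(centers[:, 1].mean()))

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.pixel_coords[:, 0], self.pixel_coords[:, 1]] = True
        return out

    def touches_border(self, shape: tuple[int, int]) -> bool:
        r, c = self.pixel_coords[:, 0], self.pixel_coords[:, 1]
        return bool(
            (r == 0).any() or (c == 0).any() or (r == shape[0] - 1).any() or (c == shape[1] - 1).any()
        )


def read_image(path: str | Path, pixel_size_um: float, channel_name: str = "", page: int = 0) -> ImagePlane:
    """Read one grayscale TIFF page as an :class:`ImagePlane`.

    Non-8-bit input is linearly rescaled to 0–255 with a logged warning.
    """
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path, key=page)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single grayscale plane, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        logger.warning("%s: dtype %s rescaled to 8-bit", path, arr.dtype)
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr, dtype=np.float64) if hi == lo else (arr - lo) / (hi - lo) * 255.0
        arr = np.round(arr).astype(np.uint8)
    return ImagePlane(pixels=arr, pixel_size_um=pixel_size_um, channel_name=channel_name)


def write_image(plane: ImagePlane, path: str | Path) -> None:
    """Write an :class:`ImagePlane` to a single-page 8-bit grayscale TIFF."""
    tifffile.imwrite(Path(path), plane.pixels)


def write_mask(regions: list["RegionMask"], shape: tuple[int, int], path: str | Path) -> None:
    """Write regions as a 0/255 binary TIFF mask."""
    out = np.zeros(shape, dtype=np.uint8)
    for reg in regions:
        out[reg.pixel_coords[:, 0], reg.pixel_coords[:, 1]] = 255
    tifffile.imwrite(Path(path), out)


def segment(
    image: ImagePlane,
    low: int,
    high: int = 255,
    min_area_px: int = 30,
) -> list[RegionMask]:
    """Threshold-segment an image into labeled 8-connected regions.

    Foreground pixels are those with value in the inclusive interval
    ``[low, high]``.  Components smaller than ``min_area_px`` are discarded;
    surviving regions are relabeled 1..K in raster order of their first
    foreground pixel.
    """
    if not (0 <= low <= 255 and 0 <= high <= 255):
        raise ValueError("thresholds must be within [0, 255]")
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")
    fg = (image.pixels >= low) & (image.pixels <= high)
    labeled = measure.label(fg, connectivity=2)
    ncols = image.pixels.shape[1]
    regions: list[tuple[int, np.ndarray]] = []
    for props in measure.regionprops(labeled):
        coords = props.coords
        if coords.shape[0] < min_area_px:
            continue
        first = int((coords[:, 0] * ncols + coords[:, 1]).min())
        regions.append((first, coords))
    regions.sort(key=lambda t: t[0])
    return [
        RegionMask(label=i + 1, pixel_coords=coords, pixel_size_um=image.pixel_size_um)
        for i, (_, coords) in enumerate(regions)
    ]


def regions_to_frame(regions: list[RegionMask]) -> pd.DataFrame:
    """Tabulate regions as a DataFrame (one row per region)."""
    rows = []
    for reg in regions:
        cr, cc = reg.centroid
        rows.append(
            {
                "label": reg.label,
                "area_px": reg.area_px,
                "area_um2": reg.area_um2,
                "convex_area_um2": reg.convex_area_um2,
                "feret_um": reg.feret_um,
                "centroid_row": cr,
                "centroid_col": cc,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "area_px", "area_um2", "convex_area_um2", "feret_um", "centroid_row", "centroid_col"],
    )
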