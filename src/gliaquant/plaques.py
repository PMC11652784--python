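"""Plaque detection, Feret neighborhoods, halo intensity and slope comparison.

A plaque's *neighborhood* is the disk centered on the plaque centroid whose
diameter is 8x the plaque's Feret diameter (radius = 4 x Feret).  Glial
activation around a plaque is scored as the background-corrected integrated
intensity of the glial channel inside that disk, counting only pixels whose
raw value lies in the glial threshold window (default 30–255).  Plaques whose
neighborhoods overlap are excluded from analysis, both members of each
overlapping pair.

Group-level analysis regresses halo intensity on plaque area per group
(ordinary least squares) and tests slope differences against a reference
group through the area x group interaction term of a pooled model — the
classic ANCOVA heterogeneity-of-slopes test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from gliaquant.imaging import ImagePlane, RegionMask, segment

__all__ = [
    "PlaqueRecord",
    "RegressionFit",
    "SlopeComparison",
    "detect_plaques",
    "exclude_overlaps",
    "default_background",
    "halo_intensity",
    "regress_intensity_on_area",
    "compare_slopes",
    "count_plaques_and_clusters",
    "plaques_to_frame",
]

NEIGHBORHOOD_FACTOR = 8  # neighborhood *diameter* in units of Feret diameter


@dataclass
class PlaqueRecord:
    """Geometry and halo measurement for one detected plaque."""

    plaque_id: int
    region: RegionMask = field(repr=False)
    excluded: bool = False
    halo_intensity: float | None = None

    @property
    def area_um2(self) -> float:
        return self.region.area_um2

    @property
    def feret_um(self) -> float:
        return self.region.feret_um

    @property
    def centroid(self) -> tuple[float, float]:
        return self.region.centroid

    @property
    def neighborhood_radius_um(self) -> float:
        return NEIGHBORHOOD_FACTOR / 2 * self.feret_um


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float = float("nan")
    slope_ci: tuple[float, float] = (float("nan"), float("nan"))


@dataclass
class SlopeComparison:
    group: str
    slope_difference: float
    p_value: float


def detect_plaques(
    plaque_channel: ImagePlane,
    low: int = 20,
    high: int = 255,
    min_area_px: int = 20,
) -> list[PlaqueRecord]:
    """Segment the plaque channel (default threshold 20–255) into records."""
    regions = segment(plaque_channel, low=low, high=high, min_area_px=min_area_px)
    return [PlaqueRecord(plaque_id=reg.label, region=reg) for reg in regions]


def exclude_overlaps(plaques: list[PlaqueRecord], mode: str = "disk") -> list[PlaqueRecord]:
    """Flag plaques whose neighborhoods overlap; both members of a pair.

    ``mode="disk"`` (default) flags any pair whose neighborhood disks
    intersect (centroid distance < sum of neighborhood radii).  ``mode="mask"``
    is the looser variant that only flags a pair when one plaque's *mask*
    reaches into the other's neighborhood disk.  Flags are set in place and
    the list is returned; the operation is symmetric and idempotent.
    """
    if mode not in ("disk", "mask"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    for i, a in enumerate(plaques):
        pa = a.region.pixel_size_um
        ca = np.array(a.centroid) * pa
        for b in plaques[i + 1 :]:
            cb = np.array(b.centroid) * b.region.pixel_size_um
            dist = float(np.hypot(*(ca - cb)))
            if mode == "disk":
                overlap = dist < a.neighborhood_radius_um + b.neighborhood_radius_um
            else:
                overlap = _mask_in_disk(a, b) or _mask_in_disk(b, a)
            if overlap:
                a.excluded = True
                b.excluded = True
    return plaques


def _mask_in_disk(inner: PlaqueRecord, outer: PlaqueRecord) -> bool:
    px = inner.region.pixel_size_um
    centers = (inner.region.pixel_coords + 0.5) * px
    center = np.array(outer.centroid) * outer.region.pixel_size_um
    d = np.hypot(centers[:, 0] - center[0], centers[:, 1] - center[1])
    return bool((d <= outer.neighborhood_radius_um).any())


def neighborhood_mask(plaque: PlaqueRecord, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the plaque's neighborhood disk (pixel centers within
    the radius, inclusive)."""
    px = plaque.region.pixel_size_um
    cr, cc = plaque.centroid
    radius_px = plaque.neighborhood_radius_um / px
    rows = np.arange(shape[0])[:, None] + 0.5
    cols = np.arange(shape[1])[None, :] + 0.5
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= radius_px**2


def default_background(
    glial_channel: ImagePlane,
    plaques: list[PlaqueRecord],
    erode_px: int = 5,
) -> np.ndarray:
    """Default non-plaque-associated reference region.

    Complement of the union of all neighborhood disks, eroded by ``erode_px``
    pixels to keep the reference clear of halo fringes.
    """
    shape = glial_channel.shape
    union = np.zeros(shape, dtype=bool)
    for p in plaques:
        union |= neighborhood_mask(p, shape)
    bg = ~union
    if erode_px > 0:
        bg = ndimage.binary_erosion(bg, iterations=erode_px)
    if not bg.any():
        raise ValueError("background region is empty; provide an explicit ROI")
    return bg


def halo_intensity(
    glial_channel: ImagePlane,
    plaque: PlaqueRecord,
    background: np.ndarray | RegionMask,
    low: int = 30,
    high: int = 255,
) -> float:
    """Background-corrected integrated glial intensity in the neighborhood.

    Sum over neighborhood-disk pixels of ``max(value - background_mean, 0)``,
    counting only pixels whose raw value lies in ``[low, high]``.  The
    background mean is the mean raw intensity of the reference region.  The
    result is stored on the record and returned.
    """
    if plaque.excluded:
        raise ValueError(f"plaque {plaque.plaque_id} is excluded from analysis")
    bg_mask = background.to_mask(glial_channel.shape) if isinstance(background, RegionMask) else background
    if not bg_mask.any():
        raise ValueError("empty background region")
    pixels = glial_channel.pixels.astype(np.float64)
    bg_mean = float(pixels[bg_mask].mean())
    disk = neighborhood_mask(plaque, glial_channel.shape)
    vals = pixels[disk]
    vals = vals[(vals >= low) & (vals <= high)]
    total = float(np.maximum(vals - bg_mean, 0.0).sum())
    plaque.halo_intensity = total
    return total


def regress_intensity_on_area(
    records: list[PlaqueRecord] | list[tuple[float, float]],
    alpha: float = 0.05,
) -> RegressionFit:
    """OLS fit of halo intensity on plaque area for non-excluded records."""
    x, y = _xy(records)
    if len(x) < 3:
        raise ValueError(f"need at least 3 records, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in plaque area")
    if np.ptp(y) == 0:
        # Constant response: flat fit, no variance explained.
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=len(x), slope_se=0.0, slope_ci=(0.0, 0.0))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=len(x),
        slope_se=float(model.bse[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
    )


def _xy(records) -> tuple[np.ndarray, np.ndarray]:
    if len(records) and isinstance(records[0], PlaqueRecord):
        kept = [r for r in records if not r.excluded]
        missing = [r.plaque_id for r in kept if r.halo_intensity is None]
        if missing:
            raise ValueError(f"records without halo_intensity: {missing}")
        x = np.array([r.area_um2 for r in kept], dtype=float)
        y = np.array([r.halo_intensity for r in kept], dtype=float)
    else:
        arr = np.asarray(records, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    return x, y


def compare_slopes(
    groups: dict[str, list[PlaqueRecord] | list[tuple[float, float]]],
    reference: str,
) -> list[SlopeComparison]:
    """Test each group's regression slope against the reference group.

    Fits the pooled model ``y ~ area + group + area:group`` with the
    reference group as baseline; each non-reference group's p-value is the
    Wald test of its interaction coefficient (slope difference).
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    frames = []
    for name, recs in groups.items():
        x, y = _xy(recs)
        if len(x) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 records")
        frames.append(pd.DataFrame({"area": x, "intensity": y, "group": name}))
    df = pd.concat(frames, ignore_index=True)
    others = [g for g in groups if g != reference]
    # Reference-coded design: intercept + area for the reference, plus a
    # level shift and slope shift per other group.
    cols = {"const": np.ones(len(df)), "area": df["area"].to_numpy()}
    for g in others:
        ind = (df["group"] == g).to_numpy(dtype=float)
        cols[f"g[{g}]"] = ind
        cols[f"area:g[{g}]"] = ind * df["area"].to_numpy()
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("degenerate design: collinear area/group structure")
    model = sm.OLS(df["intensity"].to_numpy(), X).fit()
    return [
        SlopeComparison(
            group=g,
            slope_difference=float(model.params[f"area:g[{g}]"]),
            p_value=float(model.pvalues[f"area:g[{g}]"]),
        )
        for g in others
    ]


def count_plaques_and_clusters(
    plaque_channel: ImagePlane,
    gfap_channel: ImagePlane,
    iba1_channel: ImagePlane,
    plaque_low: int = 20,
    glial_low: int = 30,
    glial_high: int = 255,
    min_cluster_px: int = 30,
    min_plaque_px: int = 20,
) -> tuple[int, int, int]:
    """Count plaques and plaque-associated glial clusters.

    A glial cluster is a glial-channel region (threshold window
    ``[glial_low, glial_high]``, minimum size ``min_cluster_px``) whose
    centroid lies within some plaque's neighborhood disk.  Returns
    ``(n_plaques, n_gfap_clusters, n_iba1_clusters)``.
    """
    if not (plaque_channel.shape == gfap_channel.shape == iba1_channel.shape):
        raise ValueError("channel shapes differ; channels must be co-registered")
    plaques = detect_plaques(plaque_channel, low=plaque_low, min_area_px=min_plaque_px)
    disks = np.zeros(plaque_channel.shape, dtype=bool)
    for p in plaques:
        disks |= neighborhood_mask(p, plaque_channel.shape)

    def n_clusters(channel: ImagePlane) -> int:
        regions = segment(channel, low=glial_low, high=glial_high, min_area_px=min_cluster_px)
        count = 0
        for reg in regions:
            cr, cc = reg.centroid
            r, c = int(cr), int(cc)
            if 0 <= r < disks.shape[0] and 0 <= c < disks.shape[1] and disks[r, c]:
                count += 1
        return count

    return len(plaques), n_clusters(gfap_channel), n_clusters(iba1_channel)


def plaques_to_frame(plaques: list[PlaqueRecord]) -> pd.DataFrame:
    rows = []
    for p in plaques:
        cr, cc = p.centroid
        rows.append(
            {
                "plaque_id": p.plaque_id,
                "area_um2": p.area_um2,
                "feret_um": p.feret_um,
                "centroid_row": cr,
                "centroid_col": cc,
                "neighborhood_radius_um": p.neighborhood_radius_um,
                "excluded": p.excluded,
                "halo_intensity": p.halo_intensity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plaque_id",
            "area_um2",
            "feret_um",
            "centroid_row",
            "centroid_col",
            "neighborhood_radius_um",
            "excluded",
            "halo_intensity",
        ],
    )
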