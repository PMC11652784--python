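"""Seeded synthetic-scene generator with ground truth for every stage.

Each generator consumes a spec dataclass plus an integer seed and returns
both the synthetic input (image planes, vector scene, tables) and a truth
object describing exactly what was drawn, so downstream measurements can be
validated by recovery tests.  A single seed drives one named pseudorandom
stream per scene component, so adding a component never perturbs existing
draws, and identical spec + seed reproduces bit-identical output.

What the scenes emulate (and what they do not): microglia are a soma disk
plus jittered-walk branches — no real process tortuosity, no touching cells;
plaques are radial-falloff blobs with glial halos painted to an exact linear
target in plaque area — no photophysics beyond that (no PSF, no Poisson shot
noise); subgranular-zone scenes are vector annotations with a QC raster —
not a stain model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw

from gliaquant.imaging import ImagePlane
from gliaquant.neurogenesis import DendritePath, SgzScene
from gliaquant.plaques import detect_plaques, neighborhood_mask

__all__ = [
    "rng_for",
    "MicrogliaSpec",
    "PlaqueSpec",
    "SgzSpec",
    "SignatureSpec",
    "MetabolicGroup",
    "MetabolicSpec",
    "generate_microglia_scene",
    "generate_plaque_scene",
    "generate_sgz_scene",
    "generate_signature_tables",
    "generate_metabolic_cohort",
    "sigma_for_r2",
]


def rng_for(seed: int, component: str) -> np.random.Generator:
    """Independent, reproducible stream for one named scene component."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(component.encode())])
    )


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place all objects."""


def _place_centers(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_dist: np.ndarray | float,
    max_retries: int = 5000,
) -> np.ndarray:
    """Place n points in the box [lo, hi] with pairwise distance constraints.

    ``min_dist`` may be scalar or per-point radii (pair constraint is the
    radii sum).  Raises :class:`PackingError` if the canvas is too crowded.
    """
    radii = np.broadcast_to(np.atleast_1d(min_dist).astype(float) / 2.0, (n,))
    centers: list[np.ndarray] = []
    for i in range(n):
        for _ in range(max_retries):
            cand = lo + rng.random(2) * (hi - lo)
            ok = all(
                np.hypot(*(cand - c)) >= radii[i] + radii[j] for j, c in enumerate(centers)
            )
            if ok:
                centers.append(cand)
                break
        else:
            raise PackingError(
                f"could not place object {i + 1}/{n} after {max_retries} tries; "
                "canvas too small for the requested count"
            )
    return np.array(centers)


# ---------------------------------------------------------------------------
# Microglia scenes
# ---------------------------------------------------------------------------


@dataclass
class MicrogliaSpec:
    """Microglial scene layout.

    ``activation`` is a branch-retraction fraction in [0, 1): 0 leaves
    branches at ``branch_length_um`` (ramified), values near 1 retract them
    toward the soma (amoeboid/activated morphology).
    """

    image_size_px: int = 640
    pixel_size_um: float = 0.5
    n_cells: int = 6
    soma_radius_um: float = 8.0
    n_branches: int = 5
    branch_length_um: float = 30.0
    branch_width_um: float = 2.0
    activation: float = 0.0
    foreground_intensity: int = 200
    channel_name: str = "Iba1"


@dataclass
class CellTruth:
    center: tuple[float, float]
    soma_radius_px: float
    branch_length_px: float
    n_branches: int
    solidity_class: str  # "amoeboid" | "ramified"
    n_pixels: int


def generate_microglia_scene(spec: MicrogliaSpec, seed: int) -> tuple[ImagePlane, list[CellTruth]]:
    """Rasterize non-overlapping synthetic microglia with per-cell truth."""
    if not 0 <= spec.activation < 1:
        raise ValueError("activation must be in [0, 1)")
    rng = rng_for(seed, "microglia")
    px = spec.pixel_size_um
    size = spec.image_size_px
    soma_r = spec.soma_radius_um / px
    eff_len = (spec.branch_length_um * (1.0 - spec.activation) / px) if spec.n_branches else 0.0
    width_r = max(spec.branch_width_um / px / 2.0, 0.5)
    envelope = soma_r + (eff_len if spec.n_branches else 0) + 2 * width_r + 2
    margin = envelope + 2
    if 2 * margin >= size:
        raise PackingError("cells larger than canvas")
    centers = _place_centers(
        rng,
        spec.n_cells,
        lo=np.array([margin, margin]),
        hi=np.array([size - margin, size - margin]),
        min_dist=2 * envelope + 2,
    )
    canvas = np.zeros((size, size), dtype=np.uint8)
    truths = []
    for center in centers:
        mask = np.zeros_like(canvas, dtype=bool)
        rr, cc = draw.disk(tuple(center), soma_r, shape=canvas.shape)
        mask[rr, cc] = True
        base_angle = rng.uniform(0, 2 * np.pi)
        for b in range(spec.n_branches):
            if eff_len < 1:
                break
            angle = base_angle + 2 * np.pi * b / spec.n_branches + rng.normal(0, 0.15)
            pos = center + (soma_r - 1) * np.array([np.sin(angle), np.cos(angle)])
            for _ in range(int(round(eff_len))):
                angle += rng.normal(0, 0.12)
                pos = pos + np.array([np.sin(angle), np.cos(angle)])
                rr, cc = draw.disk(tuple(pos), width_r + 0.5, shape=canvas.shape)
                mask[rr, cc] = True
        canvas[mask] = spec.foreground_intensity
        truths.append(
            CellTruth(
                center=(float(center[0]), float(center[1])),
                soma_radius_px=soma_r,
                branch_length_px=eff_len,
                n_branches=spec.n_branches,
                solidity_class="amoeboid" if eff_len < soma_r else "ramified",
                n_pixels=int(mask.sum()),
            )
        )
    plane = ImagePlane(pixels=canvas, pixel_size_um=px, channel_name=spec.channel_name)
    return plane, truths


# ---------------------------------------------------------------------------
# Plaque scenes
# ---------------------------------------------------------------------------


@dataclass
class PlaqueSpec:
    """Plaque + glial-halo scene.

    The glial channel paints, inside each plaque's 8xFeret neighborhood
    disk, clustered blobs whose total excess intensity over background is
    ``beta1 * area_um2 + beta0 + Normal(0, sigma)`` — the linear halo model
    (default coefficients follow the vehicle-group fit y = 633.8x + 276,179).
    The target is quantized to integers with the remainder spread one count
    per pixel, so the painted excess matches the drawn target to < 1 a.u.
    """

    image_size_px: int = 768
    pixel_size_um: float = 1.0
    n_plaques: int = 5
    radius_um_range: tuple[float, float] = (5.0, 10.0)
    beta1: float = 633.8
    beta0: float = 276179.0
    sigma: float = 0.0
    glial_background: int = 10
    n_cluster_blobs: int = 3
    cluster_radius_px: float = 7.0
    allow_overlap: bool = False
    plaque_channel_name: str = "AmyloGlo"
    glial_channel_name: str = "Iba1"


@dataclass
class PlaqueTruth:
    plaque_id: int
    radius_px: float
    area_um2: float
    feret_um: float
    target_excess: float
    painted_excess: int
    beta1: float
    beta0: float
    sigma: float


def generate_plaque_scene(
    spec: PlaqueSpec, seed: int
) -> tuple[ImagePlane, ImagePlane, list[PlaqueTruth]]:
    """Rasterize plaques, detect them, then paint halos from the linear model.

    Halos are painted from the *detected* plaque geometry (area and
    neighborhood from the same segmentation the pipeline applies), so the
    stored truth is exactly what a correct measurement should recover.
    """
    rng = rng_for(seed, "plaque")
    size = spec.image_size_px
    px = spec.pixel_size_um
    r_lo, r_hi = spec.radius_um_range
    radii_px = rng.uniform(r_lo, r_hi, size=spec.n_plaques) / px
    # Spacing keeps the 8xFeret neighborhood disks disjoint: Feret of a
    # radial-falloff blob thresholded at 20/255 is ~2 * 0.93 * R.
    nbhd = 4 * 2 * 0.95 * radii_px
    margin = float(nbhd.max()) + 4
    if spec.allow_overlap:
        min_dist = 2 * radii_px + 2
    else:
        min_dist = 2 * nbhd + 8
    centers = _place_centers(
        rng,
        spec.n_plaques,
        lo=np.array([margin, margin]),
        hi=np.array([size - margin, size - margin]),
        min_dist=min_dist,
    )
    plaque_px = np.zeros((size, size), dtype=np.uint8)
    rows = np.arange(size)[:, None] + 0.5
    cols = np.arange(size)[None, :] + 0.5
    for (cr, cc), R in zip(centers, radii_px):
        d = np.hypot(rows - cr, cols - cc)
        vals = np.clip(255.0 * (1.0 - d / R), 0, 255)
        plaque_px = np.maximum(plaque_px, np.round(vals).astype(np.uint8))
    plaque_plane = ImagePlane(plaque_px, px, spec.plaque_channel_name)

    records = detect_plaques(plaque_plane, low=20, min_area_px=20)
    glial = np.full((size, size), spec.glial_background, dtype=np.uint8)
    truths = []
    radius_by_record = _match_radii(records, centers, radii_px)
    for rec in records:
        target = spec.beta1 * rec.area_um2 + spec.beta0 + rng.normal(0, spec.sigma)
        target = max(target, 0.0)
        painted = _paint_halo(glial, rec, target, spec, rng)
        truths.append(
            PlaqueTruth(
                plaque_id=rec.plaque_id,
                radius_px=radius_by_record[rec.plaque_id],
                area_um2=rec.area_um2,
                feret_um=rec.feret_um,
                target_excess=target,
                painted_excess=painted,
                beta1=spec.beta1,
                beta0=spec.beta0,
                sigma=spec.sigma,
            )
        )
    glial_plane = ImagePlane(glial, px, spec.glial_channel_name)
    return plaque_plane, glial_plane, truths


def _match_radii(records, centers, radii_px) -> dict[int, float]:
    out = {}
    for rec in records:
        c = np.array(rec.centroid)
        d = np.hypot(centers[:, 0] - c[0], centers[:, 1] - c[1])
        out[rec.plaque_id] = float(radii_px[int(d.argmin())])
    return out


def _paint_halo(glial, record, target, spec: PlaqueSpec, rng) -> int:
    """Paint clustered blobs inside the neighborhood disk summing to target."""
    bg = spec.glial_background
    q = int(round(target))
    if q < 30 - bg:
        return 0
    disk = neighborhood_mask(record, glial.shape)
    cr, cc = record.centroid
    radius_px = record.neighborhood_radius_um / record.region.pixel_size_um
    # Enough pixels that integer values stay within [30, 255]; aim mid-range.
    n_min = int(np.ceil(q / (255 - bg - 1)))
    n_max = int(q // (30 - bg))
    n_cap = int(0.9 * disk.sum())
    if n_min > n_cap:
        raise PackingError("halo target exceeds neighborhood intensity capacity")
    n_target = int(np.clip(int(np.ceil(q / 120)), n_min, min(max(n_min, n_max), n_cap)))
    chosen = np.zeros_like(disk)
    blobs = 0
    while chosen.sum() < n_target:
        blobs += 1
        if blobs > 60:
            # Blob placement saturated; top up from the remaining disk pixels.
            remaining = np.argwhere(disk & ~chosen)
            need = n_target - int(chosen.sum())
            pick = remaining[rng.permutation(len(remaining))[:need]]
            chosen[pick[:, 0], pick[:, 1]] = True
            break
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.7) * radius_px
        center = (cr + rad * np.sin(ang), cc + rad * np.cos(ang))
        rr, cols_ = draw.disk(center, spec.cluster_radius_px, shape=glial.shape)
        keep = disk[rr, cols_]
        chosen[rr[keep], cols_[keep]] = True
    coords = np.argwhere(chosen)
    order = rng.permutation(len(coords))[:n_target] if len(coords) > n_target else np.arange(len(coords))
    coords = coords[order]
    n = len(coords)
    base = q // n
    rem = q - base * n
    vals = np.full(n, bg + base, dtype=int)
    vals[:rem] += 1
    glial[coords[:, 0], coords[:, 1]] = vals.astype(np.uint8)
    return q


def sigma_for_r2(beta1: float, areas_um2: np.ndarray, r_squared: float) -> float:
    """Noise SD giving an expected regression R² at the given slope/areas."""
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must be in (0, 1)")
    signal_sd = abs(beta1) * float(np.std(areas_um2))
    return signal_sd * np.sqrt((1 - r_squared) / r_squared)


def sample_halo_records(
    spec: PlaqueSpec, seed: int, n: int, area_um2_range: tuple[float, float] = (50.0, 400.0)
) -> np.ndarray:
    """Record-level halo sampler: (area, intensity) pairs from the linear
    model, without rasterization.  Shares the generator's model and spec so
    large regression simulations stay cheap."""
    rng = rng_for(seed, "halo-records")
    areas = rng.uniform(*area_um2_range, size=n)
    y = spec.beta1 * areas + spec.beta0 + rng.normal(0, spec.sigma, size=n)
    return np.column_stack([areas, y])


# ---------------------------------------------------------------------------
# Subgranular-zone scenes
# ---------------------------------------------------------------------------


@dataclass
class SgzSpec:
    """Vector SGZ scene with exact laminar ground truth.

    Each soma carries ``primaries_per_soma`` primary dendrites; a fraction
    ``frac_primary_crossing`` of all primaries crosses the mid-GCL line.
    Crossing primaries carry ``secondaries_per_primary`` secondaries each, of
    which ``frac_secondary_crossing`` cross the outer-GCL edge.
    """

    length_um: float = 2000.0
    pixel_size_um: float = 1.0
    n_somata: int = 12
    primaries_per_soma: int = 1
    secondaries_per_primary: int = 2
    frac_primary_crossing: float = 1.0
    frac_secondary_crossing: float = 1.0
    mid_gcl_offset_um: float = 30.0
    outer_gcl_offset_um: float = 60.0
    wobble_um: float = 6.0
    n_brdu: int = 8
    qc_image: bool = False


@dataclass
class SgzTruth:
    a: int
    b: int
    c: int
    density_per_mm: float


def generate_sgz_scene(spec: SgzSpec, seed: int) -> tuple[SgzScene, SgzTruth, ImagePlane | None]:
    """Build a vector SGZ annotation scene plus optional QC raster."""
    rng = rng_for(seed, "sgz")
    px = spec.pixel_size_um
    length_px = spec.length_um / px
    x0 = 20.0
    xs = np.linspace(x0, x0 + length_px, 60)
    y_sgz = 40.0 + spec.outer_gcl_offset_um / px + spec.mid_gcl_offset_um / px
    ys = y_sgz + (spec.wobble_um / px) * np.sin(np.linspace(0, 3 * np.pi, xs.size))
    sgz = np.column_stack([ys, xs])
    mid_y = y_sgz - spec.mid_gcl_offset_um / px
    outer_y = y_sgz - spec.outer_gcl_offset_um / px
    mid = np.array([[mid_y, x0 - 10], [mid_y, x0 + length_px + 10]])
    outer = np.array([[outer_y, x0 - 10], [outer_y, x0 + length_px + 10]])

    # Somata at even arc spacing with jitter, hugging the trace.
    def along(n):
        if n == 0:
            return np.empty((0, 2))
        t = (np.arange(n) + 0.5) / n + rng.uniform(-0.2, 0.2, n) / max(n, 1)
        t = np.clip(t, 0.01, 0.99)
        x = x0 + t * length_px
        y = np.interp(x, xs, ys) + rng.uniform(-3, 3, n)
        return np.column_stack([y, x])

    dcx = along(spec.n_somata)
    brdu = along(spec.n_brdu)

    n_primaries = spec.n_somata * spec.primaries_per_soma
    n_cross_primary = int(round(spec.frac_primary_crossing * n_primaries))
    n_secondaries = n_cross_primary * spec.secondaries_per_primary
    sec_cross_budget = int(round(spec.frac_secondary_crossing * n_secondaries))
    dendrites: list[DendritePath] = []
    k = 0
    sec_seen = 0
    b_true = c_true = 0
    for si in range(spec.n_somata):
        for _ in range(spec.primaries_per_soma):
            crossing = k < n_cross_primary
            k += 1
            soma = dcx[si]
            x_drift = rng.uniform(-8, 8)
            if crossing:
                tip_y = mid_y - rng.uniform(4, 10)
                b_true += 1
            else:
                tip_y = mid_y + rng.uniform(4, 10)  # stops short of mid line
            prim = np.array(
                [soma, [0.5 * (soma[0] + tip_y), soma[1] + 0.5 * x_drift], [tip_y, soma[1] + x_drift]]
            )
            dendrites.append(DendritePath(points=prim, order="primary", soma_index=si))
            if not crossing:
                continue
            for _j in range(spec.secondaries_per_primary):
                sec_seen += 1
                sx = prim[-1][1] + rng.uniform(-10, 10)
                if sec_seen <= sec_cross_budget:
                    sy = outer_y - rng.uniform(4, 10)
                    c_true += 1
                else:
                    sy = outer_y + rng.uniform(4, 10)
                sec = np.array([prim[-1], [sy, sx]])
                dendrites.append(DendritePath(points=sec, order="secondary", soma_index=si))

    scene = SgzScene(
        sgz_polyline=sgz,
        mid_gcl_line=mid,
        outer_gcl_line=outer,
        pixel_size_um=px,
        soma_positions={"DCX": dcx, "BrdU": brdu},
        dendrites=dendrites,
    )
    arc_um = float(np.hypot(*np.diff(sgz, axis=0).T).sum()) * px
    truth = SgzTruth(
        a=spec.n_somata, b=b_true, c=c_true, density_per_mm=spec.n_somata / (arc_um / 1000.0)
    )
    qc = _rasterize_sgz(scene) if spec.qc_image else None
    return scene, truth, qc


def _rasterize_sgz(scene: SgzScene) -> ImagePlane:
    h = int(max(p[:, 0].max() for p in (scene.sgz_polyline,)) + 60)
    w = int(scene.sgz_polyline[:, 1].max() + 40)
    canvas = np.zeros((h, w), dtype=np.uint8)

    def paint_line(pts, value):
        pts = np.asarray(pts)
        for p, qpt in zip(pts[:-1], pts[1:]):
            rr, cc = draw.line(int(p[0]), int(p[1]), int(qpt[0]), int(qpt[1]))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            canvas[rr[keep], cc[keep]] = value

    paint_line(scene.sgz_polyline, 80)
    paint_line(scene.mid_gcl_line, 120)
    paint_line(scene.outer_gcl_line, 160)
    for d in scene.dendrites:
        paint_line(d.points, 200)
    for pts, val in ((scene.soma_positions.get("DCX"), 255), (scene.soma_positions.get("BrdU"), 230)):
        if pts is None:
            continue
        for p in pts:
            rr, cc = draw.disk((p[0], p[1]), 3, shape=canvas.shape)
            canvas[rr, cc] = val
    return ImagePlane(canvas, scene.pixel_size_um, "QC")


# ---------------------------------------------------------------------------
# Signature tables
# ---------------------------------------------------------------------------


@dataclass
class SignatureSpec:
    """Designed-overlap gene fold and perturbagen score tables.

    ``up_regions``/``down_regions`` map a tuple of group names to the number
    of genes differential in exactly that subset of groups (a disjoint Venn
    region).  Default design mirrors the screening tables' structure: 6
    genes up in all three treatment groups, 5 up in A1 and C1 only, 10 down
    in all three.
    """

    groups: tuple[str, ...] = ("A1", "S1", "C1")
    up_regions: dict = field(
        default_factory=lambda: {
            ("A1", "S1", "C1"): 6,
            ("A1", "C1"): 5,
            ("A1", "S1"): 1,
            ("C1", "S1"): 1,
            ("A1",): 4,
            ("C1",): 2,
            ("S1",): 3,
        }
    )
    down_regions: dict = field(
        default_factory=lambda: {
            ("A1", "S1", "C1"): 10,
            ("A1", "C1"): 2,
            ("A1",): 2,
            ("S1",): 1,
            ("C1",): 2,
        }
    )
    n_unchanged: int = 60
    scores_per_group: int = 40


def generate_signature_tables(
    spec: SignatureSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw fold and score tables with known set structure.

    Returns ``(gene_table, score_table, truth)`` where truth holds the
    designed up/down region memberships and per-threshold score counts.
    """
    rng = rng_for(seed, "signatures")
    rows = []
    truth_up: dict[tuple, list[str]] = {}
    truth_down: dict[tuple, list[str]] = {}
    gid = 0

    def next_gene():
        nonlocal gid
        gid += 1
        return f"G{gid:04d}"

    for regions, truth_map, lo, hi in (
        (spec.up_regions, truth_up, 2.0, 4.0),
        (spec.down_regions, truth_down, -4.0, -2.0),
    ):
        for region, count in regions.items():
            members = frozenset(region)
            if not members <= set(spec.groups):
                raise ValueError(f"region {region} outside groups {spec.groups}")
            names = [next_gene() for _ in range(count)]
            truth_map[tuple(sorted(members))] = names
            for gene in names:
                for g in spec.groups:
                    if g in members:
                        fold = rng.uniform(lo, hi)
                    else:
                        fold = rng.uniform(-1.5, 1.5)
                    rows.append({"gene": gene, "group": g, "fold": round(float(fold), 3)})
    for _ in range(spec.n_unchanged):
        gene = next_gene()
        for g in spec.groups:
            rows.append({"gene": gene, "group": g, "fold": round(float(rng.uniform(-1.5, 1.5)), 3)})
    gene_table = pd.DataFrame(rows, columns=["gene", "group", "fold"])

    score_rows = []
    for g in spec.groups:
        for i in range(spec.scores_per_group):
            score_rows.append(
                {
                    "name": f"{g}-pert-{i:03d}",
                    "kind": "PCL" if i % 2 == 0 else "PC",
                    "group": g,
                    "score": round(float(rng.uniform(-100, 100)), 2),
                }
            )
    score_table = pd.DataFrame(score_rows, columns=["name", "kind", "group", "score"])
    truth = {
        "up_regions": truth_up,
        "down_regions": truth_down,
        "score_counts_above": {
            thr: int((score_table["score"] > thr).sum()) for thr in (80.0, 90.0)
        },
    }
    return gene_table, score_table, truth


# ---------------------------------------------------------------------------
# Metabolic cohorts
# ---------------------------------------------------------------------------


@dataclass
class MetabolicGroup:
    """Group-level metabolic parameters.

    OGTT curves rise linearly from baseline to peak over the first 30 min
    and then decay exponentially at rate ``ogtt_decay`` (per 30 min); a
    decay near 0 leaves glucose at peak through 120 min — the impaired
    return-to-baseline of metabolically stressed animals.
    """

    glucose_mean: float
    glucose_sd: float
    insulin_mean: float
    insulin_sd: float
    ogtt_peak: float
    ogtt_decay: float
    body_weight_g: float = float("nan")


@dataclass
class MetabolicSpec:
    groups: dict = field(
        default_factory=lambda: {
            "NCD": MetabolicGroup(7.0, 0.8, 12.0, 2.5, 14.0, 1.2, 26.45),
            "HFSTZ": MetabolicGroup(15.0, 2.0, 25.0, 5.0, 25.0, 0.05, 36.65),
        }
    )
    n_per_group: int = 6
    ogtt_times: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)
    ogtt_noise_sd: float = 0.4


def ogtt_curve(baseline: float, peak: float, decay: float, times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    rise = baseline + (peak - baseline) * np.clip(t / 30.0, 0, 1)
    fall = baseline + (peak - baseline) * np.exp(-decay * np.maximum(t - 30.0, 0) / 30.0)
    return np.where(t <= 30.0, rise, fall)


def generate_metabolic_cohort(spec: MetabolicSpec, seed: int) -> tuple[pd.DataFrame, dict]:
    """Per-animal fasting values and OGTT series with group truth."""
    rng = rng_for(seed, "metabolic")
    rows = []
    aid = 0
    for gname, g in spec.groups.items():
        for _ in range(spec.n_per_group):
            aid += 1
            glucose = max(float(rng.normal(g.glucose_mean, g.glucose_sd)), 0.5)
            insulin = max(float(rng.normal(g.insulin_mean, g.insulin_sd)), 0.1)
            curve = ogtt_curve(glucose, g.ogtt_peak, g.ogtt_decay, spec.ogtt_times)
            curve = np.maximum(curve + rng.normal(0, spec.ogtt_noise_sd, curve.size), 0.5)
            row = {
                "animal_id": f"M{aid:03d}",
                "group": gname,
                "fasting_glucose_mM": round(glucose, 3),
                "fasting_insulin_UmL": round(insulin, 3),
                "body_weight_g": round(float(rng.normal(g.body_weight_g, 1.5)), 2)
                if np.isfinite(g.body_weight_g)
                else np.nan,
            }
            for t, v in zip(spec.ogtt_times, curve):
                row[f"ogtt_{int(t)}"] = round(float(v), 3)
            rows.append(row)
    df = pd.DataFrame(rows)
    truth = {
        gname: {
            "homa_ir_expected": g.glucose_mean * g.insulin_mean / 22.5,
            "glucose_mean": g.glucose_mean,
            "insulin_mean": g.insulin_mean,
            "ogtt_decay": g.ogtt_decay,
            "ogtt_peak": g.ogtt_peak,
        }
        for gname, g in spec.groups.items()
    }
    return df, truth
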