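"""Per-cell form-factor morphometry and group summaries.

The form factor is cell area divided by convex-hull area (a solidity
measure): close to 1 for compact, amoeboid microglia, low for ramified cells
whose processes sweep out a large hull.  Group comparisons use one-way ANOVA
followed by Tukey HSD, with significance at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gliaquant.imaging import ImagePlane, RegionMask, segment

__all__ = ["MorphRecord", "form_factor", "score_scene", "summarize_groups"]


@dataclass
class MorphRecord:
    """One cell's morphometry under a condition label."""

    cell_id: int
    group: str
    area_um2: float
    convex_area_um2: float
    form_factor: float


def form_factor(region: RegionMask) -> float:
    """Cell area divided by convex-hull area; in (0, 1] by construction."""
    return region.area_um2 / region.convex_area_um2


def score_scene(
    image: ImagePlane,
    group: str,
    low: int = 30,
    high: int = 255,
    min_area_px: int = 30,
    exclude_border: bool = True,
) -> list[MorphRecord]:
    """Segment a microglial channel and score each cell's form factor.

    Cells touching the image border are excluded by default: their truncated
    hulls bias the form factor upward.
    """
    regions = segment(image, low=low, high=high, min_area_px=min_area_px)
    records = []
    for reg in regions:
        if exclude_border and reg.touches_border(image.shape):
            continue
        records.append(
            MorphRecord(
                cell_id=reg.label,
                group=group,
                area_um2=reg.area_um2,
                convex_area_um2=reg.convex_area_um2,
                form_factor=form_factor(reg),
            )
        )
    return records


def records_to_frame(records: list[MorphRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "group": r.group,
                "area_um2": r.area_um2,
                "convex_area_um2": r.convex_area_um2,
                "form_factor": r.form_factor,
            }
            for r in records
        ],
        columns=["cell_id", "group", "area_um2", "convex_area_um2", "form_factor"],
    )


def summarize_groups(
    records: list[MorphRecord] | pd.DataFrame,
    value: str = "form_factor",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean/SD/SEM/n plus ANOVA-Tukey pairwise comparisons.

    Returns ``(summary, comparisons)``.  With a single group the comparisons
    frame is empty.  If every group is constant (zero variance) the ANOVA is
    degenerate; comparisons carry a ``degenerate`` flag and NaN p-values.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        return (
            pd.DataFrame(columns=["group", "n", "mean", "sd", "sem"]),
            pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj", "significant", "degenerate"]),
        )
    grp = df.groupby("group")[value]
    summary = pd.DataFrame(
        {
            "group": list(grp.groups),
            "n": grp.count().values,
            "mean": grp.mean().values,
            "sd": grp.std(ddof=1).values,
            "sem": grp.sem(ddof=1).values,
        }
    )
    groups = list(grp.groups)
    comparisons = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj", "significant", "degenerate"])
    if len(groups) >= 2 and (grp.count() >= 2).all():
        samples = [grp.get_group(g).to_numpy() for g in groups]
        pooled_var = np.concatenate([s - s.mean() for s in samples]).var(ddof=len(groups))
        if pooled_var == 0:
            pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
            comparisons = pd.DataFrame(
                {
                    "group1": [p[0] for p in pairs],
                    "group2": [p[1] for p in pairs],
                    "meandiff": [
                        float(grp.get_group(b).mean() - grp.get_group(a).mean()) for a, b in pairs
                    ],
                    "p_adj": np.nan,
                    "significant": False,
                    "degenerate": True,
                }
            )
        else:
            res = stats.tukey_hsd(*samples)
            rows = []
            for i, a in enumerate(groups):
                for j in range(i + 1, len(groups)):
                    b = groups[j]
                    p = float(res.pvalue[i, j])
                    rows.append(
                        {
                            "group1": a,
                            "group2": b,
                            "meandiff": float(samples[j].mean() - samples[i].mean()),
                            "p_adj": p,
                            "significant": p < alpha,
                            "degenerate": False,
                        }
                    )
            comparisons = pd.DataFrame(rows)
    return summary, comparisons


def anova_pvalue(records: list[MorphRecord] | pd.DataFrame, value: str = "form_factor") -> float:
    """One-way ANOVA p-value across groups (NaN if degenerate)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    samples = [s.to_numpy() for _, s in df.groupby("group")[value]]
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        return float(stats.f_oneway(*samples).pvalue)
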