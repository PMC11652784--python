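"""Metabolic indices: HOMA-IR and OGTT area under the curve.

HOMA-IR = fasting glucose [mM] x fasting insulin [U/mL] / 22.5.  Unit
conversion (e.g. insulin in pmol/L) is the caller's responsibility.

The OGTT AUC is the trapezoidal integral of the blood-glucose curve over the
full sampled window (mM·min); an incremental variant subtracts the baseline
(first sampled value) before integrating, clipping at zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["homa_ir", "ogtt_auc", "cohort_frame", "summarize_cohort"]

HOMA_IR_DENOMINATOR = 22.5


def homa_ir(glucose_mM: float, insulin_UmL: float) -> float:
    """Insulin-resistance index: glucose [mM] x insulin [U/mL] / 22.5."""
    if glucose_mM < 0 or insulin_UmL < 0:
        raise ValueError(f"negative input: glucose={glucose_mM}, insulin={insulin_UmL}")
    return glucose_mM * insulin_UmL / HOMA_IR_DENOMINATOR


def ogtt_auc(series, incremental: bool = False) -> float:
    """Trapezoidal AUC (mM·min) of an OGTT time series.

    ``series`` is a sequence of (time_min, glucose_mM) pairs with strictly
    increasing times and at least two points.
    """
    arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (time, glucose) points")
    t, g = arr[:, 0], arr[:, 1]
    if not (np.diff(t) > 0).all():
        raise ValueError("times must be strictly increasing")
    if (g < 0).any():
        raise ValueError("negative glucose value")
    if incremental:
        g = np.maximum(g - g[0], 0.0)
    return float(np.trapezoid(g, t))


def cohort_frame(path_or_df) -> pd.DataFrame:
    """Load/validate a cohort table.

    Expected columns: ``animal_id, group, fasting_glucose_mM,
    fasting_insulin_UmL`` plus OGTT columns named ``ogtt_<time>`` (glucose in
    mM at <time> minutes).  Adds a ``homa_ir`` column.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {"animal_id", "group", "fasting_glucose_mM", "fasting_insulin_UmL"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df = df.copy()
    df["homa_ir"] = [
        homa_ir(g, i) for g, i in zip(df["fasting_glucose_mM"], df["fasting_insulin_UmL"])
    ]
    return df


def _ogtt_columns(df: pd.DataFrame) -> list[tuple[float, str]]:
    cols = []
    for col in df.columns:
        if col.startswith("ogtt_"):
            cols.append((float(col.removeprefix("ogtt_")), col))
    return sorted(cols)


def summarize_cohort(df: pd.DataFrame, incremental: bool = False) -> pd.DataFrame:
    """Per-group mean±SEM of fasting glucose, insulin, HOMA-IR and OGTT AUC."""
    df = cohort_frame(df)
    ogtt_cols = _ogtt_columns(df)
    if ogtt_cols:
        times = [t for t, _ in ogtt_cols]
        df["ogtt_auc"] = [
            ogtt_auc(list(zip(times, row)), incremental=incremental)
            for row in df[[c for _, c in ogtt_cols]].to_numpy()
        ]
    metrics = ["fasting_glucose_mM", "fasting_insulin_UmL", "homa_ir"] + (
        ["ogtt_auc"] if ogtt_cols else []
    )
    out = df.groupby("group")[metrics].agg(["count", "mean", "sem"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()
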