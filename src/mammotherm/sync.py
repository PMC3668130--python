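"""Backwards synchronization of daily series to menses onset.

Menstrual cycles vary mostly in follicular length while the luteal phase is
comparatively constant (12–14 d), so aligning subjects by counting *back*
from menses onset (day +1; the preceding days −1, −2, … −28) synchronizes
the luteal phases across women with 19–39 d cycles. Day 0 does not exist:
for arithmetic spanning onset, label ℓ maps to t = ℓ for ℓ < 0 and
t = ℓ − 1 for ℓ > 0, making −1 and +1 adjacent.

Vascularity is breast minus oral temperature (°C): subtracting the oral
(arterial) temperature removes each woman's hypothalamic set point, so more
negative values mean a cooler, less vascular breast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .simulate import SubjectSeries

CYCLE_DAY_MIN = -28
CYCLE_DAY_MAX = 2


def label_to_t(label: int | np.ndarray) -> np.ndarray:
    """Map cycle-day labels (no day 0) to a contiguous day axis (onset = 0)."""
    label = np.asarray(label)
    if np.any(label == 0):
        raise ValueError("cycle-day label 0 does not exist")
    return np.where(label < 0, label, label - 1)


def t_to_label(t: int | np.ndarray) -> np.ndarray:
    """Inverse of :func:`label_to_t`."""
    t = np.asarray(t)
    return np.where(t < 0, t, t + 1)


def average_breasts(left_C: float | None, right_C: float | None) -> float:
    """Mean of whichever breast temperatures are available; NaN if neither."""
    vals = [v for v in (left_C, right_C) if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return float("nan")
    return float(sum(vals) / len(vals))


def vascularity(breast_C: float, oral_C: float) -> float:
    """Breast-specific temperature: breast minus oral, °C. NaN propagates."""
    return breast_C - oral_C


@dataclass
class SyncedSeries:
    """A subject's series relabeled to cycle days −28…−1, +1, +2.

    ``data`` columns: ``cycle_day`` (never 0), ``breast_C`` (L/R average),
    ``oral_C``, ``vascularity_C`` (= breast − oral), ``progesterone_pM``.
    """

    subject_id: str
    group: str
    menses_onset_date: date
    data: pd.DataFrame


def sync_backwards(series: SubjectSeries) -> SyncedSeries:
    """Relabel a subject's days relative to menses onset and compute vascularity.

    The day of onset becomes +1, the day before −1, back to −28 (earlier
    days dropped); the day after onset is +2 (later days dropped).
    """
    df = series.data
    offsets = np.array([(d - series.menses_onset_date).days for d in df["date"]])
    if not np.any(offsets < 0):
        raise ValueError(
            f"subject {series.subject_id}: no records before menses onset; nothing to synchronize"
        )
    cycle_day = np.where(offsets < 0, offsets, offsets + 1)
    keep = (cycle_day >= CYCLE_DAY_MIN) & (cycle_day <= CYCLE_DAY_MAX)
    sub = df.loc[keep].copy()
    sub["cycle_day"] = cycle_day[keep]
    breast = np.array(
        [average_breasts(l, r) for l, r in zip(sub["breast_left_C"], sub["breast_right_C"])]
    )
    out = pd.DataFrame(
        {
            "cycle_day": sub["cycle_day"].to_numpy(),
            "breast_C": breast,
            "oral_C": sub["oral_C"].to_numpy(dtype=float),
            "vascularity_C": breast - sub["oral_C"].to_numpy(dtype=float),
            "progesterone_pM": sub["progesterone_pM"].to_numpy(dtype=float)
            if "progesterone_pM" in sub
            else np.nan,
        }
    ).sort_values("cycle_day", kind="stable", ignore_index=True)
    return SyncedSeries(series.subject_id, series.group, series.menses_onset_date, out)


def cycle_day_to_date(onset: date, cycle_day: int) -> date:
    """Recover the calendar date of a cycle-day label from the onset date."""
    if cycle_day == 0:
        raise ValueError("cycle-day label 0 does not exist")
    offset = cycle_day if cycle_day < 0 else cycle_day - 1
    return onset + timedelta(days=int(offset))


def synced_to_frame(synced: list[SyncedSeries]) -> pd.DataFrame:
    """Stack synchronized series into one tidy frame."""
    frames = []
    for s in synced:
        df = s.data.copy()
        df.insert(0, "subject_id", s.subject_id)
        df.insert(1, "group", s.group)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def group_daily_means(
    synced: list[SyncedSeries] | pd.DataFrame,
    group: str,
    variable: str = "vascularity_C",
) -> pd.DataFrame:
    """Cross-subject mean, SE and n of ``variable`` on each cycle day.

    Per-day n varies when subjects miss days; days with no contributing
    subject are absent from the result.
    """
    df = synced if isinstance(synced, pd.DataFrame) else synced_to_frame(synced)
    sub = df[(df["group"] == group) & df[variable].notna()]
    if sub.empty:
        raise ValueError(f"group {group!r} has no usable observations for {variable!r}")
    g = sub.groupby("cycle_day")[variable]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out[["cycle_day", "mean", "se", "n"]]


def moving_average_3(daily: dict[int, float] | pd.Series) -> pd.Series:
    """3-day centered moving average over cycle days (−1 and +1 adjacent).

    The window shrinks at the series ends and skips absent days: each
    smoothed value averages the day itself with whichever immediate
    neighbors (on the gapless mapped axis) are present.
    """
    if isinstance(daily, dict):
        daily = pd.Series(daily)
    labels = daily.index.to_numpy(dtype=int)
    t = label_to_t(labels)
    lookup = dict(zip(t, daily.to_numpy(dtype=float)))
    smoothed = []
    for ti in t:
        window = [lookup[u] for u in (ti - 1, ti, ti + 1) if u in lookup and not math.isnan(lookup[u])]
        smoothed.append(float(np.mean(window)) if window else float("nan"))
    return pd.Series(smoothed, index=labels, name=getattr(daily, "name", None))
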