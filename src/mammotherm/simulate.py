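"""Synthetic-cohort generator.

Generates subject-level daily breast/oral/progesterone series — and
optionally the per-minute evening recordings they summarize — with the
statistical structure the downstream analysis assumes: a cosine-shaped
mammary-vascularity rhythm anchored to menses onset, a biphasic basal
body-temperature step after ovulation, a mid-luteal progesterone bump,
uniform-at-random missing subject-days, and tumour pathology records for
the cancer groups.

The group luteal level parameter is *defined* as the noise-free mean of
vascularity (breast − oral, °C) over cycle days −11…−1, so the generator is
calibrated to its configured group levels exactly, whatever cycle length a
subject draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Any

import numpy as np
import pandas as pd

from .config import GROUPS, SimConfig
from .plateau import MinuteTrace


@dataclass
class SubjectSeries:
    """One subject's daily measurements across one studied menstrual cycle.

    ``data`` has one row per calendar day with columns ``date``,
    ``cycle_day_raw`` (log-sheet day count, +1 = first day of menses),
    ``breast_left_C``, ``breast_right_C``, ``oral_C``, ``progesterone_pM``
    and ``missing``. ``truth`` carries the generator's ground truth for
    parameter-recovery checks; it is absent for series read from files.
    """

    subject_id: str
    group: str
    menses_onset_date: date
    data: pd.DataFrame
    truth: dict[str, Any] = field(default_factory=dict)


@dataclass
class Cohort:
    """A simulated study cohort: subjects, pathology and provenance."""

    subjects: list[SubjectSeries]
    pathology: pd.DataFrame
    config: SimConfig

    def to_daily_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-subject-day frame (the daily-log CSV schema)."""
        frames = []
        for s in self.subjects:
            df = s.data.copy()
            df.insert(0, "subject_id", s.subject_id)
            df.insert(1, "group", s.group)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out = out.rename(columns={"date": "calendar_date", "missing": "missing_flag"})
        return out


def _rhythm_shape(t: np.ndarray, peak_t: float, period: float, asymmetric: bool) -> np.ndarray:
    """Unit rhythm shape on the mapped day axis, peaking at ``peak_t``.

    Either a pure cosine of the given period or a saw-tooth variant with a
    slow three-quarter-period rise and fast quarter-period fall.
    """
    if not asymmetric:
        return np.cos(2.0 * np.pi * (t - peak_t) / period)
    x = np.mod(t - peak_t, period) / period  # phase in [0, 1), 0 = peak
    fall = 0.25
    out = np.where(x < fall, 1.0 - 2.0 * x / fall, -1.0 + 2.0 * (x - fall) / (1.0 - fall))
    return out


def simulate_subject(
    config: SimConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "S000",
    onset_date: date | None = None,
) -> SubjectSeries:
    """Simulate one subject's cycle of daily values.

    Breast temperature is the subject's set point plus the basal (oral)
    profile plus a vascularity rhythm with the group's acrophase and luteal
    level; left and right breasts differ only by measurement noise. Oral
    temperature steps up by ``oral_rise`` after ovulation. Progesterone is a
    smooth bump rising after day −12 and peaking mid-luteally.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if onset_date is None:
        onset_date = config.start_date + timedelta(days=40)

    cycle_len = int(rng.integers(config.cycle_length_range[0], config.cycle_length_range[1] + 1))
    luteal_len = int(rng.integers(config.luteal_length_range[0], config.luteal_length_range[1] + 1))

    # Mapped day axis: −L…−1 pre-onset, 0 = onset day (+1), 1 = day +2.
    t = np.arange(-cycle_len, 2, dtype=float)
    raw_day = np.where(t < 0, t + cycle_len + 1, t + 1).astype(int)
    dates = [onset_date + timedelta(days=int(ti)) for ti in t]

    amp = config.breast_rise / 2.0
    acro = config.group_acrophase[group]  # days after onset, [0, 28)
    peak_t = acro - 28.0  # mapped axis, in (−28, 0]
    shape = _rhythm_shape(t, peak_t, float(cycle_len), config.asymmetric)
    luteal_days = np.arange(-11.0, 0.0)
    luteal_shape_mean = float(
        np.mean(_rhythm_shape(luteal_days, peak_t, float(cycle_len), config.asymmetric))
    )
    level = config.group_luteal_mean[group] + rng.normal(0.0, config.subject_level_sd) if config.subject_level_sd > 0 else config.group_luteal_mean[group]
    mesor = level - amp * luteal_shape_mean
    vascularity_true = mesor + amp * shape

    set_point = rng.uniform(-config.baseline_spread / 2.0, config.baseline_spread / 2.0)
    oral_true = config.oral_basal + set_point + np.where(t >= -luteal_len, config.oral_rise, 0.0)
    breast_true = oral_true + vascularity_true

    sd = config.daily_noise_sd
    n = len(t)
    oral = oral_true + (rng.normal(0.0, sd, n) if sd > 0 else 0.0)
    left = breast_true + (rng.normal(0.0, sd, n) if sd > 0 else 0.0)
    right = breast_true + (rng.normal(0.0, sd, n) if sd > 0 else 0.0)

    prog_true = config.progesterone_baseline + (
        config.progesterone_peak - config.progesterone_baseline
    ) * np.exp(-((t + 6.0) ** 2) / (2.0 * 3.0**2))
    psd = config.progesterone_noise_sd
    prog = np.clip(prog_true + (rng.normal(0.0, psd, n) if psd > 0 else 0.0), 0.0, None)

    missing = rng.random(n) < config.missing_fraction if config.missing_fraction > 0 else np.zeros(n, bool)

    df = pd.DataFrame(
        {
            "date": dates,
            "cycle_day_raw": raw_day,
            "breast_left_C": np.where(missing, np.nan, left),
            "breast_right_C": np.where(missing, np.nan, right),
            "oral_C": np.where(missing, np.nan, oral),
            "progesterone_pM": np.where(missing, np.nan, prog),
            "missing": missing,
        }
    )
    truth = {
        "cycle_length": cycle_len,
        "luteal_length": luteal_len,
        "acrophase_days_after_onset": acro,
        "luteal_mean": level,
        "set_point": set_point,
        "breast_true": breast_true,
        "vascularity_true": vascularity_true,
        "mapped_day": t,
    }
    return SubjectSeries(subject_id, group, onset_date, df, truth)


def _draw_pathology(rng: np.random.Generator, subject_id: str, group: str) -> dict[str, Any]:
    age = float(np.clip(rng.normal(39.0, 6.0), 26.0, 56.0))
    in_situ = bool(group == "survivor" and rng.random() < 3.0 / 18.0)
    size_mm = int(np.clip(round(rng.lognormal(np.log(22.0), 0.6)), 5, 120))
    grade = int(rng.choice([1, 2, 3], p=[0.1, 0.3, 0.6]))
    if group == "survivor":
        nodes = int(rng.random() < 1.0 / 18.0)
        survival_y = float(rng.uniform(15.0, 28.0))
    else:
        nodes = int(rng.geometric(0.5) - 1)  # mean 1.0, skewed to small counts
        survival_y = float(np.clip(rng.lognormal(np.log(6.2), 0.9), 0.5, 23.0))
    return {
        "subject_id": subject_id,
        "group": group,
        "age_at_surgery_y": round(age, 2),
        "survival_y": round(survival_y, 2),
        "size_mm": np.nan if in_situ else size_mm,
        "grade": np.nan if in_situ else grade,
        "nodes": nodes,
        "in_situ": in_situ,
    }


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate ``n_per_group`` subjects per group, deterministically in seed."""
    if config.n_per_group <= 0:
        raise ValueError(f"n_per_group must be positive, got {config.n_per_group}")
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectSeries] = []
    pathology_rows: list[dict[str, Any]] = []
    idx = 0
    for group in GROUPS:
        for _ in range(config.n_per_group):
            sid = f"S{idx:03d}"
            onset = config.start_date + timedelta(days=40 + 3 * idx)
            subjects.append(simulate_subject(config, group, rng, sid, onset))
            if group in ("survivor", "non-survivor"):
                pathology_rows.append(_draw_pathology(rng, sid, group))
            idx += 1
    pathology = pd.DataFrame(pathology_rows) if pathology_rows else pd.DataFrame(
        columns=["subject_id", "group", "age_at_surgery_y", "survival_y", "size_mm", "grade", "nodes", "in_situ"]
    )
    return Cohort(subjects, pathology, config)


def emit_minute_traces(
    series: SubjectSeries,
    config: SimConfig,
    rng: np.random.Generator,
    duration_min: int | None = None,
) -> list[MinuteTrace]:
    """Per-minute evening recordings for each recorded (non-missing) day.

    Each trace approaches that day's true deep-breast temperature as a
    saturating exponential from ``trace_start_C`` with time constant
    ``trace_tau_min``, sampled once per minute, plus Gaussian noise. The
    daily plateau value is recoverable by plateau extraction.
    """
    duration = config.trace_duration_min if duration_min is None else duration_min
    if duration < 30:
        raise ValueError(f"trace duration must be at least 30 minutes, got {duration}")
    minutes = np.arange(duration, dtype=float)
    decay = np.exp(-minutes / config.trace_tau_min)
    traces: list[MinuteTrace] = []
    for _, row in series.data.iterrows():
        if row["missing"]:
            continue
        for side, col in (("left", "breast_left_C"), ("right", "breast_right_C")):
            plateau = float(row[col])
            temps = plateau + (config.trace_start_C - plateau) * decay
            if config.trace_noise_sd > 0:
                temps = temps + rng.normal(0.0, config.trace_noise_sd, duration)
            traces.append(
                MinuteTrace(
                    minute_index=np.arange(duration),
                    temp_C=temps,
                    subject_id=series.subject_id,
                    date=row["date"],
                    side=side,
                )
            )
    return traces
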