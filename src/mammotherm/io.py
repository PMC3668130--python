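"""CSV readers and writers for the pipeline's interchange formats.

One interchange format throughout: CSV with ISO-8601 dates and °C
temperatures. The daily-log schema (one row per subject-day) is the same
whether written by the simulator or transcribed from paper log sheets:

    subject_id, group, calendar_date, cycle_day_raw, breast_left_C,
    breast_right_C, oral_C, progesterone_pM, missing_flag

Rows violating physiological bounds are quarantined with a reason rather
than silently dropped or silently used.
"""

from __future__ import annotations

import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .plateau import PHYSIO_MAX_C, PHYSIO_MIN_C, MinuteTrace
from .simulate import Cohort, SubjectSeries

logger = logging.getLogger("mammotherm")

DAILY_COLUMNS = [
    "subject_id",
    "group",
    "calendar_date",
    "cycle_day_raw",
    "breast_left_C",
    "breast_right_C",
    "oral_C",
    "progesterone_pM",
    "missing_flag",
]

TRACE_COLUMNS = ["subject_id", "date", "side", "minute_index", "temp_C"]


def write_daily_log(cohort: Cohort, path: str | Path) -> pd.DataFrame:
    """Write a cohort's daily log CSV; returns the frame written."""
    df = cohort.to_daily_frame()
    df.to_csv(path, index=False)
    logger.info("wrote daily log: %d rows -> %s", len(df), path)
    return df


def read_daily_log(path: str | Path) -> tuple[list[SubjectSeries], pd.DataFrame]:
    """Read and validate a daily-log CSV into per-subject series.

    Menses onset is taken from a ``menses_onset_date`` column when present,
    otherwise inferred as the date of each subject's *last* day with
    ``cycle_day_raw == 1`` (+1 marks the first day of a menses; the last
    such day terminates the studied cycle).

    Returns
    -------
    (series, quarantined)
        Validated subject series, and a frame of rows that failed
        physiological bounds with a ``quarantine_reason`` column.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "calendar_date", "breast_left_C", "breast_right_C", "oral_C"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"daily log {path} missing required columns: {sorted(missing_cols)}")
    df["calendar_date"] = pd.to_datetime(df["calendar_date"]).dt.date
    if df.duplicated(subset=["subject_id", "calendar_date"]).any():
        dups = df[df.duplicated(subset=["subject_id", "calendar_date"], keep=False)]
        raise ValueError(f"duplicate subject-date rows in {path}: {dups['subject_id'].unique().tolist()}")
    if "missing_flag" not in df.columns:
        df["missing_flag"] = df[["breast_left_C", "breast_right_C", "oral_C"]].isna().all(axis=1)
    if "group" not in df.columns:
        df["group"] = "control"
    if "progesterone_pM" not in df.columns:
        df["progesterone_pM"] = np.nan

    reasons = []
    for _, r in df.iterrows():
        reason = ""
        if not r["missing_flag"]:
            for col in ("breast_left_C", "breast_right_C", "oral_C"):
                v = r[col]
                if pd.notna(v) and not (PHYSIO_MIN_C <= v <= PHYSIO_MAX_C):
                    reason = f"{col}={v} outside [{PHYSIO_MIN_C}, {PHYSIO_MAX_C}] C"
                    break
            if not reason and pd.notna(r["progesterone_pM"]) and r["progesterone_pM"] < 0:
                reason = f"progesterone_pM={r['progesterone_pM']} negative"
        reasons.append(reason)
    df = df.assign(quarantine_reason=reasons)
    quarantined = df[df["quarantine_reason"] != ""].copy()
    clean = df[df["quarantine_reason"] == ""].drop(columns="quarantine_reason")
    for _, row in quarantined.iterrows():
        logger.debug("quarantined %s %s: %s", row["subject_id"], row["calendar_date"], row["quarantine_reason"])

    series: list[SubjectSeries] = []
    for sid, sub in clean.groupby("subject_id", sort=False):
        sub = sub.sort_values("calendar_date")
        if "menses_onset_date" in sub.columns and sub["menses_onset_date"].notna().any():
            onset = pd.to_datetime(sub["menses_onset_date"].dropna().iloc[0]).date()
        elif "cycle_day_raw" in sub.columns and (sub["cycle_day_raw"] == 1).any():
            onset = sub.loc[sub["cycle_day_raw"] == 1, "calendar_date"].iloc[-1]
        else:
            raise ValueError(f"subject {sid}: no menses onset (no +1 day and no menses_onset_date column)")
        data = pd.DataFrame(
            {
                "date": sub["calendar_date"].to_numpy(),
                "cycle_day_raw": sub["cycle_day_raw"].to_numpy() if "cycle_day_raw" in sub.columns else np.nan,
                "breast_left_C": sub["breast_left_C"].to_numpy(dtype=float),
                "breast_right_C": sub["breast_right_C"].to_numpy(dtype=float),
                "oral_C": sub["oral_C"].to_numpy(dtype=float),
                "progesterone_pM": sub["progesterone_pM"].to_numpy(dtype=float),
                "missing": sub["missing_flag"].to_numpy(dtype=bool),
            }
        )
        series.append(SubjectSeries(str(sid), str(sub["group"].iloc[0]), onset, data))
    logger.info("read daily log %s: %d subjects, %d rows, %d quarantined", path, len(series), len(clean), len(quarantined))
    return series, quarantined.drop(columns=[], errors="ignore")


def write_traces(traces: list[MinuteTrace], path: str | Path) -> None:
    """Write per-minute traces as one long CSV (subject, date, side, minute, °C)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "date": tr.date,
                    "side": tr.side,
                    "minute_index": tr.minute_index,
                    "temp_C": tr.temp_C,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACE_COLUMNS)
    out.to_csv(path, index=False)
    logger.info("wrote %d traces (%d rows) -> %s", len(traces), len(out), path)


def read_traces(path: str | Path) -> list[MinuteTrace]:
    """Read a per-minute trace CSV back into :class:`MinuteTrace` objects."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    traces = []
    for (sid, day, side), sub in df.groupby(["subject_id", "date", "side"], sort=False):
        sub = sub.sort_values("minute_index")
        traces.append(
            MinuteTrace(
                minute_index=sub["minute_index"].to_numpy(),
                temp_C=sub["temp_C"].to_numpy(dtype=float),
                subject_id=str(sid),
                date=day,
                side=str(side),
            )
        )
    return traces


def plateaus_to_daily_log(plateaus: pd.DataFrame, daily: pd.DataFrame) -> pd.DataFrame:
    """Replace the daily log's breast columns with extracted plateau values.

    ``plateaus`` is the frame produced by
    :meth:`mammotherm.plateau.PlateauExtractor.transform`; rows without an
    ``ok`` quality flag contribute nothing.
    """
    ok = plateaus[plateaus["quality_flag"] == "ok"]
    wide = ok.pivot_table(index=["subject_id", "date"], columns="side", values="plateau_C")
    wide = wide.rename(columns={"left": "breast_left_C", "right": "breast_right_C"})
    out = daily.copy()
    out["calendar_date"] = pd.to_datetime(out["calendar_date"]).map(lambda d: d.date() if hasattr(d, "date") else d)
    merged = out.drop(columns=["breast_left_C", "breast_right_C"]).merge(
        wide.reset_index(),
        left_on=["subject_id", "calendar_date"],
        right_on=["subject_id", "date"],
        how="left",
    )
    return merged.drop(columns=["date"])


def parse_iso_date(s: str) -> date:
    return date.fromisoformat(s)
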