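"""Peak-plateau extraction from per-minute evening breast recordings.

A surface sensor held against the breast equilibrates with the deep tissue
temperature; once heat flow stabilizes, the trace flattens at the deep
temperature (the same principle as non-invasive deep-body thermometry). The
detector smooths the trace, discards a preliminary warm-up span, finds the
maximal runs where the per-minute slope magnitude stays within tolerance
for at least a minimum duration, and reports the level of the warmest such
run — the "peak plateau" temperature for that day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

PHYSIO_MIN_C = 25.0
PHYSIO_MAX_C = 42.0


@dataclass
class MinuteTrace:
    """One evening's per-minute temperature recording for one breast."""

    minute_index: np.ndarray
    temp_C: np.ndarray
    subject_id: str = ""
    date: Any = None
    side: str = ""

    def __post_init__(self) -> None:
        self.minute_index = np.asarray(self.minute_index, dtype=int)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        if self.minute_index.shape != self.temp_C.shape:
            raise ValueError("minute_index and temp_C must have equal length")
        if self.minute_index.size and np.any(np.diff(self.minute_index) <= 0):
            raise ValueError("minute indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.minute_index.size)


@dataclass
class PlateauResult:
    """Detected plateau: its level, window, and a quality flag."""

    plateau_C: float
    window_start: int  # minute index
    window_end: int  # minute index, inclusive
    quality_flag: str  # "ok" | "short-trace" | "no-plateau"
    n_flagged_samples: int = 0
    subject_id: str = ""
    date: Any = None
    side: str = ""


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a window shrinking at the edges."""
    if window <= 1 or values.size <= 1:
        return values.astype(float)
    half = (window - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    n = values.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def extract_plateau(
    trace: MinuteTrace,
    smooth_window: int = 5,
    slope_tol: float = 0.02,
    min_duration: int = 10,
    discard_initial: int = 30,
) -> PlateauResult:
    """Detect the day's peak plateau temperature in a per-minute trace.

    Parameters
    ----------
    trace
        The per-minute recording. Samples outside physiological bounds
        (25–42 °C) are flagged and excluded, never used silently.
    smooth_window
        Width (samples) of the centered moving average applied before
        slope evaluation.
    slope_tol
        Maximum smoothed slope magnitude, °C per minute, inside a plateau.
    min_duration
        Minimum plateau span in minutes.
    discard_initial
        Preliminary warm-up span (minutes from the start of recording)
        excluded from detection.

    Returns
    -------
    PlateauResult
        The highest-level maximal flat run (ties broken toward the latest
        window). If no run qualifies, the maximum of the smoothed trace is
        reported with ``quality_flag="no-plateau"``; traces too short after
        the warm-up span yield ``quality_flag="short-trace"`` and NaN.
    """
    if smooth_window <= 0 or slope_tol <= 0 or min_duration <= 0:
        raise ValueError("smooth_window, slope_tol and min_duration must be positive")
    meta = dict(subject_id=trace.subject_id, date=trace.date, side=trace.side)

    if len(trace) == 0:
        return PlateauResult(np.nan, -1, -1, "short-trace", 0, **meta)
    in_bounds = (trace.temp_C >= PHYSIO_MIN_C) & (trace.temp_C <= PHYSIO_MAX_C)
    n_flagged = int(np.sum(~in_bounds))
    keep = in_bounds & (trace.minute_index >= trace.minute_index[0] + discard_initial)
    minutes = trace.minute_index[keep]
    temps = trace.temp_C[keep]

    if minutes.size < 2 or minutes[-1] - minutes[0] < min_duration:
        return PlateauResult(np.nan, -1, -1, "short-trace", n_flagged, **meta)

    smoothed = _smooth(temps, smooth_window)
    slopes = np.diff(smoothed) / np.diff(minutes)
    ok = np.abs(slopes) <= slope_tol

    # Maximal runs of consecutive within-tolerance slopes; a run over slope
    # indices i..j covers samples i..j+1.
    candidates: list[tuple[float, int, int]] = []  # (mean level, start, end) sample idx
    i = 0
    m = ok.size
    while i < m:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and ok[j + 1]:
            j += 1
        start, end = i, j + 1
        if minutes[end] - minutes[start] >= min_duration:
            level = float(np.mean(smoothed[start : end + 1]))
            candidates.append((level, start, end))
        i = j + 1

    if not candidates:
        k = int(np.argmax(smoothed))
        return PlateauResult(float(smoothed[k]), int(minutes[k]), int(minutes[k]), "no-plateau", n_flagged, **meta)

    # highest level, then latest window
    level, start, end = max(candidates, key=lambda c: (c[0], c[1]))
    return PlateauResult(level, int(minutes[start]), int(minutes[end]), "ok", n_flagged, **meta)


class PlateauExtractor(BaseEstimator):
    """Transformer-style wrapper around :func:`extract_plateau`.

    Stateless: ``fit`` only validates parameters, ``transform`` maps a
    sequence of :class:`MinuteTrace` to a tidy result frame with one row per
    trace (subject, date, side, plateau_C, window, quality flag).
    """

    def __init__(
        self,
        smooth_window: int = 5,
        slope_tol: float = 0.02,
        min_duration: int = 10,
        discard_initial: int = 30,
    ):
        self.smooth_window = smooth_window
        self.slope_tol = slope_tol
        self.min_duration = min_duration
        self.discard_initial = discard_initial

    def fit(self, X: Iterable[MinuteTrace] | None = None, y: Any = None) -> "PlateauExtractor":
        if self.smooth_window <= 0 or self.slope_tol <= 0 or self.min_duration <= 0:
            raise ValueError("smooth_window, slope_tol and min_duration must be positive")
        self.n_features_in_ = 1
        return self

    def extract(self, trace: MinuteTrace) -> PlateauResult:
        return extract_plateau(
            trace,
            smooth_window=self.smooth_window,
            slope_tol=self.slope_tol,
            min_duration=self.min_duration,
            discard_initial=self.discard_initial,
        )

    def transform(self, X: Iterable[MinuteTrace]) -> pd.DataFrame:
        rows = []
        for trace in X:
            r = self.extract(trace)
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "date": r.date,
                    "side": r.side,
                    "plateau_C": r.plateau_C,
                    "window_start": r.window_start,
                    "window_end": r.window_end,
                    "quality_flag": r.quality_flag,
                    "n_flagged_samples": r.n_flagged_samples,
                }
            )
        return pd.DataFrame(rows)

    def fit_transform(self, X: Iterable[MinuteTrace], y: Any = None) -> pd.DataFrame:
        return self.fit(X).transform(X)
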