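import numpy as np
import pytest

from mammotherm.config import SimConfig
from mammotherm.plateau import MinuteTrace


@pytest.fixture
def noise_free_config() -> SimConfig:
    """All stochastic components off: pure group-level physiology."""
    return SimConfig(
        daily_noise_sd=0.0,
        subject_level_sd=0.0,
        missing_fraction=0.0,
        progesterone_noise_sd=0.0,
        trace_noise_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def saturating_trace(
    plateau: float = 34.6,
    start: float = 32.0,
    tau: float = 8.0,
    duration: int = 90,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MinuteTrace:
    minutes = np.arange(duration)
    temps = plateau + (start - plateau) * np.exp(-minutes / tau)
    if noise_sd > 0:
        temps = temps + (rng or np.random.default_rng(0)).normal(0, noise_sd, duration)
    return MinuteTrace(minutes, temps)


def plateau_oracle(
    trace: MinuteTrace,
    smooth_window: int = 5,
    slope_tol: float = 0.02,
    min_duration: int = 10,
    discard_initial: int = 30,
):
    """Exhaustive window-enumeration reference for plateau detection.

    Enumerates every candidate window, checks the slope criterion sample by
    sample, keeps only maximal (non-extendable) windows of sufficient
    duration and returns (level, start_minute, end_minute) of the highest
    mean level, ties to the latest window — independently of the run-scan
    implementation, including an explicit-loop moving average.
    """
    keep = (
        (trace.temp_C >= 25.0)
        & (trace.temp_C <= 42.0)
        & (trace.minute_index >= trace.minute_index[0] + discard_initial)
    )
    minutes = trace.minute_index[keep]
    temps = trace.temp_C[keep]
    n = len(temps)
    if n < 2 or minutes[-1] - minutes[0] < min_duration:
        return None
    half = (smooth_window - 1) // 2
    smoothed = np.array(
        [np.mean(temps[max(0, i - half) : min(n - 1, i + half) + 1]) for i in range(n)]
    )
    ok = [
        abs((smoothed[i + 1] - smoothed[i]) / (minutes[i + 1] - minutes[i])) <= slope_tol
        for i in range(n - 1)
    ]
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            if not all(ok[i:j]):
                continue
            if i > 0 and ok[i - 1]:
                continue  # extendable left
            if j < n - 1 and ok[j]:
                continue  # extendable right
            if minutes[j] - minutes[i] < min_duration:
                continue
            level = float(np.mean(smoothed[i : j + 1]))
            key = (level, i)
            if best is None or key > best[0]:
                best = (key, int(minutes[i]), int(minutes[j]))
    if best is None:
        return ("no-plateau", float(np.max(smoothed)))
    return ("ok", best[0][0], best[1], best[2])
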