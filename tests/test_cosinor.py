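"""Cosinor rhythmometry: exact recovery, oracle optimality, equivariance."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammotherm.cosinor import (
    CosinorRegression,
    acrophase_diff,
    cosinor_fit,
    fit_group_rhythms,
)
from mammotherm.sync import SyncedSeries


def cosine(t, mesor, amp, peak, tau=28.0):
    return mesor + amp * np.cos(2 * np.pi * (t - peak) / tau)


def grid_search_rss(t, y, tau=28.0, n_m=61, n_a=61, n_phi=113):
    """Brute-force best RSS over an (M, A, phi) grid — independent oracle."""
    m_grid = np.linspace(y.mean() - 2 * y.std(), y.mean() + 2 * y.std(), n_m)
    a_grid = np.linspace(0, 3 * y.std(), n_a)
    phi_grid = np.linspace(0, tau, n_phi, endpoint=False)
    cos_term = np.cos(2 * np.pi * (t[None, :] - phi_grid[:, None]) / tau)  # (phi, t)
    best = np.inf
    for a in a_grid:
        pred = a * cos_term  # (phi, t)
        resid0 = y[None, :] - pred  # (phi, t)
        for m in m_grid:
            rss = np.sum((resid0 - m) ** 2, axis=1).min()
            best = min(best, rss)
    return best


def test_exact_recovery_noise_free():
    """A pure cosine is recovered to at least 10 significant digits."""
    t = np.arange(28.0)
    fit = cosinor_fit(t, cosine(t, -1.6, 0.35, 21.5))
    assert fit.mesor == pytest.approx(-1.6, rel=1e-10)
    assert fit.amplitude == pytest.approx(0.35, rel=1e-10)
    assert fit.acrophase_days_after_onset == pytest.approx(21.5, rel=1e-10)
    assert fit.p_zero_amplitude == 0.0
    assert fit.amplitude == pytest.approx(np.hypot(fit.beta_cos, fit.beta_sin))


def test_model_peaks_at_acrophase():
    t = np.linspace(0, 28, 2000)
    est = CosinorRegression().fit(np.arange(28.0), cosine(np.arange(28.0), 0.5, 1.2, 9.7))
    pred = est.predict(t)
    assert t[np.argmax(pred)] == pytest.approx(est.acrophase_, abs=0.02)


def test_constant_series_degenerate():
    fit = cosinor_fit(np.arange(10.0), np.full(10, 3.25))
    assert fit.mesor == pytest.approx(3.25)
    assert fit.amplitude == pytest.approx(0.0, abs=1e-12)
    assert fit.p_zero_amplitude == 1.0


def test_insufficient_or_collinear_design_rejected():
    with pytest.raises(ValueError, match="at least 4"):
        cosinor_fit([0, 1, 2], [1, 2, 3])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        cosinor_fit([0, 28, 56, 84], [1, 2, 3, 4])  # all equal mod tau


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_least_squares_beats_grid_oracle(seed):
    """OLS cosinor RSS never exceeds the brute-force grid-search RSS."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 31))
    t = np.sort(rng.uniform(-28, 2, n))
    y = rng.normal(0, 1, n)
    fit = cosinor_fit(t, y)
    assert fit.rss <= grid_search_rss(t, y) + 1e-9


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.integers(0, 2**31 - 1),
    st.floats(-2, 2),
    st.floats(-10, 10),
)
def test_shift_equivariance(seed, value_shift, time_shift):
    """Value shifts move only the MESOR; time shifts move only the acrophase."""
    rng = np.random.default_rng(seed)
    t = np.arange(-27.0, 2.0)
    y = cosine(t, -1.5, 0.4, 20.0) + rng.normal(0, 0.1, t.size)
    base = cosinor_fit(t, y)
    shifted_v = cosinor_fit(t, y + value_shift)
    assert shifted_v.mesor - base.mesor == pytest.approx(value_shift, abs=1e-9)
    assert shifted_v.amplitude == pytest.approx(base.amplitude, abs=1e-9)
    assert shifted_v.acrophase_days_after_onset == pytest.approx(
        base.acrophase_days_after_onset, abs=1e-9
    )
    shifted_t = cosinor_fit(t + time_shift, y)
    assert acrophase_diff(
        shifted_t.acrophase_days_after_onset, base.acrophase_days_after_onset
    ) == pytest.approx(acrophase_diff(time_shift, 0.0), abs=1e-9)


@pytest.mark.parametrize("sigma", [0.0, 0.05, 0.2])
def test_amplitude_estimate_unbiased_in_noise_limit(sigma):
    """Mean amplitude bias over replicates shrinks with the noise level."""
    rng = np.random.default_rng(99)
    t = np.arange(28.0)
    amps = []
    for _ in range(200):
        y = cosine(t, -1.6, 0.35, 21.5) + rng.normal(0, sigma, t.size)
        amps.append(cosinor_fit(t, y).amplitude)
    bias = abs(np.mean(amps) - 0.35)
    assert bias < max(2e-12, 0.3 * sigma**2 / 0.35 + 3 * sigma / np.sqrt(2 * 200))


@pytest.mark.parametrize(
    "a, b, expected",
    [(21.5, 27.4, -5.9), (20.1, 27.4, -7.3), (3.0, 3.0, 0.0), (1.0, 27.0, 2.0)],
)
def test_acrophase_diff(a, b, expected):
    assert acrophase_diff(a, b) == pytest.approx(expected)


def _synced(sid, group, days, values):
    return SyncedSeries(
        sid,
        group,
        date(2024, 1, 20),
        pd.DataFrame(
            {
                "cycle_day": days,
                "breast_C": np.nan,
                "oral_C": np.nan,
                "vascularity_C": values,
                "progesterone_pM": np.nan,
            }
        ),
    )


def test_single_subject_group_fit_equals_subject_fit():
    days = list(range(-14, 0))
    t = np.array(days, dtype=float)
    s = _synced("solo", "control", days, cosine(t, -1.4, 0.3, 27.0) + 0.01 * np.sin(t))
    group_fits, subject_fits = fit_group_rhythms([s])
    solo = subject_fits.iloc[0]
    assert group_fits["control"].mesor == pytest.approx(solo["mesor"])
    assert group_fits["control"].acrophase_days_after_onset == pytest.approx(
        solo["acrophase_days_after_onset"]
    )


def test_group_fit_pools_subject_days():
    rng = np.random.default_rng(3)
    days = list(range(-20, 0)) + [1, 2]
    t = np.where(np.array(days) < 0, np.array(days), np.array(days) - 1).astype(float)
    series = [
        _synced(f"s{i}", "survivor", days, cosine(t, -1.65, 0.33, 21.5) + rng.normal(0, 0.1, t.size))
        for i in range(6)
    ]
    group_fits, subject_fits = fit_group_rhythms(series)
    assert len(subject_fits) == 6
    assert group_fits["survivor"].n == 6 * len(days)
    assert group_fits["survivor"].acrophase_days_after_onset == pytest.approx(21.5, abs=0.5)


def test_survivor_phase_advance_vs_control():
    """Survivor rhythms peak earlier than control rhythms (negative difference)."""
    days = list(range(-27, 0)) + [1, 2]
    t = np.where(np.array(days) < 0, np.array(days), np.array(days) - 1).astype(float)
    series = [
        _synced("c1", "control", days, cosine(t, -1.42, 0.33, 27.4)),
        _synced("v1", "survivor", days, cosine(t, -1.65, 0.33, 21.5)),
    ]
    fits, _ = fit_group_rhythms(series)
    diff = acrophase_diff(
        fits["survivor"].acrophase_days_after_onset, fits["control"].acrophase_days_after_onset
    )
    assert diff < 0
    assert diff == pytest.approx(-5.9, abs=0.1)


def test_estimator_sklearn_contract():
    from sklearn.base import clone

    est = CosinorRegression(period=28.0)
    assert clone(est).get_params() == est.get_params()
    t = np.arange(28.0).reshape(-1, 1)
    est.fit(t, cosine(np.arange(28.0), 1.0, 0.5, 5.0))
    assert est.score(t, cosine(np.arange(28.0), 1.0, 0.5, 5.0)) == pytest.approx(1.0)
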