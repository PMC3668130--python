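"""Single-cosinor rhythmometry with a fixed 28-day period.

The cosinor model is

    y(t) = M + A·cos(2π(t − t_peak)/τ) + e,   A ≥ 0,

with MESOR M (the rhythm-adjusted mean), amplitude A (half the
peak-to-trough distance) and acrophase t_peak (the timing of the crest).
Linearizing with β_c = A·cos(ωt_peak), β_s = A·sin(ωt_peak),
ω = 2π/τ turns the fit into ordinary least squares on the regressors
cos(ωt) and sin(ωt); the zero-amplitude F test compares the cosine model
against the constant model with (2, n − 3) degrees of freedom.

Times are on the mapped day axis of :mod:`mammotherm.sync` (onset = 0, −1
and +1 adjacent), so the acrophase in days after menses onset is simply
t_peak modulo the period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .sync import SyncedSeries, label_to_t

DEFAULT_PERIOD = 28.0


class CosinorRegression(RegressorMixin, BaseEstimator):
    """Least-squares fit of a fixed-period cosine.

    Parameters
    ----------
    period : float, default 28.0
        Rhythm period τ in days, held fixed during fitting.

    Attributes
    ----------
    mesor_ : float
        Rhythm-adjusted mean M.
    amplitude_ : float
        Cosine amplitude A ≥ 0.
    acrophase_ : float
        Peak time in days after menses onset, in [0, period).
    coef_ : ndarray of shape (2,)
        Linearized coefficients (β_cos, β_sin).
    rss_ : float
        Residual sum of squares.
    f_statistic_, p_zero_amplitude_ : float
        Zero-amplitude F test with (2, n − 3) degrees of freedom; for a
        perfectly constant series the test is degenerate and p is 1 by
        convention.
    n_obs_ : int
        Number of observations used.
    """

    def __init__(self, period: float = DEFAULT_PERIOD):
        self.period = period

    @staticmethod
    def _times(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError(f"expected a single time column, got shape {t.shape}")
            t = t[:, 0]
        elif t.ndim != 1:
            raise ValueError("times must be 1-d or a single-column 2-d array")
        return t

    def fit(self, X, y) -> "CosinorRegression":
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        t = self._times(X)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and values must have equal length")
        mask = ~(np.isnan(t) | np.isnan(y))
        t, y = t[mask], y[mask]
        n = t.size
        if n < 4 or np.unique(t).size < 4:
            raise ValueError(f"cosinor fit needs at least 4 distinct time points, got {np.unique(t).size}")
        omega = 2.0 * np.pi / self.period
        design = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("collinear design: times are degenerate modulo the period")
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        rss = float(resid @ resid)
        rss0 = float(np.sum((y - y.mean()) ** 2))

        self.mesor_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.amplitude_ = float(np.hypot(beta[1], beta[2]))
        # peak where ωt ≡ atan2(β_s, β_c)
        self.acrophase_ = float(np.mod(np.arctan2(beta[2], beta[1]) / omega, self.period))
        self.rss_ = rss
        self.n_obs_ = int(n)
        self.dof_resid_ = int(n - 3)
        if rss0 <= 1e-12 * max(1.0, abs(y.mean())):
            # constant series: no variance to explain, test degenerate
            self.f_statistic_ = float("nan")
            self.p_zero_amplitude_ = 1.0
        elif rss <= 1e-12 * rss0:
            # exact cosine: infinitely strong rhythm
            self.f_statistic_ = float("inf")
            self.p_zero_amplitude_ = 0.0
        else:
            f = ((rss0 - rss) / 2.0) / (rss / (n - 3))
            self.f_statistic_ = float(f)
            self.p_zero_amplitude_ = float(sps.f.sf(f, 2, n - 3))
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        t = self._times(X)
        omega = 2.0 * np.pi / self.period
        return self.mesor_ + self.amplitude_ * np.cos(omega * (t - self.acrophase_))


@dataclass
class CosinorFit:
    """Fitted rhythm parameters for one series or one pooled group."""

    mesor: float
    amplitude: float
    acrophase_days_after_onset: float  # [0, period)
    acrophase_mapped_day: float  # (−period, 0]; cycle-day axis with onset at 0
    period: float
    n: int
    rss: float
    f_statistic: float
    p_zero_amplitude: float
    beta_cos: float
    beta_sin: float

    @classmethod
    def from_estimator(cls, est: CosinorRegression) -> "CosinorFit":
        return cls(
            mesor=est.mesor_,
            amplitude=est.amplitude_,
            acrophase_days_after_onset=est.acrophase_,
            acrophase_mapped_day=est.acrophase_ - est.period,
            period=est.period,
            n=est.n_obs_,
            rss=est.rss_,
            f_statistic=est.f_statistic_,
            p_zero_amplitude=est.p_zero_amplitude_,
            beta_cos=float(est.coef_[0]),
            beta_sin=float(est.coef_[1]),
        )


def cosinor_fit(times, values, period: float = DEFAULT_PERIOD) -> CosinorFit:
    """Fit the fixed-period cosinor to (time, value) points.

    ``times`` are on the mapped day axis (onset = 0; use
    :func:`mammotherm.sync.label_to_t` to convert cycle-day labels).
    """
    est = CosinorRegression(period=period).fit(np.asarray(times, dtype=float), values)
    return CosinorFit.from_estimator(est)


def acrophase_diff(phi_a: float, phi_b: float, tau: float = DEFAULT_PERIOD) -> float:
    """Signed circular phase difference in (−τ/2, τ/2], days.

    Negative means the first phase is earlier (phase-advanced) relative to
    the second.
    """
    raw = np.mod(phi_a - phi_b, tau)
    return float(raw if raw <= tau / 2.0 else raw - tau)


def fit_group_rhythms(
    synced: list[SyncedSeries],
    variable: str = "vascularity_C",
    period: float = DEFAULT_PERIOD,
    pool: str = "days",
) -> tuple[dict[str, CosinorFit], pd.DataFrame]:
    """Group-level and per-subject cosinor fits.

    The group fit pools every subject-day point of the group (keeping
    per-day n differences honest); set ``pool="daily-means"`` to fit the
    cross-subject daily means instead. Per-subject fits are returned for
    dispersion estimates; subjects with fewer than 4 usable days are
    reported with NaN parameters.

    Returns
    -------
    (group_fits, subject_fits)
        ``group_fits`` maps group label to :class:`CosinorFit`;
        ``subject_fits`` is a tidy frame with one row per subject.
    """
    if pool not in ("days", "daily-means"):
        raise ValueError(f"pool must be 'days' or 'daily-means', got {pool!r}")
    groups: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    subject_rows = []
    for s in synced:
        d = s.data[s.data[variable].notna()]
        t = label_to_t(d["cycle_day"].to_numpy(dtype=int)).astype(float)
        v = d[variable].to_numpy(dtype=float)
        groups.setdefault(s.group, []).append((t, v))
        row: dict = {"subject_id": s.subject_id, "group": s.group, "variable": variable}
        try:
            fit = cosinor_fit(t, v, period)
            row.update(
                mesor=fit.mesor,
                amplitude=fit.amplitude,
                acrophase_days_after_onset=fit.acrophase_days_after_onset,
                n=fit.n,
                f_statistic=fit.f_statistic,
                p_zero_amplitude=fit.p_zero_amplitude,
            )
        except ValueError:
            row.update(
                mesor=np.nan,
                amplitude=np.nan,
                acrophase_days_after_onset=np.nan,
                n=int(v.size),
                f_statistic=np.nan,
                p_zero_amplitude=np.nan,
            )
        subject_rows.append(row)

    group_fits: dict[str, CosinorFit] = {}
    for group, pieces in groups.items():
        t = np.concatenate([p[0] for p in pieces])
        v = np.concatenate([p[1] for p in pieces])
        if v.size == 0:
            raise ValueError(f"group {group!r} has no usable subject-days for {variable!r}")
        if pool == "daily-means":
            df = pd.DataFrame({"t": t, "v": v}).groupby("t", as_index=False)["v"].mean()
            t, v = df["t"].to_numpy(), df["v"].to_numpy()
        group_fits[group] = cosinor_fit(t, v, period)
    return group_fits, pd.DataFrame(subject_rows)
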