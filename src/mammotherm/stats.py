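"""Luteal-phase group comparisons, prognostic scoring and cohort summaries.

The headline comparison operates on the 11 cross-subject daily mean
vascularity values of cycle days −11…−1 (the luteal window), summarized per
group as mean ± sample SD and compared pairwise with two-tailed unpaired
t-tests (pooled-variance Student by default, df = n₁ + n₂ − 2; Welch behind
a flag).

Tumour prognosis uses the Nottingham Prognostic Index,

    NPI = 0.2 × size(cm) + grade + nodal stage,

with nodal stage 1 for 0 involved nodes, 2 for 1–3, 3 for ≥4; the score is
undefined for in-situ (non-invasive) disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

LUTEAL_WINDOW = (-11, -1)


@dataclass
class LutealStats:
    group: str
    daily_means: pd.Series  # indexed by cycle day
    overall_mean: float
    overall_sd: float  # sample SD of the available daily means
    n_days: int


@dataclass
class TTestResult:
    group_a: str
    group_b: str
    mean_difference: float  # mean(a) − mean(b)
    t_stat: float
    df: float
    p_two_tailed: float
    degenerate: bool = False


def luteal_stats(
    daily_means: dict[int, float] | pd.Series,
    group: str = "",
    window: tuple[int, int] = LUTEAL_WINDOW,
) -> LutealStats:
    """Overall mean and sample SD of the luteal-window daily means.

    ``daily_means`` maps cycle day to the cross-subject mean vascularity for
    that day. Days of the window absent from the input are warned about and
    the statistics computed on the available days; fewer than two available
    days is an error.
    """
    if isinstance(daily_means, dict):
        daily_means = pd.Series(daily_means)
    lo, hi = window
    wanted = list(range(lo, hi + 1))
    avail = daily_means.reindex(wanted).dropna()
    missing = sorted(set(wanted) - set(avail.index))
    if missing:
        warnings.warn(f"luteal window days {missing} unavailable; using {len(avail)} days", stacklevel=2)
    if len(avail) < 2:
        raise ValueError(f"need at least 2 luteal-window days, got {len(avail)}")
    return LutealStats(
        group=group,
        daily_means=avail,
        overall_mean=float(avail.mean()),
        overall_sd=float(avail.std(ddof=1)),
        n_days=int(len(avail)),
    )


def pooled_t_test(
    a,
    b,
    label_a: str = "a",
    label_b: str = "b",
    welch: bool = False,
) -> TTestResult:
    """Two-tailed unpaired t-test between two samples of daily means.

    Student's pooled-variance test by default (df = n₁ + n₂ − 2); Welch's
    unequal-variance variant with ``welch=True``. Identical constant samples
    give t = 0, p = 1; zero pooled variance with unequal means is flagged
    degenerate with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if diff == 0.0:
            return TTestResult(label_a, label_b, 0.0, 0.0, a.size + b.size - 2, 1.0)
        return TTestResult(label_a, label_b, diff, np.inf, a.size + b.size - 2, 0.0, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TTestResult(label_a, label_b, diff, float(res.statistic), df, float(res.pvalue))


def node_stage(nodes: int) -> int:
    """Nodal stage from the involved-lymph-node count: 0→1, 1–3→2, ≥4→3."""
    if nodes < 0 or int(nodes) != nodes:
        raise ValueError(f"node count must be a non-negative integer, got {nodes}")
    if nodes == 0:
        return 1
    return 2 if nodes <= 3 else 3


def npi(size_mm: float, grade: int, nodes: int, in_situ: bool = False) -> float | None:
    """Nottingham Prognostic Index; ``None`` for in-situ (non-invasive) disease."""
    if in_situ:
        return None
    if grade not in (1, 2, 3):
        raise ValueError(f"grade must be 1, 2 or 3, got {grade}")
    if not size_mm > 0:
        raise ValueError(f"size_mm must be positive, got {size_mm}")
    return 0.2 * (size_mm / 10.0) + grade + node_stage(nodes)


@dataclass
class PathologyRecord:
    """One tumour's pathology with the derived nodal stage and NPI score."""

    subject_id: str
    size_mm: float | None
    grade: int | None
    nodes: int
    in_situ: bool = False

    @property
    def node_stage(self) -> int:
        return node_stage(self.nodes)

    @property
    def npi(self) -> float | None:
        if self.in_situ or self.size_mm is None or self.grade is None:
            return None
        return npi(self.size_mm, self.grade, self.nodes)


def score_pathology(pathology: pd.DataFrame) -> pd.DataFrame:
    """Add ``node_stage`` and ``npi`` columns to a pathology frame.

    Expects columns ``size_mm``, ``grade``, ``nodes`` and optionally
    ``in_situ``; in-situ rows (and rows lacking size or grade) get NaN NPI.
    """
    out = pathology.copy()
    out["node_stage"] = [node_stage(int(n)) for n in out["nodes"]]
    scores = []
    for _, r in out.iterrows():
        ins = bool(r.get("in_situ", False))
        if ins or pd.isna(r["size_mm"]) or pd.isna(r["grade"]):
            scores.append(np.nan)
        else:
            scores.append(npi(float(r["size_mm"]), int(r["grade"]), int(r["nodes"])))
    out["npi"] = scores
    return out


def _median(values: np.ndarray) -> float:
    # midpoint-of-two rule for even n (the ordinary sample median)
    return float(np.median(values))


def cohort_summary(pathology: pd.DataFrame, parameters: list[str] | None = None) -> pd.DataFrame:
    """Per-group n, mean ± SD and median of study parameters, with t-tests.

    Operates on a pathology/follow-up frame with a ``group`` column; NPI is
    (re)computed from size/grade/nodes, excluding in-situ rows, so per-group
    n varies by parameter. When exactly two groups are present, a pooled
    two-tailed t-test p-value comparing them is attached per parameter.
    """
    if "group" not in pathology.columns or pathology.empty:
        raise ValueError("pathology frame must be non-empty with a 'group' column")
    scored = score_pathology(pathology)
    if parameters is None:
        parameters = [
            c
            for c in ("age_at_surgery_y", "size_mm", "grade", "nodes", "npi", "survival_y")
            if c in scored.columns
        ]
    groups = list(dict.fromkeys(scored["group"]))
    rows = []
    for param in parameters:
        row: dict = {"parameter": param}
        samples = {}
        for g in groups:
            vals = scored.loc[scored["group"] == g, param].dropna().to_numpy(dtype=float)
            samples[g] = vals
            row[f"{g}_n"] = int(vals.size)
            row[f"{g}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{g}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            row[f"{g}_median"] = _median(vals) if vals.size else np.nan
        if len(groups) == 2:
            a, b = samples[groups[0]], samples[groups[1]]
            if a.size >= 2 and b.size >= 2:
                row["p_t_test"] = pooled_t_test(a, b, *groups).p_two_tailed
            else:
                row["p_t_test"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
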