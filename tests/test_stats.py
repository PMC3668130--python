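"""Luteal-window statistics, NPI scoring and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from mammotherm.datasets import load_reference_luteal_daily_means, load_reference_pathology
from mammotherm.stats import (
    PathologyRecord,
    cohort_summary,
    luteal_stats,
    node_stage,
    npi,
    pooled_t_test,
    score_pathology,
)

SURVIVOR_DAILY = [-1.66, -1.56, -1.56, -1.63, -1.38, -1.71, -1.83, -1.54, -1.41, -1.64, -2.22]
CONTROL_DAILY = [-1.53, -1.47, -1.58, -1.49, -1.42, -1.44, -1.39, -1.32, -1.34, -1.38, -1.29]


def manual_pooled_t(a, b):
    """Independent route: pooled-variance formula + regularized-beta t CDF."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = special.betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, df, p


def test_luteal_stats_reference_columns():
    """The printed survivor/control daily values give the printed mean ± SD."""
    surv = luteal_stats(dict(zip(range(-11, 0), SURVIVOR_DAILY)), "survivor")
    assert round(surv.overall_mean, 2) == -1.65
    assert round(surv.overall_sd, 2) == 0.23
    ctrl = luteal_stats(dict(zip(range(-11, 0), CONTROL_DAILY)), "control")
    assert round(ctrl.overall_mean, 2) == -1.42
    assert round(ctrl.overall_sd, 2) == 0.09
    # independent summation route
    assert surv.overall_mean == pytest.approx(sum(SURVIVOR_DAILY) / 11, abs=1e-12)


def test_luteal_stats_identical_values():
    ls = luteal_stats({d: 1.5 for d in range(-11, 0)})
    assert ls.overall_mean == 1.5 and ls.overall_sd == 0.0


def test_luteal_stats_partial_window_warns():
    with pytest.warns(UserWarning, match="unavailable"):
        ls = luteal_stats({-1: 1.0, -2: 2.0})
    assert ls.n_days == 2
    with pytest.raises(ValueError, match="at least 2"):
        luteal_stats({-1: 1.0})


def test_pooled_t_against_manual_formula():
    res = pooled_t_test(CONTROL_DAILY, SURVIVOR_DAILY, "control", "survivor")
    t, df, p = manual_pooled_t(CONTROL_DAILY, SURVIVOR_DAILY)
    assert res.df == df == 20
    assert res.t_stat == pytest.approx(t, rel=1e-12)
    assert res.p_two_tailed == pytest.approx(p, rel=1e-10)
    assert res.mean_difference == pytest.approx(0.226, abs=5e-4)
    assert round(res.p_two_tailed, 4) == 0.0062


def test_pooled_t_symmetry_and_degenerate_cases():
    fwd = pooled_t_test(CONTROL_DAILY, SURVIVOR_DAILY)
    rev = pooled_t_test(SURVIVOR_DAILY, CONTROL_DAILY)
    assert fwd.mean_difference == -rev.mean_difference
    assert fwd.p_two_tailed == pytest.approx(rev.p_two_tailed)
    same = pooled_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert same.t_stat == 0.0 and same.p_two_tailed == 1.0
    degen = pooled_t_test([1.0, 1.0], [2.0, 2.0])
    assert degen.degenerate and degen.p_two_tailed == 0.0


def test_welch_variant_differs():
    student = pooled_t_test(CONTROL_DAILY, SURVIVOR_DAILY)
    welch = pooled_t_test(CONTROL_DAILY, SURVIVOR_DAILY, welch=True)
    assert welch.df < student.df


def test_power_of_luteal_comparison():
    """Two groups of 11 daily means, true difference 0.405 °C, SDs 0.23/0.12:
    the Monte-Carlo detection rate at p < 0.001 matches the noncentral-t
    power (≈ 0.88) and the comparison is decisively powered."""
    from scipy import stats as sps

    ncp = 0.405 / np.sqrt((0.23**2 + 0.12**2) / 11)
    t_crit = sps.t.ppf(1 - 0.0005, 20)
    power = sps.nct.sf(t_crit, 20, ncp) + sps.nct.cdf(-t_crit, 20, ncp)
    rng = np.random.default_rng(2024)
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        a = rng.normal(-1.245, 0.12, 11)
        b = rng.normal(-1.650, 0.23, 11)
        if pooled_t_test(a, b).p_two_tailed < 0.001:
            hits += 1
    rate = hits / n_rep
    assert rate > 0.8
    assert abs(rate - power) < 3.5 * np.sqrt(power * (1 - power) / n_rep)


@pytest.mark.parametrize("nodes, stage", [(0, 1), (1, 2), (2, 2), (3, 2), (4, 3), (11, 3)])
def test_node_stage(nodes, stage):
    assert node_stage(nodes) == stage


def test_node_stage_rejects_negative():
    with pytest.raises(ValueError):
        node_stage(-1)


@pytest.mark.parametrize(
    "size, grade, nodes, expected",
    [
        (15, 2, 1, 4.30),
        (120, 3, 2, 7.40),
        (30, 1, 1, 3.60),
        (80, 3, 0, 5.60),
        (21, 3, 4, 6.42),
    ],
)
def test_npi_reference_rows(size, grade, nodes, expected):
    assert npi(size, grade, nodes) == pytest.approx(expected, abs=1e-9)


def test_npi_in_situ_and_validation():
    assert npi(30, 2, 0, in_situ=True) is None
    rec = PathologyRecord("x", None, None, 0, in_situ=True)
    assert rec.npi is None and rec.node_stage == 1
    with pytest.raises(ValueError):
        npi(30, 4, 0)
    with pytest.raises(ValueError):
        npi(0, 2, 0)


def test_npi_strictly_increasing_in_each_argument():
    base = npi(20, 2, 1)
    assert npi(30, 2, 1) > base
    assert npi(20, 3, 1) > base
    assert npi(20, 2, 4) > base


def test_reference_pathology_scores_match_print():
    """Recomputed NPI equals the printed scores (one 0.01 print rounding aside)."""
    scored = score_pathology(load_reference_pathology())
    invasive = scored[~scored["in_situ"]]
    mismatch = (invasive["npi"] - invasive["npi_printed"]).abs()
    assert (mismatch <= 0.015).all()
    assert (mismatch <= 1e-9).sum() >= len(invasive) - 1
    assert scored.loc[scored["in_situ"], "npi"].isna().all()


def test_cohort_summary_reference_follow_up():
    """Survivor/non-survivor follow-up and node summaries match the report."""
    summary = cohort_summary(load_reference_pathology()).set_index("parameter")
    surv = summary.loc["survival_y"]
    assert round(surv["survivor_mean"], 1) == 22.4
    assert round(surv["survivor_median"], 1) == 22.7
    assert round(surv["non-survivor_mean"], 1) == 7.8
    assert round(surv["non-survivor_median"], 1) == 6.2
    nodes = summary.loc["nodes"]
    assert round(nodes["survivor_mean"], 2) == 0.06
    assert round(nodes["non-survivor_mean"], 2) == 1.00
    assert nodes["p_t_test"] == pytest.approx(0.0103, abs=5e-4)
    npi_row = summary.loc["npi"]
    assert npi_row["survivor_n"] == 15 and npi_row["non-survivor_n"] == 18


def test_cohort_summary_single_subject_group():
    df = pd.DataFrame(
        {
            "group": ["a"],
            "survival_y": [5.0],
            "size_mm": [20],
            "grade": [2],
            "nodes": [0],
            "in_situ": [False],
        }
    )
    out = cohort_summary(df).set_index("parameter")
    assert out.loc["survival_y", "a_mean"] == 5.0
    assert out.loc["survival_y", "a_median"] == 5.0
    assert np.isnan(out.loc["survival_y", "a_sd"])
    with pytest.raises(ValueError):
        cohort_summary(pd.DataFrame())


def test_reference_luteal_table_consistent_with_columns():
    ref = load_reference_luteal_daily_means()
    assert list(ref.index) == list(range(-11, 0))
    np.testing.assert_allclose(ref["survivor"].to_numpy(), SURVIVOR_DAILY)
    np.testing.assert_allclose(ref["control"].to_numpy(), CONTROL_DAILY)
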