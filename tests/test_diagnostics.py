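"""Statistical battery: group tests, ROC/AUC, DeLong, LOOCV, laterality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nigramap.contrast import REGION_COLUMNS, cr_column
from nigramap.diagnostics import (
    DiagnosticsError,
    compare_groups,
    compare_rocs,
    dominant_side,
    laterality_concordance,
    loocv,
    mann_whitney_exact_p,
    roc_analysis,
)


def _table(ipd_values, hc_values, region="left_n1n2"):
    """Minimal CR table with one region filled; the rest copy it."""
    n1, n0 = len(ipd_values), len(hc_values)
    rows = {
        "subject_id": [f"ipd_{i}" for i in range(n1)] + [f"hc_{i}" for i in range(n0)],
        "group": ["IPD"] * n1 + ["HC"] * n0,
    }
    values = list(ipd_values) + list(hc_values)
    for r in REGION_COLUMNS:
        rows[cr_column(r)] = values
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# compare_groups / exact Mann-Whitney
# --------------------------------------------------------------------------- #


def test_identical_groups_give_p_one():
    values = [0.1, 0.2, 0.3, 0.4]
    results = compare_groups(_table(values, values), regions=["left_n1n2"])
    assert results[0].p_raw == pytest.approx(1.0)


def test_exact_mwu_textbook_example():
    """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 2/20 = 0.1."""
    u, p = mann_whitney_exact_p(np.array([1, 2, 3]), np.array([4, 5, 6]))
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_exact_mwu_matches_scipy_on_untied_data(rng):
    for _ in range(20):
        x = rng.normal(size=rng.integers(3, 8))
        y = rng.normal(size=rng.integers(3, 8))
        u, p = mann_whitney_exact_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_exact_mwu_handles_ties():
    # with ties, p must still be a valid probability and U uses midranks
    u, p = mann_whitney_exact_p(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 2.0]))
    assert 0.0 < p <= 1.0
    # U from midranks: ranks of pooled [1,1,2,1,2,2] -> [2,2,5,2,5,5]
    assert u == pytest.approx(2 + 2 + 5 - 6)


def test_bonferroni_adjustment_and_cap():
    rng = np.random.default_rng(0)
    ipd = rng.normal(0.10, 0.02, 12)
    hc = rng.normal(0.20, 0.02, 12)
    results = compare_groups(_table(ipd, hc))
    m = len(REGION_COLUMNS)
    for r in results:
        assert r.p_adjusted == pytest.approx(min(1.0, m * r.p_raw))
        assert r.p_adjusted >= r.p_raw


def test_summary_style_matches_test_used():
    rng = np.random.default_rng(4)
    normal_ipd = rng.normal(0.1, 0.01, 20)
    normal_hc = rng.normal(0.2, 0.01, 20)
    res = compare_groups(_table(normal_ipd, normal_hc), regions=["left_n1"])[0]
    assert res.test == "t-test" and "±" in res.summary_ipd

    skewed_ipd = np.exp(rng.normal(0, 2.5, 20))
    skewed_hc = np.exp(rng.normal(1, 2.5, 20))
    res = compare_groups(_table(skewed_ipd, skewed_hc), regions=["left_n1"])[0]
    assert res.test == "mann-whitney" and "(" in res.summary_ipd


def test_compare_groups_degenerate_error():
    with pytest.raises(DiagnosticsError):
        compare_groups(_table([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]), regions=["left_n1"])


def test_compare_groups_needs_three_per_group():
    with pytest.raises(DiagnosticsError):
        compare_groups(_table([1.0, 2.0], [3.0, 4.0, 5.0]))


# --------------------------------------------------------------------------- #
# roc_analysis
# --------------------------------------------------------------------------- #


def _brute_force_auc(ipd, hc):
    wins = sum(1.0 if x < y else 0.5 if x == y else 0.0 for x in ipd for y in hc)
    return wins / (len(ipd) * len(hc))


def test_auc_perfect_separation():
    res = roc_analysis(_table([0.1, 0.2], [0.3, 0.4, 0.5]), "left_n1n2")
    assert res.auc == 1.0
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_auc_identical_groups_is_half():
    res = roc_analysis(_table([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]), "left_n1n2")
    assert res.auc == pytest.approx(0.5)


def test_auc_degenerate_constant_warns():
    res = roc_analysis(_table([1.0, 1.0], [1.0, 1.0]), "left_n1n2")
    assert res.auc == 0.5 and res.warnings


def test_auc_equals_brute_force_with_ties(rng):
    for _ in range(25):
        ipd = rng.integers(0, 6, rng.integers(3, 12)).astype(float)
        hc = rng.integers(0, 6, rng.integers(3, 12)).astype(float)
        res = roc_analysis(_table(ipd, hc), "left_n1n2")
        assert res.auc == pytest.approx(_brute_force_auc(ipd, hc), abs=1e-12)


def test_auc_ci_contains_auc(rng):
    ipd = rng.normal(0.1, 0.05, 15)
    hc = rng.normal(0.18, 0.05, 15)
    res = roc_analysis(_table(ipd, hc), "left_n1n2")
    assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0


def test_youden_tie_broken_toward_specificity():
    # two thresholds achieve J = 0.5; the lower one (higher specificity) wins
    ipd = [1.0, 3.0]
    hc = [2.0, 4.0]
    res = roc_analysis(_table(ipd, hc), "left_n1n2")
    assert res.threshold < 2.0
    assert res.specificity == 1.0


# --------------------------------------------------------------------------- #
# compare_rocs
# --------------------------------------------------------------------------- #


def test_compare_rocs_diagonal_and_identical_regions():
    rng = np.random.default_rng(5)
    table = _table(rng.normal(0.1, 0.05, 20), rng.normal(0.2, 0.05, 20))
    p = compare_rocs(table, regions=["left_n1", "left_n2"])
    assert p.loc["left_n1", "left_n1"] == 1.0
    # every region holds the same scores in _table, so all pairs give p = 1
    assert p.loc["left_n1", "left_n2"] == 1.0
    assert np.allclose(p.values, p.values.T)


def test_compare_rocs_strong_vs_null_effect_with_permutation_oracle():
    rng = np.random.default_rng(7)
    n = 50
    strong_ipd, strong_hc = rng.normal(-1.5, 1, n), rng.normal(0.5, 1, n)
    null_ipd, null_hc = rng.normal(0, 1, n), rng.normal(0, 1, n)
    table = _table(list(strong_ipd), list(strong_hc))
    table[cr_column("left_n2")] = list(null_ipd) + list(null_hc)
    regions = ["left_n1", "left_n2"]
    p = compare_rocs(table, regions=regions)
    assert p.loc["left_n1", "left_n2"] < 0.05

    # permutation oracle: group labels permuted jointly for both regions
    def auc(x, y):
        return ((x[:, None] < y[None, :]) + 0.5 * (x[:, None] == y[None, :])).mean()

    scores = np.column_stack([
        np.concatenate([strong_ipd, strong_hc]),
        np.concatenate([null_ipd, null_hc]),
    ])
    obs = abs(auc(scores[:n, 0], scores[n:, 0]) - auc(scores[:n, 1], scores[n:, 1]))
    perm_rng = np.random.default_rng(11)
    exceed = 0
    n_perm = 2000
    for _ in range(n_perm):
        idx = perm_rng.permutation(2 * n)
        d = abs(auc(scores[idx[:n], 0], scores[idx[n:], 0])
                - auc(scores[idx[:n], 1], scores[idx[n:], 1]))
        if d >= obs:
            exceed += 1
    p_perm = (1 + exceed) / (n_perm + 1)
    assert p_perm < 0.05  # oracle agrees the difference is significant


def test_compare_rocs_rejects_missing_values():
    table = _table([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
    table.loc[0, cr_column("left_n1")] = np.nan
    with pytest.raises(DiagnosticsError):
        compare_rocs(table)


# --------------------------------------------------------------------------- #
# loocv
# --------------------------------------------------------------------------- #


def test_loocv_perfect_separation():
    res = loocv(_table([0.1, 0.12, 0.15], [0.3, 0.35, 0.4]), "left_n1n2")
    assert res["cv_sensitivity"] == 1.0 and res["cv_specificity"] == 1.0
    assert res["cv_auc"] == 1.0


def test_loocv_null_youden_j_near_zero():
    rng = np.random.default_rng(21)
    js = []
    for _ in range(100):
        values = rng.normal(size=16)
        res = loocv(_table(values[:8], values[8:]), "left_n1n2")
        js.append(res["cv_sensitivity"] + res["cv_specificity"] - 1.0)
    # under the null the cross-validated Youden J is centred at zero
    assert abs(np.mean(js)) < 3 * np.std(js, ddof=1) / 10  # 3 SEM over 100 seeds


def test_loocv_optimism_cv_not_better_than_apparent():
    rng = np.random.default_rng(22)
    cv_sens, app_sens = [], []
    for _ in range(100):
        values = rng.normal(size=16)
        table = _table(values[:8], values[8:])
        res = loocv(table, "left_n1n2")
        roc = roc_analysis(table, "left_n1n2")
        cv_sens.append(res["cv_sensitivity"])
        app_sens.append(roc.sensitivity)
    assert np.mean(cv_sens) <= np.mean(app_sens)


# --------------------------------------------------------------------------- #
# laterality
# --------------------------------------------------------------------------- #


def test_dominant_side_rule():
    assert dominant_side(10, 7) == "right"
    assert dominant_side(5, 4) == "indeterminate"
    assert dominant_side(4, 6) == "left"
    assert dominant_side(6, 4) == "right"


def _hypergeom_fisher_p(table):
    """Two-sided Fisher p by direct enumeration over fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        return stats.hypergeom.pmf(a_, n, r1, c1)

    p_obs = prob(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_ = prob(a_)
        if p_ <= p_obs * (1 + 1e-9):
            total += p_
    return total


def test_fisher_p_matches_hypergeometric_enumeration():
    table = np.array([[8, 2], [1, 9]])
    _, scipy_p = stats.fisher_exact(table, alternative="two-sided")
    assert scipy_p == pytest.approx(_hypergeom_fisher_p(table), rel=1e-9)


def _records_and_table(rows):
    """rows: (sid, right_score, left_score, cr_right_n1, cr_left_n1)."""
    records = pd.DataFrame(
        {
            "subject_id": [r[0] for r in rows],
            "group": ["IPD"] * len(rows),
            "right_motor_score": [r[1] for r in rows],
            "left_motor_score": [r[2] for r in rows],
        }
    )
    table = pd.DataFrame({"subject_id": [r[0] for r in rows]})
    for region in REGION_COLUMNS:
        table[cr_column(region)] = 0.1
    table[cr_column("right_n1")] = [r[3] for r in rows]
    table[cr_column("left_n1")] = [r[4] for r in rows]
    return records, table


def test_laterality_concordance_counts():
    rows = [
        ("a", 9, 4, 0.2, 0.1),   # dominant right, higher CR right -> concordant
        ("b", 3, 8, 0.1, 0.2),   # dominant left, higher CR left -> concordant
        ("c", 8, 3, 0.1, 0.2),   # dominant right, higher CR left -> discordant
        ("d", 5, 5, 0.2, 0.1),   # indeterminate, excluded
    ]
    records, table = _records_and_table(rows)
    res = laterality_concordance(records, table)
    assert res.n_indeterminate == 1
    assert res.table.sum() == 3
    assert res.table[0, 0] == 1 and res.table[1, 1] == 1 and res.table[0, 1] == 1
    assert 0.0 < res.fisher_p <= 1.0


def test_laterality_all_indeterminate_errors():
    rows = [("a", 5, 5, 0.2, 0.1), ("b", 4, 5, 0.1, 0.2)]
    records, table = _records_and_table(rows)
    with pytest.raises(DiagnosticsError):
        laterality_concordance(records, table)
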