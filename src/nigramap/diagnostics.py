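"""Diagnostic evaluation of the contrast-ratio marker.

Covers the full statistical battery: normality-gated group comparisons with
Bonferroni correction, ROC/AUC with DeLong confidence intervals and paired
AUC-difference tests, Youden operating points, leave-one-out cross-validation
with per-fold threshold refitting, and concordance between clinical motor
laterality and the side of the higher N1 contrast ratio (Fisher exact test).

Direction convention, fixed globally: disease (IPD) has the *lower* CR; the
classifier calls a subject a patient when the CR falls below the threshold.
AUC is therefore P(CR_patient < CR_control) with ties counting one half, which
equals the Mann-Whitney U of the control-higher ordering divided by n1*n0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .contrast import REGION_COLUMNS, cr_column

__all__ = [
    "ComparisonResult",
    "RocResult",
    "LateralityResult",
    "compare_groups",
    "mann_whitney_exact_p",
    "roc_analysis",
    "compare_rocs",
    "loocv",
    "dominant_side",
    "laterality_concordance",
]

LATERALITY_CUTOFF = 2  # points of per-side motor-score difference


class DiagnosticsError(RuntimeError):
    pass


# --------------------------------------------------------------------------- #
# Group comparisons
# --------------------------------------------------------------------------- #


@dataclass
class ComparisonResult:
    region: str
    test: str  # "t-test" or "mann-whitney"
    statistic: float
    p_raw: float
    p_adjusted: float
    summary_ipd: str
    summary_hc: str


def _summary(values: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{values.mean():.6f} ± {values.std(ddof=1):.6f}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.6f} ({q1:.6f}–{q3:.6f})"


def mann_whitney_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (handles ties).

    Enumerates every assignment of the pooled values to the two groups and
    returns (U of x vs y with ties counting one half, two-sided p), where the
    two-sided p is the null probability of a U at least as far from its mean
    n*m/2 as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    mean_u = n * m / 2.0
    dev_obs = abs(u_obs - mean_u)

    count = 0
    total = comb(n + m, n)
    offset = n * (n + 1) / 2.0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mean_u) >= dev_obs - 1e-9:
            count += 1
    return u_obs, count / total


_EXACT_MWU_MAX_N = 8


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) <= _EXACT_MWU_MAX_N and len(y) <= _EXACT_MWU_MAX_N:
        return mann_whitney_exact_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    cr_table: pd.DataFrame,
    regions: list[str] | None = None,
    normality_alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Per-region IPD vs HC comparison with a Shapiro-Wilk normality gate.

    Both groups normal at ``normality_alpha`` -> two-sided Welch t-test
    (summaries mean +/- SD); otherwise two-sided Mann-Whitney U (exact
    enumeration when both groups have <= 8 subjects, tie-corrected normal
    approximation otherwise; summaries median (IQR)).  Raw p values are
    Bonferroni-adjusted over the region list.
    """
    regions = regions or REGION_COLUMNS
    m = len(regions)
    ipd = cr_table[cr_table["group"] == "IPD"]
    hc = cr_table[cr_table["group"] == "HC"]
    if len(ipd) < 3 or len(hc) < 3:
        raise DiagnosticsError("need at least 3 subjects per group for comparisons")

    results = []
    for region in regions:
        col = cr_column(region)
        x = ipd[col].to_numpy(dtype=float)
        y = hc[col].to_numpy(dtype=float)
        x_const = np.ptp(x) == 0
        y_const = np.ptp(y) == 0
        if x_const and y_const:
            raise DiagnosticsError(f"degenerate data (both groups constant) in region {region}")
        normal = False
        if not x_const and not y_const:
            normal = (
                stats.shapiro(x).pvalue > normality_alpha
                and stats.shapiro(y).pvalue > normality_alpha
            )
        if normal:
            res = stats.ttest_ind(x, y, equal_var=False)
            test, statistic, p_raw = "t-test", float(res.statistic), float(res.pvalue)
        else:
            statistic, p_raw = _mann_whitney(x, y)
            test = "mann-whitney"
        results.append(
            ComparisonResult(
                region=region,
                test=test,
                statistic=statistic,
                p_raw=p_raw,
                p_adjusted=min(1.0, m * p_raw),
                summary_ipd=_summary(x, normal),
                summary_hc=_summary(y, normal),
            )
        )
    return results


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [r.region for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "summary_ipd": [r.summary_ipd for r in results],
            "summary_hc": [r.summary_hc for r in results],
        }
    )


# --------------------------------------------------------------------------- #
# ROC / AUC
# --------------------------------------------------------------------------- #


@dataclass
class RocResult:
    region: str
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    direction: str = "lower CR = disease"
    cv_auc: float | None = None
    cv_sensitivity: float | None = None
    cv_specificity: float | None = None
    warnings: list = field(default_factory=list)
    note: str = ""


def _split_groups(cr_table: pd.DataFrame, region: str) -> tuple[np.ndarray, np.ndarray]:
    col = cr_column(region)
    ipd = cr_table.loc[cr_table["group"] == "IPD", col].to_numpy(dtype=float)
    hc = cr_table.loc[cr_table["group"] == "HC", col].to_numpy(dtype=float)
    if len(ipd) == 0 or len(hc) == 0:
        raise DiagnosticsError(f"empty group for region {region}")
    return ipd, hc


def _placements(ipd: np.ndarray, hc: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components for the rule 'lower CR => disease'.

    psi = 1 when the patient's CR is below the control's, 1/2 on ties.
    Returns (per-patient placements, per-control placements, AUC).
    """
    cmp_matrix = (
        (ipd[:, None] < hc[None, :]).astype(float)
        + 0.5 * (ipd[:, None] == hc[None, :])
    )
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    return v10, v01, float(cmp_matrix.mean())


def _youden_threshold(ipd: np.ndarray, hc: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity - 1 for 'CR < t => IPD'.

    Candidate thresholds are midpoints between adjacent distinct pooled values
    plus one below and one above the data range; ties in J are broken toward
    higher specificity (the lower threshold).
    """
    values = np.unique(np.concatenate([ipd, hc]))
    if len(values) == 1:
        candidates = np.array([values[0]])  # degenerate: everything identical
    else:
        mids = (values[:-1] + values[1:]) / 2.0
        span = values[-1] - values[0]
        candidates = np.concatenate([[values[0] - 0.5 * span], mids, [values[-1] + 0.5 * span]])
    sens = (ipd[:, None] < candidates[None, :]).mean(axis=0)
    spec = (hc[:, None] >= candidates[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first maximum = lowest threshold = highest specificity
    return float(candidates[best]), float(sens[best]), float(spec[best])


def roc_analysis(cr_table: pd.DataFrame, region: str, ci_level: float = 0.95) -> RocResult:
    """AUC with DeLong CI and the Youden-optimal operating point."""
    ipd, hc = _split_groups(cr_table, region)
    v10, v01, auc = _placements(ipd, hc)
    warnings_: list = []

    pooled = np.concatenate([ipd, hc])
    if np.ptp(pooled) == 0:
        auc = 0.5
        warnings_.append("all values identical; AUC degenerate at 0.5")

    var = 0.0
    if len(ipd) > 1 and len(hc) > 1:
        var = float(np.var(v10, ddof=1) / len(ipd) + np.var(v01, ddof=1) / len(hc))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    threshold, sensitivity, specificity = _youden_threshold(ipd, hc)
    return RocResult(
        region=region,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        threshold=threshold,
        sensitivity=sensitivity,
        specificity=specificity,
        warnings=warnings_,
    )


def roc_curve_points(cr_table: pd.DataFrame, region: str) -> pd.DataFrame:
    """(1 - specificity, sensitivity) at every distinct threshold, for plotting."""
    ipd, hc = _split_groups(cr_table, region)
    values = np.unique(np.concatenate([ipd, hc]))
    span = max(np.ptp(values), 1.0)
    thresholds = np.concatenate([[values[0] - span], (values[:-1] + values[1:]) / 2.0,
                                 [values[-1] + span]])
    sens = (ipd[:, None] < thresholds[None, :]).mean(axis=0)
    spec = (hc[:, None] >= thresholds[None, :]).mean(axis=0)
    return pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "fpr": 1.0 - spec})


def compare_rocs(cr_table: pd.DataFrame, regions: list[str] | None = None) -> pd.DataFrame:
    """DeLong paired AUC-difference tests, Bonferroni-adjusted.

    All regions must be scored on the same subjects (paired design); returns a
    symmetric matrix of adjusted p values with 1.0 on the diagonal.
    """
    regions = regions or REGION_COLUMNS
    cols = [cr_column(r) for r in regions]
    if cr_table[cols].isna().any().any():
        raise DiagnosticsError("paired ROC comparison requires complete scores for all regions")

    ipd = cr_table[cr_table["group"] == "IPD"]
    hc = cr_table[cr_table["group"] == "HC"]
    n1, n0 = len(ipd), len(hc)
    if n1 < 2 or n0 < 2:
        raise DiagnosticsError("need at least 2 subjects per group")

    v10 = np.empty((n1, len(regions)))
    v01 = np.empty((n0, len(regions)))
    aucs = np.empty(len(regions))
    for k, region in enumerate(regions):
        x = ipd[cr_column(region)].to_numpy(dtype=float)
        y = hc[cr_column(region)].to_numpy(dtype=float)
        v10[:, k], v01[:, k], aucs[k] = _placements(x, y)

    s10 = np.cov(v10, rowvar=False, ddof=1)
    s01 = np.cov(v01, rowvar=False, ddof=1)
    cov = s10 / n1 + s01 / n0

    m = len(regions)
    n_pairs = m * (m - 1) // 2
    p = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            if var <= 0:
                p_raw = 1.0
            else:
                zstat = (aucs[i] - aucs[j]) / np.sqrt(var)
                p_raw = 2.0 * stats.norm.sf(abs(zstat))
            p[i, j] = p[j, i] = min(1.0, n_pairs * p_raw)
    return pd.DataFrame(p, index=regions, columns=regions)


# --------------------------------------------------------------------------- #
# Leave-one-out cross-validation
# --------------------------------------------------------------------------- #


def loocv(cr_table: pd.DataFrame, region: str) -> dict:
    """LOOCV of the Youden-threshold classifier for one region.

    The threshold is refit on each n-1 training set and applied to the held-out
    subject; pooled held-out calls give the cross-validated sensitivity and
    specificity.  The cross-validated AUC is computed from the pooled held-out
    scores, which are unchanged by holding out, so it equals the apparent AUC;
    it is reported for completeness with a note.
    """
    col = cr_column(region)
    groups = cr_table["group"].to_numpy()
    values = cr_table[col].to_numpy(dtype=float)
    if (groups == "IPD").sum() < 2 or (groups == "HC").sum() < 2:
        raise DiagnosticsError("need at least 2 subjects per group for LOOCV")

    calls = np.zeros(len(values), dtype=bool)  # True = called IPD
    used = np.ones(len(values), dtype=bool)
    skipped = 0
    for i in range(len(values)):
        train = np.ones(len(values), dtype=bool)
        train[i] = False
        x = values[train & (groups == "IPD")]
        y = values[train & (groups == "HC")]
        if len(x) == 0 or len(y) == 0:
            used[i] = False
            skipped += 1
            continue
        threshold, _, _ = _youden_threshold(x, y)
        calls[i] = values[i] < threshold

    is_ipd = groups == "IPD"
    tp = (calls & is_ipd & used).sum()
    fn = (~calls & is_ipd & used).sum()
    tn = (~calls & ~is_ipd & used).sum()
    fp = (calls & ~is_ipd & used).sum()
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    _, _, auc = _placements(values[is_ipd], values[~is_ipd])
    return {
        "region": region,
        "cv_sensitivity": float(sens),
        "cv_specificity": float(spec),
        "cv_auc": float(auc),
        "folds_skipped": int(skipped),
        "note": "held-out scores equal apparent scores under LOOCV, so cv_auc equals the apparent AUC",
    }


# --------------------------------------------------------------------------- #
# Laterality concordance
# --------------------------------------------------------------------------- #


@dataclass
class LateralityResult:
    per_subject: pd.DataFrame  # subject_id, dominant_side, higher_cr_side, concordant
    table: np.ndarray  # 2x2: dominant (right/left) x higher-CR side (right/left)
    fisher_p: float
    n_indeterminate: int


def dominant_side(right_score: int, left_score: int, cutoff: int = LATERALITY_CUTOFF) -> str:
    """Clinically dominant symptom side from per-side motor-score sums.

    A side dominates when its score exceeds the other by at least ``cutoff``
    points (default two); otherwise laterality is indeterminate.
    """
    if right_score - left_score >= cutoff:
        return "right"
    if left_score - right_score >= cutoff:
        return "left"
    return "indeterminate"


def laterality_concordance(records: pd.DataFrame, cr_table: pd.DataFrame) -> LateralityResult:
    """Concordance of clinical laterality with the side of the higher N1 CR.

    Patients whose per-side scores differ by less than two points are
    indeterminate and excluded from the 2x2 table; the association is tested
    with Fisher's exact test (two-sided).
    """
    merged = records.merge(cr_table, on="subject_id", suffixes=("", "_cr"))
    ipd = merged[merged["group"] == "IPD"]
    if len(ipd) == 0:
        raise DiagnosticsError("no IPD subjects for laterality analysis")

    rows = []
    for _, rec in ipd.iterrows():
        dom = dominant_side(int(rec["right_motor_score"]), int(rec["left_motor_score"]))
        higher = "right" if rec[cr_column("right_n1")] > rec[cr_column("left_n1")] else "left"
        rows.append(
            {
                "subject_id": rec["subject_id"],
                "dominant_side": dom,
                "higher_cr_side": higher,
                "concordant": dom != "indeterminate" and dom == higher,
            }
        )
    per_subject = pd.DataFrame(rows)
    determinate = per_subject[per_subject["dominant_side"] != "indeterminate"]
    n_indet = len(per_subject) - len(determinate)
    if len(determinate) == 0:
        raise DiagnosticsError("all subjects have indeterminate laterality")

    table = np.zeros((2, 2), dtype=int)
    for i, dom in enumerate(("right", "left")):
        for j, high in enumerate(("right", "left")):
            table[i, j] = (
                (determinate["dominant_side"] == dom)
                & (determinate["higher_cr_side"] == high)
            ).sum()
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return LateralityResult(per_subject, table, float(fisher_p), n_indet)
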