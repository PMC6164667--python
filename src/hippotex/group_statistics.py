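"""Group-level screening of texture features.

Each feature is screened with a one-way ANOVA F-test over all groups and
pairwise two-sided Mann-Whitney-Wilcoxon (MWW) tests, then corrected for
multiple testing with Bonferroni (family-wise error rate) and
Benjamini-Hochberg (false discovery rate). The default correction family
is all features of one ROI for one comparison, so with the full panel
m = 25; the family rule is explicit because per-ROI significance counts
are the reporting unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, TableFormatError
from .volume_io import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: Correction family rules for evaluate_cohort.
FAMILIES = ("per_roi_comparison", "pooled")


def anova_f(groups) -> float:
    """Two-sided p-value of the classical one-way ANOVA F-test.

    ``groups`` is a list of >= 2 numeric samples, each with n >= 2. Returns
    NaN (missing) when the total variance is zero, where F is undefined.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ParameterError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ParameterError("each ANOVA group needs at least two values")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*groups)
    p = float(res.pvalue)
    return p if np.isfinite(p) else float("nan")


def mww(x, y) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact (full enumeration of rank assignments) when the pooled sample has
    at most 12 observations and no ties; otherwise the normal approximation
    with tie and continuity corrections. Two identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 12 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return min(1.0, float(res.pvalue))


def bonferroni(p, alpha: float = 0.05):
    """Bonferroni-adjusted p-values ``min(1, m*p)`` and flags ``adjusted < alpha``.

    NaN entries are excluded from m and stay NaN/unflagged.
    """
    return _adjust(p, alpha, "bonferroni")


def bh(p, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and flags ``adjusted < alpha``."""
    return _adjust(p, alpha, "fdr_bh")


def _adjust(p, alpha, method):
    p = np.asarray(p, dtype=float)
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        _, corrected, _, _ = multipletests(p[ok], alpha=alpha, method=method)
        adj[ok] = corrected
    flags = np.zeros(p.shape, dtype=bool)
    flags[ok] = adj[ok] < alpha
    return adj, flags


@dataclass
class CohortResult:
    """Per-test results and per-(ROI, comparison) significance counts."""

    tests: pd.DataFrame
    summary: pd.DataFrame
    alpha: float
    family: str


def evaluate_cohort(
    table: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "per_roi_comparison",
    min_per_group: int = 2,
) -> CohortResult:
    """Screen every feature of every ROI across the cohort's groups.

    Per (ROI, feature): one ANOVA p-value over all groups and one MWW
    p-value per group pair, with missing feature values dropped per test.
    Bonferroni and BH corrections are applied within each family
    (default: the features of one ROI for one comparison). ``summary``
    counts significant features per (ROI, comparison, correction), the
    reporting unit of the screening.
    """
    if family not in FAMILIES:
        raise ParameterError(f"family must be one of {FAMILIES}")
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    group_labels = sorted(table["group"].astype(str).unique())
    if len(group_labels) < 2:
        raise TableFormatError("cohort must contain at least two groups")
    comparisons = ["anova"] + [f"{a}_vs_{b}" for a, b in combinations(group_labels, 2)]

    records = []
    for roi_id, roi_rows in table.groupby("roi_id", sort=True):
        by_group = {
            g: roi_rows[roi_rows["group"].astype(str) == g] for g in group_labels
        }
        for feature in FEATURE_NAMES:
            samples = {
                g: rows[feature].dropna().to_numpy() for g, rows in by_group.items()
            }
            usable = {g: s for g, s in samples.items() if len(s) >= min_per_group}
            for comp in comparisons:
                if comp == "anova":
                    if len(usable) == len(group_labels):
                        p = anova_f(list(usable.values()))
                    else:
                        p = float("nan")
                        logger.warning(
                            "ANOVA skipped for %s/%s: group with <%d usable values",
                            roi_id, feature, min_per_group,
                        )
                else:
                    a, b = comp.split("_vs_")
                    if a in usable and b in usable:
                        p = mww(usable[a], usable[b])
                    else:
                        p = float("nan")
                        logger.warning(
                            "MWW %s skipped for %s/%s: too few usable values",
                            comp, roi_id, feature,
                        )
                records.append(
                    {"feature": feature, "roi_id": roi_id, "comparison": comp, "p_raw": p}
                )
    tests = pd.DataFrame.from_records(records)

    tests["p_bonferroni"] = np.nan
    tests["p_bh"] = np.nan
    fam_cols = ["roi_id", "comparison"] if family == "per_roi_comparison" else ["comparison"]
    for _, idx in tests.groupby(fam_cols, sort=False).groups.items():
        p = tests.loc[idx, "p_raw"].to_numpy()
        tests.loc[idx, "p_bonferroni"] = bonferroni(p, alpha)[0]
        tests.loc[idx, "p_bh"] = bh(p, alpha)[0]
    tests["sig_raw"] = tests["p_raw"] < alpha
    tests["sig_bonferroni"] = tests["p_bonferroni"] < alpha
    tests["sig_bh"] = tests["p_bh"] < alpha

    summary = (
        tests.groupby(["roi_id", "comparison"], sort=True)[
            ["sig_raw", "sig_bonferroni", "sig_bh"]
        ]
        .sum()
        .astype(int)
        .reset_index()
        .rename(
            columns={
                "sig_raw": "n_sig_raw",
                "sig_bonferroni": "n_sig_bonferroni",
                "sig_bh": "n_sig_bh",
            }
        )
    )
    return CohortResult(tests=tests, summary=summary, alpha=alpha, family=family)
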