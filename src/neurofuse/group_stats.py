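"""Two-group inference: normality screening with log-transform fallback,
Welch t / Mann-Whitney routing, Benjamini-Hochberg FDR within feature
families, and Cohen's d effect sizes."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    feature: str
    family: str
    test: str  # "t" | "mann_whitney"
    log_transformed: bool
    statistic: float
    p_raw: float
    p_fdr: float
    cohens_d: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def _normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    # Lilliefors-corrected KS (normal with estimated parameters).
    _, p = lilliefors(x, dist="norm")
    return p > alpha


def normality_route(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> tuple[str, bool]:
    """Pick the test: ``("t" | "mann_whitney", log_transform_applied)``.

    Both groups must pass a Lilliefors KS screen at ``alpha``; a failing
    all-positive pair is log-transformed and retested; anything else routes
    to Mann-Whitney.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if min(a.size, b.size) < 4:
        raise ValueError("need at least 4 observations per group")
    if _normal(a, alpha) and _normal(b, alpha):
        return "t", False
    if a.min() > 0 and b.min() > 0:
        la, lb = np.log(a), np.log(b)
        if _normal(la, alpha) and _normal(lb, alpha):
            return "t", True
    return "mann_whitney", False


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """(mean_a - mean_b) / pooled SD, pooled with n-1 weights."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if min(a.size, b.size) < 2:
        raise ValueError("need at least 2 observations per group")
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def group_compare_table(
    features: pd.DataFrame,
    group_col: str = "group",
    family_col: str = "family",
    feature_col: str = "feature",
    value_col: str = "value",
    q: float = 0.05,
    global_fdr: bool = False,
) -> pd.DataFrame:
    """Route, test, and FDR-correct every feature of a long-format table.

    ``features`` holds one row per (subject, feature) with a two-level group
    column; the first group in sorted order is treated as group A (effect
    sign = A - B). FDR correction is applied within each feature family
    unless ``global_fdr``.
    """
    groups = sorted(features[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    rows: list[TestResult] = []
    for (family, feature), chunk in features.groupby([family_col, feature_col], sort=False):
        a = chunk.loc[chunk[group_col] == ga, value_col].to_numpy(dtype=np.float64)
        b = chunk.loc[chunk[group_col] == gb, value_col].to_numpy(dtype=np.float64)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if min(a.size, b.size) < 4 or (a.std() == 0 and b.std() == 0):
            log.info("skipping constant/short feature %s/%s", family, feature)
            continue
        test, logged = normality_route(a, b)
        ta, tb = (np.log(a), np.log(b)) if logged else (a, b)
        if test == "t":
            stat, p = stats.ttest_ind(ta, tb, equal_var=False)
        else:
            stat, p = stats.mannwhitneyu(ta, tb, alternative="two-sided")
        rows.append(
            TestResult(
                feature=str(feature), family=str(family), test=test,
                log_transformed=logged, statistic=float(stat), p_raw=float(p),
                p_fdr=float("nan"), cohens_d=cohens_d(a, b),
                mean_a=float(a.mean()), mean_b=float(b.mean()),
                sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                n_a=int(a.size), n_b=int(b.size),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return df
    if global_fdr:
        df["p_fdr"], df["significant"] = fdr_bh(df["p_raw"].to_numpy(), q)
    else:
        df["significant"] = False
        for fam, idx in df.groupby("family").groups.items():
            adj, rej = fdr_bh(df.loc[idx, "p_raw"].to_numpy(), q)
            df.loc[idx, "p_fdr"] = adj
            df.loc[idx, "significant"] = rej
    return df
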