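"""Group comparisons and clinical-severity correlations.

Disease-group differences in patient-level features are tested with
two-tailed Mann-Whitney U tests (exact enumeration for small samples,
tie-corrected normal approximation otherwise) under a Bonferroni family
threshold.  Feature-severity relationships use Spearman correlations
with Monte Carlo permutation p-values (5000 shuffles by default, add-one
rule) and Benjamini-Hochberg false-discovery-rate control.

Clinical severity scores are normalized to percent of the maximum of
their scale: UPDRS-III total (108), UPDRS-III hypokinetic items 23-26
(32), TWSTRS (85), BFMDRS (120).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Maximum attainable raw score per clinical scale.
SCALE_MAX = {
    "UPDRSIII_total": 108.0,
    "UPDRSIII_hypokinetic": 32.0,
    "TWSTRS": 85.0,
    "BFMDRS": 120.0,
}

#: Sample-size bound below which the MWU test enumerates exactly.
MWU_EXACT_MAX_N = 12

DEFAULT_N_PERM = 5000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome."""

    feature: str
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False
    method: str = ""


def normalize_score(raw: float, scale: str) -> float:
    """Normalize a raw clinical score to percent of its scale maximum."""
    if scale not in SCALE_MAX:
        raise ValueError(f"unknown scale {scale!r}; one of {sorted(SCALE_MAX)}")
    mx = SCALE_MAX[scale]
    if not (0.0 <= raw <= mx):
        raise ValueError(f"raw score {raw} outside [0, {mx}] for {scale}")
    return 100.0 * raw / mx


def _mwu_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x (rank-sum form, average ranks for ties)."""
    nx = x.size
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def _mwu_exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-tailed p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx, n = x.size, pooled.size
    center = nx * (n - nx) / 2.0
    d_obs = abs(u_obs - center) - 1e-12
    offset = nx * (nx + 1) / 2.0
    count = 0
    for idx in combinations(range(n), nx):
        u = ranks[list(idx)].sum() - offset
        if abs(u - center) >= d_obs:
            count += 1
    return count / comb(n, nx)


def _mwu_asymptotic_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    nx, ny = x.size, y.size
    n = nx + ny
    mu = nx * ny / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    d = abs(u_obs - mu)
    z = max(d - 0.5, 0.0) / sqrt(var)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return min(1.0, max(0.0, p))


def mwu_test(x, y, feature: str = "") -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration of all rank assignments when the pooled sample has
    at most 12 observations, tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    u_obs = _mwu_u(x, y)
    if x.size + y.size <= MWU_EXACT_MAX_N:
        p = _mwu_exact_p(x, y, u_obs)
        method = "mwu_exact"
    else:
        p = _mwu_asymptotic_p(x, y, u_obs)
        method = "mwu_asymptotic"
    return TestResult(feature, u_obs, p, method=method)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance threshold alpha/m (4 decimals)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return round(alpha / m, 4)


def spearman_perm(x, y, n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                  feature: str = "") -> TestResult:
    """Spearman correlation with a Monte Carlo permutation p-value.

    rho is the Pearson correlation of average ranks.  One sample is
    randomly shuffled ``n_perm`` times to form the null distribution;
    the two-sided p-value uses the add-one rule
    (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1), which never
    returns zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rx = rankdata(x)
    ry = rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.linalg.norm(rx_c) * np.linalg.norm(ry_c)
    rho_obs = float(rx_c @ ry_c / denom)

    rng = np.random.default_rng(seed)
    n = x.size
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    rho_perm = (ry_c[perm] @ rx_c) / denom
    count = int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
    p = (1 + count) / (n_perm + 1)
    return TestResult(feature, rho_obs, p, method=f"spearman_perm_{n_perm}")


def bh_fdr(p_values, alpha: float = DEFAULT_ALPHA
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject, p_adjusted); adjusted p-values are monotone
    non-decreasing in the raw-p ranking.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def run_group_comparison(pd_summaries: pd.DataFrame,
                         dys_summaries: pd.DataFrame,
                         features: list[str],
                         alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Disease-group comparison of patient-level features.

    One MWU test per feature on the patient-level summary values; the
    family significance threshold is Bonferroni alpha / n_features.
    Returns a table with one row per feature.
    """
    if len(pd_summaries) < 2 or len(dys_summaries) < 2:
        raise ValueError("need at least 2 patients per group")
    thresh = bonferroni_threshold(alpha, len(features))
    rows = []
    for feat in features:
        x = pd_summaries[feat].to_numpy(dtype=float)
        y = dys_summaries[feat].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            res = TestResult(feat, x.size * y.size / 2.0, 1.0,
                             method="mwu_degenerate")
        else:
            res = mwu_test(x, y, feature=feat)
        rows.append({
            "feature": feat,
            "group_pd_n": x.size,
            "group_dystonia_n": y.size,
            "statistic_u": res.statistic,
            "median_pd": float(np.median(x)),
            "median_dystonia": float(np.median(y)),
            "p_raw": res.p_raw,
            "family_threshold": thresh,
            "significant": res.p_raw < thresh,
            "method": res.method,
        })
    return pd.DataFrame(rows)


def run_clinical_correlations(summaries: pd.DataFrame, features: list[str],
                              n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                              alpha: float = DEFAULT_ALPHA,
                              family: str = "combined") -> pd.DataFrame:
    """Per-disease feature vs. clinical-severity correlations.

    For each disease group, each feature is correlated with the
    normalized clinical score via :func:`spearman_perm` (shuffling within
    the disease group), then Benjamini-Hochberg correction is applied
    across the tested family — all disease x feature tests together by
    default, or per disease with ``family="per_disease"``.

    Patients with missing scores are excluded with a logged warning.
    """
    if family not in ("combined", "per_disease"):
        raise ValueError("family must be 'combined' or 'per_disease'")
    df = summaries.copy()
    missing = df["clinical_score_pct"].isna()
    if missing.any():
        logger.warning("excluding %d patients with missing clinical scores",
                       int(missing.sum()))
        df = df[~missing]
    rows = []
    rng = np.random.default_rng(seed)
    for disease, grp in df.groupby("disease", sort=True):
        if len(grp) < 5:
            raise ValueError(
                f"need at least 5 scored patients in group {disease!r}, "
                f"got {len(grp)}")
        scores = grp["clinical_score_pct"].to_numpy(dtype=float)
        for feat in features:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = spearman_perm(grp[feat].to_numpy(dtype=float), scores,
                                n_perm=n_perm, seed=sub_seed, feature=feat)
            rows.append({
                "disease": disease,
                "feature": feat,
                "n": len(grp),
                "rho": res.statistic,
                "p_raw": res.p_raw,
                "method": res.method,
                "seed": sub_seed,
            })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    out["significant"] = False
    if family == "combined":
        rej, padj = bh_fdr(out["p_raw"].to_numpy(), alpha)
        out["p_adjusted"], out["significant"] = padj, rej
    else:
        for disease in out["disease"].unique():
            m = out["disease"] == disease
            rej, padj = bh_fdr(out.loc[m, "p_raw"].to_numpy(), alpha)
            out.loc[m, "p_adjusted"] = padj
            out.loc[m, "significant"] = rej
    return out
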