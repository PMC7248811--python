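"""Univariate group comparison between time-to-delivery classes.

Every EHG feature and obstetric covariate is compared between the
imminent-labor and non-imminent groups with the two-sided Wilcoxon
rank-sum (Mann-Whitney) test at alpha = 0.05. p-values are reported raw,
without multiple-testing correction, matching common practice for these
descriptive cohort tables; a Benjamini-Hochberg flag is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .features import FEATURE_NAMES, OBSTETRIC_NAMES

ALPHA = 0.05
EXACT_MAX_N = 20  # combined sample size up to which the test enumerates


@dataclass
class GroupComparison:
    """One row of the group-comparison table."""

    feature_name: str
    mean_a: float
    sd_a: float
    median_a: float
    mean_b: float
    sd_b: float
    median_b: float
    p_value: float
    significant: bool


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (midranks for ties).

    Enumerates every assignment of the pooled ranks to group A and counts
    those whose rank sum deviates from the null mean at least as much as
    observed. Exact for combined n <= 20 (at most C(20,10) ~ 1.8e5
    assignments), ties handled through midranks.
    """
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    n_a = len(a)
    n = len(pooled)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9  # guard float noise on midrank sums
    count = 0
    total = comb(n, n_a)
    for idx in combinations(range(n), n_a):
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            count += 1
    return count / total


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    feature_name: str = "",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Wilcoxon rank-sum comparison of one variable between two groups.

    Exact enumeration when the combined sample size is at most 20;
    otherwise the normal approximation with tie correction (and
    continuity correction), which is the regime of the emulated cohort
    (n = 140).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if len(a) + len(b) <= EXACT_MAX_N:
        p = _exact_rank_sum_p(a, b)
    else:
        _, p = sstats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(min(p, 1.0))
    return GroupComparison(
        feature_name=feature_name,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        median_a=float(np.median(a)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        median_b=float(np.median(b)),
        p_value=p,
        significant=bool(p < alpha),
    )


def feature_table(
    features: pd.DataFrame,
    obstetric: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Group-comparison table: 23 EHG features + 6 obstetric covariates.

    ``labels`` is the binary imminent-labor indicator aligned with the
    rows of both tables (1 = TTD below the horizon). Output rows follow
    the canonical feature order; columns give mean/SD/median per group
    and the rank-sum p-value with a significance flag. ``fdr=True`` adds
    a Benjamini-Hochberg-adjusted column (off by default).
    """
    y = np.asarray(labels).astype(int)
    if len(y) != len(features) or len(y) != len(obstetric):
        raise ValueError("labels must align with the feature and obstetric rows")
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    missing = [c for c in OBSTETRIC_NAMES if c not in obstetric.columns]
    if missing:
        raise ValueError(f"obstetric table missing columns: {missing}")

    rows = []
    for name in FEATURE_NAMES:
        col = features[name].to_numpy(dtype=float)
        rows.append(compare_groups(col[y == 1], col[y == 0], name, alpha))
    for name in OBSTETRIC_NAMES:
        col = obstetric[name].to_numpy(dtype=float)
        rows.append(compare_groups(col[y == 1], col[y == 0], name, alpha))

    table = pd.DataFrame(
        {
            "feature": [r.feature_name for r in rows],
            "mean_pos": [r.mean_a for r in rows],
            "sd_pos": [r.sd_a for r in rows],
            "median_pos": [r.median_a for r in rows],
            "mean_neg": [r.mean_b for r in rows],
            "sd_neg": [r.sd_b for r in rows],
            "median_neg": [r.median_b for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
        }
    )
    if fdr:
        table["p_bh"] = _benjamini_hochberg(table["p_value"].to_numpy())
        table["significant_bh"] = table["p_bh"] < alpha
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def table_to_markdown(table: pd.DataFrame, horizon: int) -> str:
    """Render the comparison table as Markdown (mean +/- SD per group)."""
    lines = [
        f"| Feature | TTD < {horizon} | TTD >= {horizon} | p-value | significant |",
        "|---|---|---|---|---|",
    ]
    for _, r in table.iterrows():
        lines.append(
            f"| {r['feature']} | {r['mean_pos']:.3g} ± {r['sd_pos']:.3g} "
            f"| {r['mean_neg']:.3g} ± {r['sd_neg']:.3g} "
            f"| {r['p_value']:.3g} | {'*' if r['significant'] else ''} |"
        )
    return "\n".join(lines)
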