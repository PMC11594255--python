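"""Baseline cohort statistics: distribution-gated summaries and
nonparametric two-group comparison.

Numeric variables are summarized as mean +/- SD with a t-test when every
group passes Shapiro-Wilk normality at alpha = 0.05, otherwise as median
(IQR) with Mann-Whitney U (two groups) or Kruskal-Wallis (more). Categorical
variables are reported as counts and percentages.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screen import kruskal_wallis

MannWhitneyResult = namedtuple("MannWhitneyResult", ["u", "u_complement", "rank_sum_x", "p_value"])

_EXACT_LIMIT = 16  # total n at or below which the exact null is enumerated


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U via mid-ranks.

    The exact null distribution is used for small tie-free samples
    (total n <= 16); otherwise a tie-corrected normal approximation without
    continuity correction, so identical samples give p = 1 exactly. Both U
    (for x) and its complement U' = n_x*n_y - U are reported, along with the
    rank sum W_x = U + n_x(n_x+1)/2 since the "W" convention varies between
    software packages.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= _EXACT_LIMIT:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    u = float(res.statistic)
    return MannWhitneyResult(
        u=u,
        u_complement=float(x.size * y.size - u),
        rank_sum_x=float(u + x.size * (x.size + 1) / 2.0),
        p_value=min(float(res.pvalue), 1.0),
    )


def percent(count: int, total: int, decimals: int = 1) -> float:
    """A printed-table percentage: 100*count/total rounded to ``decimals``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


@dataclass
class BaselineSummary:
    variable: str
    kind: str  # "numeric" or "categorical"
    groups: dict[str, dict] = field(default_factory=dict)
    test_used: str = "none"
    statistic: float = float("nan")
    p_value: float = float("nan")


def _numeric_group_summary(v: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "n": int(v.size),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
        "median": float(med),
        "iqr": float(q3 - q1),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
    }


def summarize_baseline(
    metadata: pd.DataFrame, variables: list[str], group_var: str, alpha: float = 0.05
) -> list[BaselineSummary]:
    """Table-1-style summaries of ``variables`` split by ``group_var``."""
    if group_var not in metadata.columns:
        raise ValueError(f"group variable {group_var!r} not in metadata")
    out: list[BaselineSummary] = []
    group_levels = sorted(metadata[group_var].dropna().astype(str).unique().tolist())
    for var in variables:
        if var not in metadata.columns:
            raise ValueError(f"variable {var!r} not in metadata")
        col = metadata[var]
        if pd.api.types.is_numeric_dtype(col):
            summary = BaselineSummary(var, "numeric")
            samples = []
            all_normal = True
            for g in group_levels:
                v = col[metadata[group_var].astype(str) == g].dropna().to_numpy(dtype=float)
                if v.size == 0:
                    continue
                summary.groups[g] = _numeric_group_summary(v)
                samples.append(v)
                if v.size >= 3 and np.unique(v).size > 1:
                    if stats.shapiro(v).pvalue < alpha:
                        all_normal = False
                else:
                    all_normal = False  # too small to certify normality
            if len(samples) >= 2:
                if all_normal and len(samples) == 2:
                    t = stats.ttest_ind(samples[0], samples[1])
                    summary.test_used = "t_test"
                    summary.statistic, summary.p_value = float(t.statistic), float(t.pvalue)
                elif len(samples) == 2:
                    r = mann_whitney_u(samples[0], samples[1])
                    summary.test_used = "mann_whitney"
                    summary.statistic, summary.p_value = r.u, r.p_value
                else:
                    h, p = kruskal_wallis(samples)
                    summary.test_used = "kruskal_wallis"
                    summary.statistic, summary.p_value = h, p
            out.append(summary)
        else:
            summary = BaselineSummary(var, "categorical")
            for g in group_levels:
                sub = col[metadata[group_var].astype(str) == g].dropna().astype(str)
                total = int(sub.size)
                counts = sub.value_counts().to_dict()
                summary.groups[g] = {
                    "n": total,
                    "counts": {k: int(v) for k, v in counts.items()},
                    "percent": {k: percent(int(v), total) for k, v in counts.items()}
                    if total
                    else {},
                }
            out.append(summary)
    return out
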