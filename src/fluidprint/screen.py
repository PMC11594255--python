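"""Per-bin Kruskal-Wallis screening across groups with percentile bands.

Each retained spectral bin is tested independently for a location difference
across the study groups (rank-based Kruskal-Wallis H, tie-corrected,
chi-square tail with groups-1 degrees of freedom). Per-group medians and
5-95% percentile bands summarize the bin distributions for overlay plots.
No multiple-testing correction is applied by default, mirroring the per-bin
p < 0.05 highlighting convention; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BucketTable


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical pooled data carries no rank information and returns
    (H=0, p=1) instead of an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class BinScreenResult:
    bin_center_ppm: float
    H: float
    p_value: float
    significant: bool
    per_group: dict[str, tuple[float, float, float]]  # label -> (median, p5, p95)


def screen_bins(
    table: BucketTable | np.ndarray,
    labels,
    alpha: float = 0.05,
    bin_centers: np.ndarray | None = None,
    adjust: str | None = None,
) -> list[BinScreenResult]:
    """Kruskal-Wallis screen of every retained bin, with 5/50/95 percentiles
    per group (linear-interpolation quantiles).

    ``adjust="bh"`` applies Benjamini-Hochberg to the p-values before the
    significance call (off by default).
    """
    if isinstance(table, BucketTable):
        X = table.values
        centers = table.bin_centers_ppm
    else:
        X = np.asarray(table, dtype=float)
        centers = np.asarray(bin_centers, dtype=float) if bin_centers is not None else np.arange(X.shape[1], dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if labels.size != X.shape[0]:
        raise ValueError("labels must align with table rows")
    group_names = sorted(set(labels.tolist()))
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups to screen")
    masks = {g: labels == g for g in group_names}
    if any(m.sum() < 1 for m in masks.values()):
        raise ValueError("every group needs at least one sample")

    hs = np.empty(X.shape[1])
    ps = np.empty(X.shape[1])
    bands: list[dict[str, tuple[float, float, float]]] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        hs[j], ps[j] = kruskal_wallis([col[masks[g]] for g in group_names])
        per_group = {}
        for g in group_names:
            p5, med, p95 = np.percentile(col[masks[g]], [5, 50, 95])
            per_group[g] = (float(med), float(p5), float(p95))
        bands.append(per_group)

    if adjust == "bh":
        padj = _benjamini_hochberg(ps)
    elif adjust is None:
        padj = ps
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        BinScreenResult(float(centers[j]), float(hs[j]), float(ps[j]), bool(padj[j] < alpha), bands[j])
        for j in range(X.shape[1])
    ]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def significant_fraction(results: list[BinScreenResult]) -> float:
    """Fraction of screened bins flagged significant."""
    if not results:
        raise ValueError("no screen results given")
    return sum(r.significant for r in results) / len(results)
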