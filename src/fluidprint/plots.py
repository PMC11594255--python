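"""Figure-style plotting helpers: canonical scatter, screening overlay,
QEA dot plot. Each returns the matplotlib Figure; callers decide whether to
save or show."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .enrichment import EnrichmentResult
from .screen import BinScreenResult

_GROUP_COLORS = {"G12.0": "tab:red", "G12.1": "tab:blue", "HEALTHY": "tab:purple"}


def plot_canonical_scatter(projections: np.ndarray, labels, ax=None):
    """2-D scatter of samples in canonical space, colored by class."""
    labels = np.asarray([str(l) for l in labels])
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    P = np.atleast_2d(projections)
    y = P[:, 1] if P.shape[1] > 1 else np.zeros(P.shape[0])
    for g in sorted(set(labels.tolist())):
        m = labels == g
        ax.scatter(P[m, 0], y[m], label=g, s=18, alpha=0.8, color=_GROUP_COLORS.get(g))
    ax.set_xlabel("canonical 1")
    ax.set_ylabel("canonical 2" if P.shape[1] > 1 else "")
    ax.legend(frameon=False)
    return ax.figure


def plot_screen_overlay(results: list[BinScreenResult], ax=None):
    """Median lines with 5-95% bands per group; significant bins shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    centers = np.array([r.bin_center_ppm for r in results])
    order = np.argsort(centers)
    centers = centers[order]
    groups = sorted(results[0].per_group)
    for g in groups:
        med = np.array([results[i].per_group[g][0] for i in order])
        p5 = np.array([results[i].per_group[g][1] for i in order])
        p95 = np.array([results[i].per_group[g][2] for i in order])
        color = _GROUP_COLORS.get(g)
        ax.plot(centers, med, lw=0.8, label=g, color=color)
        ax.fill_between(centers, p5, p95, alpha=0.2, color=color, linewidth=0)
    sig = np.array([results[i].significant for i in order])
    if sig.any():
        ylim = ax.get_ylim()
        ax.fill_between(centers, *ylim, where=sig, color="pink", alpha=0.3, linewidth=0)
        ax.set_ylim(ylim)
    ax.invert_xaxis()  # NMR display convention
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("bin intensity")
    ax.legend(frameon=False, fontsize=8)
    return ax.figure


def plot_qea_dots(results: list[EnrichmentResult], top_n: int = 25, ax=None):
    """-log10(p) per pathway, dot size proportional to the enrichment ratio."""
    shown = results[:top_n]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(shown) + 1.5))
    ys = np.arange(len(shown))[::-1]
    logp = [-np.log10(max(r.p_value, 1e-300)) for r in shown]
    sizes = [40 * max(r.enrichment_ratio, 0.1) for r in shown]
    ax.scatter(logp, ys, s=sizes, c=logp, cmap="viridis")
    ax.set_yticks(ys)
    ax.set_yticklabels([r.pathway_name for r in shown], fontsize=7)
    ax.set_xlabel("-log10(p)")
    return ax.figure
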