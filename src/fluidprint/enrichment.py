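"""Quantitative enrichment analysis (QEA) over metabolite sets.

Concentrations are first normalized per biofluid: urine is expressed per
mol creatinine (the creatinine column is consumed in the process), all
fluids are then autoscaled per metabolite (mean 0, SD 1). For each pathway
(metabolite set) a Globaltest-style Q statistic measures the association
between the set's concentration profile and a two-level clinical outcome in
a linear model:

    Q = z' X X' z / (m * mean(z^2)),

with z the centered outcome indicator and X the samples x members scaled
matrix. Significance comes from an outcome-permutation null; the enrichment
ratio is Q_observed / E[Q_null], so a ratio near 1 means "no enrichment".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .core import MetaboliteTable, check_biofluid

_PUNCT = re.compile(r"[^0-9a-z]+")


def _canon(name: str) -> str:
    """Case-insensitive, punctuation-free key for metabolite name matching."""
    return _PUNCT.sub("", name.lower())


@dataclass
class PathwayLibrary:
    """Named metabolite sets (pathways), e.g. parsed from a GMT file."""

    sets: dict[str, list[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"pathway {name!r} has no members")


@dataclass
class EnrichmentResult:
    pathway_name: str
    n_members_measured: int
    Q: float
    p_value: float
    enrichment_ratio: float
    member_names: list[str]


def normalize_for_qea(table: MetaboliteTable, biofluid: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Normalize a concentration table for enrichment analysis.

    Urine: each metabolite divided by the same sample's creatinine (x1000,
    mmol/mol creatinine), creatinine column dropped; then autoscaling.
    Plasma/CSF: autoscaling only. Zero-variance metabolites are dropped with
    a warning. Returns (scaled matrix, retained metabolite names).
    """
    biofluid = check_biofluid(biofluid or table.biofluid)
    X = table.concentrations.astype(float).copy()
    names = list(table.metabolite_names)
    if biofluid == "urine":
        if "creatinine" not in names:
            raise ValueError("urine table lacks a creatinine column")
        ci = names.index("creatinine")
        crea = X[:, ci]
        bad = [table.sample_ids[i] for i in np.flatnonzero(~(crea > 0))]
        if bad:
            raise ValueError(f"creatinine missing or zero for samples: {bad}")
        X = np.delete(X, ci, axis=1) / crea[:, None] * 1000.0
        names = [n for n in names if n != "creatinine"]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance metabolites: {dropped}", stacklevel=2)
        X, means, sds = X[:, keep], means[keep], sds[keep]
        names = [n for n, k in zip(names, keep) if k]
    return (X - means) / sds, names


def globaltest_q(
    set_matrix: np.ndarray,
    outcome: np.ndarray,
    n_permutations: int = 1999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Globaltest Q for one metabolite set with a permutation p-value.

    ``outcome`` is any two-level (or numeric) vector; it is centered
    internally. Returns (Q, p, null_Q_draws); p uses the standard
    add-one permutation estimator (1 + #{Q_perm >= Q}) / (1 + n_perm).
    """
    X = np.atleast_2d(np.asarray(set_matrix, dtype=float))
    y = np.asarray(outcome)
    if y.dtype.kind in "OUS":  # encode two-level labels as +/-1
        levels = sorted(set(y.tolist()))
        if len(levels) != 2:
            raise ValueError(f"outcome must have exactly 2 levels, got {levels}")
        y = np.where(y == levels[1], 1.0, -1.0)
    y = y.astype(float)
    n, m = X.shape
    if y.size != n:
        raise ValueError("outcome length must match sample count")
    z = y - y.mean()
    z2 = float(z @ z) / n
    if z2 == 0:
        raise ValueError("outcome has a single level; Q undefined")

    def _q(zv: np.ndarray) -> float:
        s = X.T @ zv
        return float(s @ s) / (m * z2)

    q_obs = _q(z)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perms = np.empty(n_permutations)
    for b in range(n_permutations):
        perms[b] = _q(gen.permutation(z))
    p = (1.0 + np.sum(perms >= q_obs)) / (1.0 + n_permutations)
    return q_obs, float(p), perms


def run_qea(
    table: MetaboliteTable,
    labels,
    library: PathwayLibrary,
    biofluid: str | None = None,
    contrast: tuple[str, str] = ("G12.0", "G12.1"),
    min_set_size: int = 2,
    n_permutations: int = 1999,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Quantitative enrichment analysis of every pathway with enough
    measured members, for a two-class contrast.

    Samples outside the contrast classes are dropped. Member matching is
    case-insensitive after punctuation stripping. Results are sorted by
    ascending p (ties broken by descending Q). Sets with fewer than
    ``min_set_size`` measured members are skipped with a warning.
    """
    labels = np.asarray([str(l) for l in labels])
    if labels.size != len(table.sample_ids):
        raise ValueError("labels must align with table rows")
    in_contrast = np.isin(labels, list(contrast))
    if not in_contrast.any():
        raise ValueError(f"no samples in contrast {contrast}")
    sub = MetaboliteTable(
        sample_ids=[s for s, m in zip(table.sample_ids, in_contrast) if m],
        metabolite_names=list(table.metabolite_names),
        concentrations=table.concentrations[in_contrast],
        biofluid=table.biofluid,
    )
    y = labels[in_contrast]
    for level in contrast:
        if np.sum(y == level) < 2:
            raise ValueError(f"contrast level {level!r} needs >= 2 samples")
    scaled, names = normalize_for_qea(sub, biofluid)
    col_of = {_canon(n): j for j, n in enumerate(names)}

    results: list[EnrichmentResult] = []
    rng = np.random.default_rng(seed)
    for pathway, members in library.sets.items():
        cols, measured = [], []
        for m in members:
            j = col_of.get(_canon(m))
            if j is not None:
                cols.append(j)
                measured.append(names[j])
        if len(cols) < min_set_size:
            warnings.warn(
                f"skipping {pathway!r}: {len(cols)} measured member(s) < {min_set_size}",
                stacklevel=2,
            )
            continue
        q, p, perms = globaltest_q(scaled[:, cols], y, n_permutations, rng)
        null_mean = float(perms.mean())
        ratio = q / null_mean if null_mean > 0 else float("nan")
        results.append(EnrichmentResult(pathway, len(cols), q, p, ratio, measured))
    if not results:
        raise ValueError(f"no pathway has >= {min_set_size} measured members")
    results.sort(key=lambda r: (r.p_value, -r.Q))
    return results


def top_sets(results: list[EnrichmentResult], n: int = 25) -> list[EnrichmentResult]:
    """The top-n enriched sets (summary-plot selection)."""
    return results[:n]


def venn_overlap(per_fluid_sets: dict[str, set[str] | list[str]]) -> dict[str, dict]:
    """Exact inclusion-exclusion region breakdown for three collections.

    Returns a map region -> {"count", "members"} with seven regions: one per
    single fluid (exclusive), one per pair (exclusive), and "all".
    """
    if len(per_fluid_sets) != 3:
        raise ValueError("venn_overlap expects exactly 3 collections")
    keys = list(per_fluid_sets)
    sets = {k: set(v) for k, v in per_fluid_sets.items()}
    a, b, c = (sets[k] for k in keys)
    regions = {
        keys[0]: a - b - c,
        keys[1]: b - a - c,
        keys[2]: c - a - b,
        f"{keys[0]}&{keys[1]}": (a & b) - c,
        f"{keys[0]}&{keys[2]}": (a & c) - b,
        f"{keys[1]}&{keys[2]}": (b & c) - a,
        "all": a & b & c,
    }
    return {name: {"count": len(s), "members": sorted(s)} for name, s in regions.items()}


def heatmap_order(scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Metabolite ordering for heatmaps: pairwise Euclidean distances
    between metabolite columns, leaf order of average-linkage hierarchical
    clustering. Deterministic.
    """
    X = np.asarray(scaled, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 metabolites to order")
    d = pdist(X.T, metric="euclidean")
    order = leaves_list(linkage(d, method="average"))
    return np.asarray(order), squareform(d)
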