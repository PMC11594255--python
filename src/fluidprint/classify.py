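"""Supervised PCA/CA/k-NN classification with Monte-Carlo cross-validation.

The classification chain is: mean-center the bucket table, reduce it by PCA
(components retained up to a cumulative explained-variance threshold), find
canonical discriminant directions in PC space (generalized eigenproblem of
between- vs within-class scatter), select the discriminant dimension by
sequential MANOVA tests on residual Wilks' lambda (Bartlett chi-square
approximation), then assign classes in canonical space either by lowest
distance to the class center (default) or by k-nearest neighbors.

Monte-Carlo cross-validation (MCCV) repeats stratified random train/test
splits; the *entire* chain, centering included, is refit on each training
portion so no information leaks from held-out samples. Pooled held-out
assignments form a truth x assignment confusion matrix whose row-normalized
diagonal estimates per-class probabilities of correct classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .core import BucketTable

_COND_LIMIT = 1e10
_RIDGE = 1e-6


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude coefficient positive."""
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


def fit_pca(
    values: np.ndarray | BucketTable, variance_threshold: float = 0.95
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Mean-center columns and fit PCA by SVD.

    Returns (column_means, basis, n_pcs, explained_fractions). ``basis`` has
    one orthonormal loading vector per column, up to min(n_samples - 1,
    n_features) components; ``n_pcs`` is the smallest count whose cumulative
    explained-variance fraction reaches the threshold. No unit-variance
    scaling is applied: bucket values share a common intensity scale and
    variance-scaling would inflate noise bins.
    """
    X = values.values if isinstance(values, BucketTable) else np.asarray(values, dtype=float)
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("PCA needs at least 2 samples and 1 column")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    means = X.mean(axis=0)
    Xc = X - means
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("bucket table has zero total variance")
    frac = s**2 / total
    cap = min(n - 1, p)
    basis = _fix_signs(Vt[:cap].T)
    cum = np.cumsum(frac[:cap])
    n_pcs = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_pcs = min(n_pcs, cap)
    return means, basis, n_pcs, frac


def fit_canonical(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, int, np.ndarray, np.ndarray, list[str]]:
    """Canonical discriminant analysis with MANOVA dimension selection.

    Solves B a = lambda W a for between-class scatter B and within-class
    scatter W on the PC scores; directions are normalized to unit pooled
    within-class variance. The number of significant dimensions is chosen by
    sequential Bartlett chi-square tests on residual Wilks' lambda: keep
    adding leading dimensions while the residual test rejects at ``alpha``.

    Returns (canonical_basis, n_canonical, class_centers, manova_pvalues,
    class_order). ``n_canonical`` may be 0 (with a warning) when even the
    first dimension is non-significant.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    classes = sorted(set(labels.tolist()))
    k = len(classes)
    if k < 2:
        raise ValueError("canonical analysis needs at least 2 classes")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"every class needs >= 2 samples, got {counts}")

    mu = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    class_means = np.empty((k, p))
    for i, c in enumerate(classes):
        Xc = X[labels == c]
        m = Xc.mean(axis=0)
        class_means[i] = m
        d = Xc - m
        W += d.T @ d
        dm = (m - mu)[:, None]
        B += Xc.shape[0] * (dm @ dm.T)

    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        warnings.warn(
            f"within-class scatter ill-conditioned (cond={cond:.2e}); ridge-regularizing",
            stacklevel=2,
        )
        W = W + _RIDGE * (np.trace(W) / p) * np.eye(p)

    eigvals, eigvecs = sla.eigh(B, W)
    order = np.argsort(eigvals)[::-1]
    m_dims = min(p, k - 1)
    lam = np.clip(eigvals[order[:m_dims]], 0.0, None)
    A = eigvecs[:, order[:m_dims]]
    # normalize to unit pooled within-class variance along each direction
    denom = np.sqrt(np.einsum("ij,jk,ki->i", A.T, W / (n - k), A))
    denom[denom == 0] = 1.0
    A = _fix_signs(A / denom)

    # sequential Bartlett tests: dimension s tests H0 "dims > s are null"
    pvals = np.empty(m_dims)
    for s in range(m_dims):
        chi2 = (n - 1 - (p + k) / 2.0) * float(np.sum(np.log1p(lam[s:])))
        df = (p - s) * (k - 1 - s)
        pvals[s] = stats.chi2.sf(max(chi2, 0.0), df) if df > 0 else 1.0
    n_canonical = 0
    for s in range(m_dims):
        if pvals[s] < alpha:
            n_canonical += 1
        else:
            break
    if n_canonical == 0:
        warnings.warn("no significant canonical dimension at the given alpha", stacklevel=2)
    centers = class_means @ A
    return A, n_canonical, centers, pvals, classes


@dataclass
class FingerprintModel:
    """A fitted PCA/CA classification model (all parameters fold-local)."""

    column_means: np.ndarray
    pca_basis: np.ndarray
    n_pcs: int
    canonical_basis: np.ndarray
    n_canonical: int
    class_centers: np.ndarray
    class_labels: list[str]
    rule: str = "nearest_center"
    k: int = 5
    training_projections: np.ndarray | None = None
    training_labels: np.ndarray | None = None
    manova_pvalues: np.ndarray | None = None
    explained_variance: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_dims_used(self) -> int:
        # classification needs at least one coordinate even if the MANOVA
        # found no significant separation
        return max(1, self.n_canonical)

    def project(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.column_means.size:
            raise ValueError(
                f"sample has {rows.shape[1]} bins, model expects {self.column_means.size}"
            )
        t = (rows - self.column_means) @ self.pca_basis[:, : self.n_pcs]
        return t @ self.canonical_basis[:, : self.n_dims_used]


def fit_fingerprint(
    values: np.ndarray,
    labels: np.ndarray,
    variance_threshold: float = 0.95,
    alpha: float = 0.05,
    rule: str = "nearest_center",
    k: int = 5,
) -> FingerprintModel:
    """Fit the full PCA -> CA chain on a training bucket table."""
    if rule not in ("nearest_center", "knn"):
        raise ValueError(f"unknown rule {rule!r}")
    means, basis, n_pcs, frac = fit_pca(values, variance_threshold)
    scores = (np.asarray(values, dtype=float) - means) @ basis[:, :n_pcs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A, n_can, centers, pvals, classes = fit_canonical(scores, labels, alpha)
    model = FingerprintModel(
        column_means=means,
        pca_basis=basis,
        n_pcs=n_pcs,
        canonical_basis=A,
        n_canonical=n_can,
        class_centers=centers,
        class_labels=classes,
        rule=rule,
        k=k,
        manova_pvalues=pvals,
        explained_variance=frac,
    )
    proj = model.project(np.asarray(values, dtype=float))
    model.training_projections = proj
    model.training_labels = np.asarray(labels)
    model.class_centers = np.vstack(
        [proj[model.training_labels == c].mean(axis=0) for c in classes]
    )
    return model


def classify(sample_row: np.ndarray, model: FingerprintModel) -> tuple[str, dict[str, float], bool]:
    """Assign one sample; returns (label, per-class distance/vote share, tie flag).

    Ties (equidistant centers, or tied k-NN votes) are broken by
    lexicographic class-label order and flagged.
    """
    z = model.project(sample_row)[0]
    if model.rule == "nearest_center":
        dists = {
            c: float(np.linalg.norm(z - model.class_centers[i, : model.n_dims_used]))
            for i, c in enumerate(model.class_labels)
        }
        best = min(dists.values())
        winners = sorted(c for c, d in dists.items() if np.isclose(d, best, rtol=0, atol=1e-12))
        return winners[0], dists, len(winners) > 1
    if model.training_projections is None:
        raise ValueError("knn rule requires training projections in the model")
    d = np.linalg.norm(model.training_projections - z, axis=1)
    nearest = np.argsort(d, kind="stable")[: model.k]
    votes: dict[str, float] = {c: 0.0 for c in model.class_labels}
    for i in nearest:
        votes[str(model.training_labels[i])] += 1.0 / model.k
    top = max(votes.values())
    winners = sorted(c for c, v in votes.items() if v == top)
    return winners[0], votes, len(winners) > 1


@dataclass
class ConfusionMatrix:
    """Truth (rows) x assignment (columns) counts with row-normalized
    proportions; diagonal entries estimate per-class probabilities of
    correct classification."""

    class_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.class_labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be a square labels x labels matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def proportions(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row_sums > 0, self.counts / row_sums, np.nan)

    def diagonal(self) -> np.ndarray:
        return np.diag(self.proportions)


def _stratified_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        n_c = idx.size
        n_test = max(1, int(round(test_fraction * n_c)))
        n_test = min(n_test, n_c - 2)  # CA needs >= 2 training samples per class
        if n_test < 1:
            raise ValueError(f"class {c!r} has too few samples ({n_c}) for a split")
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def mccv(
    table: BucketTable | np.ndarray,
    labels,
    n_iterations: int = 500,
    test_fraction: float = 0.2,
    variance_threshold: float = 0.95,
    alpha: float = 0.05,
    rule: str = "nearest_center",
    k: int = 5,
    seed: int = 0,
) -> tuple[ConfusionMatrix, list[dict]]:
    """Monte-Carlo cross-validation of the PCA/CA classification chain.

    Each iteration draws a stratified random split, refits the whole chain
    on the training portion only, classifies the held-out samples, and
    accumulates truth x assignment counts. Reproducible from ``seed``.
    """
    X = table.values if isinstance(table, BucketTable) else np.asarray(table, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if labels.size != X.shape[0]:
        raise ValueError("labels length must match table rows")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    classes = sorted(set(labels.tolist()))
    counts_of = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts_of.values()) < 3:
        raise ValueError(f"every class needs >= 3 samples for MCCV splits, got {counts_of}")
    lut = {c: i for i, c in enumerate(classes)}
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    records: list[dict] = []
    for it in range(n_iterations):
        train, test = _stratified_split(labels, test_fraction, rng)
        model = fit_fingerprint(
            X[train], labels[train], variance_threshold=variance_threshold,
            alpha=alpha, rule=rule, k=k,
        )
        correct = 0
        for i in test:
            pred, _, _ = classify(X[i], model)
            counts[lut[labels[i]], lut[pred]] += 1
            correct += pred == labels[i]
        records.append(
            {
                "iteration": it,
                "n_test": int(test.size),
                "accuracy": correct / test.size,
                "n_pcs": model.n_pcs,
                "n_canonical": model.n_canonical,
            }
        )
    return ConfusionMatrix(classes, counts), records


def sensitivity_specificity(
    cm: ConfusionMatrix, positive_classes: set[str] | list[str]
) -> tuple[float, float]:
    """Pooled sensitivity/specificity for a subset of classes marked positive.

    Sensitivity: fraction of positive-class samples assigned to *any*
    positive class; specificity: fraction of negative-class samples assigned
    to negative classes. Empty truth rows yield NaN with a warning.
    """
    pos = set(positive_classes)
    all_labels = set(cm.class_labels)
    if not pos or not pos < all_labels:
        raise ValueError("positive_classes must be a non-empty proper subset of class labels")
    pos_idx = [i for i, c in enumerate(cm.class_labels) if c in pos]
    neg_idx = [i for i, c in enumerate(cm.class_labels) if c not in pos]
    pos_total = cm.counts[pos_idx].sum()
    neg_total = cm.counts[neg_idx].sum()
    if pos_total == 0 or neg_total == 0:
        warnings.warn("empty class row; sensitivity/specificity undefined", stacklevel=2)
    sens = cm.counts[np.ix_(pos_idx, pos_idx)].sum() / pos_total if pos_total else float("nan")
    spec = cm.counts[np.ix_(neg_idx, neg_idx)].sum() / neg_total if neg_total else float("nan")
    return float(sens), float(spec)
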