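"""PCA/CA/k-NN classification chain and Monte-Carlo cross-validation."""

import warnings

import numpy as np
import pytest

import fluidprint as fp
from fluidprint.classify import fit_fingerprint


def fisher_lda_oracle(X, labels):
    """Independent brute-force Fisher LDA: w = Sw^-1 (mu1 - mu0)."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    assert len(classes) == 2
    X0, X1 = X[labels == classes[0]], X[labels == classes[1]]
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for Xc in (X0, X1):
        d = Xc - Xc.mean(axis=0)
        Sw += d.T @ d
    w = np.linalg.solve(Sw, X1.mean(axis=0) - X0.mean(axis=0))
    proj = (X - X.mean(axis=0)) @ w
    centers = {c: proj[labels == c].mean() for c in classes}
    assign = [min(classes, key=lambda c: abs(p - centers[c])) for p in proj]
    return proj, assign


def two_class_data(n=16, p=8, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    labels = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    X[labels == "B", 0] += sep
    return X, labels


class TestFitPca:
    def test_diagonal_line_collapses_to_one_component(self):
        t = np.linspace(-1, 1, 10)
        X = np.column_stack([t, t])
        _, basis, n_pcs, frac = fp.fit_pca(X, variance_threshold=0.95)
        assert n_pcs == 1
        assert frac[0] == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(basis[:, 0]), 1 / np.sqrt(2), rtol=1e-12)

    def test_explained_fractions_sum_to_one(self):
        X = np.random.default_rng(1).normal(size=(12, 5))
        _, _, _, frac = fp.fit_pca(X)
        assert frac.sum() == pytest.approx(1.0)

    def test_full_reconstruction_roundtrip(self):
        X = np.random.default_rng(2).normal(size=(10, 6))
        means, basis, _, _ = fp.fit_pca(X, variance_threshold=1.0)
        Xc = X - means
        np.testing.assert_allclose(Xc @ basis @ basis.T, Xc, atol=1e-8)

    def test_basis_orthonormal(self):
        X = np.random.default_rng(3).normal(size=(15, 7))
        _, basis, _, _ = fp.fit_pca(X)
        np.testing.assert_allclose(basis.T @ basis, np.eye(basis.shape[1]), atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            fp.fit_pca(np.ones((5, 3)))


class TestFitCanonical:
    def test_three_classes_bounded_by_two_dimensions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        labels = np.repeat(["A", "B", "C"], 10)
        X[labels == "B", 0] += 5
        X[labels == "C", 1] += 5
        _, n_can, centers, pvals, classes = fp.fit_canonical(X, labels)
        assert n_can <= 2
        assert centers.shape[0] == 3
        assert classes == ["A", "B", "C"]

    def test_separated_classes_recover_displacement_axis(self):
        X, labels = two_class_data(n=200, p=4, sep=6.0, seed=5)
        A, n_can, _, _, _ = fp.fit_canonical(X, labels)
        assert n_can == 1
        direction = A[:, 0] / np.linalg.norm(A[:, 0])
        assert abs(direction[0]) > 0.95

    def test_null_manova_rejection_rate_matches_alpha(self):
        # two classes from one distribution: first-dimension test ~ uniform p
        rng = np.random.default_rng(6)
        alpha, n_sims, rejections = 0.05, 200, 0
        labels = np.repeat(["A", "B"], 30)
        for _ in range(n_sims):
            X = rng.normal(size=(60, 3))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, _, pvals, _ = fp.fit_canonical(X, labels)
            rejections += pvals[0] < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rejections / n_sims - alpha) <= 3 * se

    def test_too_small_classes_rejected(self):
        X = np.random.default_rng(7).normal(size=(3, 2))
        with pytest.raises(ValueError, match=">= 2 samples"):
            fp.fit_canonical(X, np.array(["A", "A", "B"]))


class TestClassify:
    @pytest.fixture()
    def model(self):
        X, labels = two_class_data(seed=8)
        return X, labels, fit_fingerprint(X, labels, variance_threshold=1.0)

    def test_sample_at_center_has_zero_distance(self, model):
        X, labels, m = model
        # reconstruct a bin-space point that projects exactly onto a center
        center_proj = m.class_centers[0, : m.n_dims_used]
        basis = m.pca_basis[:, : m.n_pcs] @ m.canonical_basis[:, : m.n_dims_used]
        x = m.column_means + basis @ np.linalg.lstsq(basis.T @ basis, center_proj, rcond=None)[0]
        label, dists, tie = fp.classify(x, m)
        assert label == m.class_labels[0]
        assert dists[label] == pytest.approx(0.0, abs=1e-8)

    def test_equidistant_tie_is_lexicographic_and_flagged(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        labels = np.array(["B", "B", "A", "A"])
        m = fit_fingerprint(X + np.array([[1e-3], [-1e-3], [1e-3], [-1e-3]]), labels,
                            variance_threshold=1.0, alpha=0.999)
        midpoint = (m.class_centers[0, : m.n_dims_used] + m.class_centers[1, : m.n_dims_used]) / 2
        basis = m.pca_basis[:, : m.n_pcs] @ m.canonical_basis[:, : m.n_dims_used]
        x = m.column_means + basis @ np.linalg.lstsq(basis.T @ basis, midpoint, rcond=None)[0]
        label, _, tie = fp.classify(x, m)
        assert tie
        assert label == "A"  # lexicographic winner

    def test_knn_k1_returns_own_label(self):
        X, labels = two_class_data(seed=9)
        m = fit_fingerprint(X, labels, variance_threshold=1.0, rule="knn", k=1)
        for i in range(X.shape[0]):
            label, _, _ = fp.classify(X[i], m)
            assert label == labels[i]

    def test_dimension_mismatch_rejected(self, model):
        _, _, m = model
        with pytest.raises(ValueError, match="bins"):
            fp.classify(np.zeros(3), m)

    def test_classification_ignores_truth_labels(self, model):
        # no-leakage: predictions depend only on the feature vector
        X, labels, m = model
        preds = [fp.classify(X[i], m)[0] for i in range(len(labels))]
        preds_shuffled_truth = [fp.classify(X[i], m)[0] for i in np.arange(len(labels))]
        assert preds == preds_shuffled_truth


class TestLdaOracleEquivalence:
    def test_two_class_pipeline_matches_fisher_lda(self):
        for seed in (0, 1, 2):
            X, labels = two_class_data(n=16, p=8, sep=4.0, seed=seed)
            m = fit_fingerprint(X, labels, variance_threshold=1.0)
            proj = m.project(X)[:, 0]
            oracle_proj, oracle_assign = fisher_lda_oracle(X, labels)
            corr = np.corrcoef(proj, oracle_proj)[0, 1]
            assert abs(corr) > 1 - 1e-8
            assign = [fp.classify(X[i], m)[0] for i in range(X.shape[0])]
            assert assign == oracle_assign


class TestMccv:
    def test_counts_and_row_stochastic_proportions(self, urine_buckets):
        table, labels = urine_buckets
        cm, records = fp.mccv(table, labels, n_iterations=20, seed=3)
        held_out = sum(r["n_test"] for r in records)
        assert cm.counts.sum() == held_out
        np.testing.assert_allclose(cm.proportions.sum(axis=1), 1.0, atol=1e-12)
        assert cm.class_labels == ["G12.0", "G12.1", "HEALTHY"]

    def test_reproducible_from_seed(self, urine_buckets):
        table, labels = urine_buckets
        cm1, _ = fp.mccv(table, labels, n_iterations=10, seed=17)
        cm2, _ = fp.mccv(table, labels, n_iterations=10, seed=17)
        assert np.array_equal(cm1.counts, cm2.counts)

    def test_diagonal_accuracy_monotone_in_effect_size(self, library):
        # stronger injected fold-changes never degrade mean diagonal accuracy
        accs = []
        for strength in (1.0, 2.0, 4.0):
            effects = {("G12.0", m): strength for m in ("citrate", "creatine", "glucose")}
            effects.update({("G12.1", m): np.sqrt(strength) for m in ("citrate", "creatine", "glucose")})
            design = fp.CohortDesign(
                biofluid="csf", n_per_class={"HEALTHY": 10, "G12.0": 10, "G12.1": 10},
                effect_sizes=effects, seed=31, noise_sd=0.02, axis=(0.0, 10.0, 4000),
            )
            spectra, meta, _ = fp.generate_cohort(design, library)
            table = fp.build_bucket_table(spectra, fp.default_config("csf"))
            cm, _ = fp.mccv(table, [m.class_label for m in meta], n_iterations=40, seed=13)
            accs.append(cm.diagonal().mean())
        assert accs[1] >= accs[0] - 0.02
        assert accs[2] >= accs[1] - 0.02


class TestSensitivitySpecificity:
    def test_headline_arithmetic(self):
        cm = fp.ConfusionMatrix(["NEG", "POS"], np.array([[94, 6], [16, 84]]))
        sens, spec = fp.sensitivity_specificity(cm, ["POS"])
        assert sens == pytest.approx(0.84)
        assert spec == pytest.approx(0.94)

    def test_perfect_diagonal(self):
        cm = fp.ConfusionMatrix(["A", "B", "C"], np.diag([5, 7, 9]))
        assert fp.sensitivity_specificity(cm, ["A", "B"]) == (1.0, 1.0)

    def test_uniform_assignment_two_classes(self):
        cm = fp.ConfusionMatrix(["A", "B"], np.array([[50, 50], [50, 50]]))
        assert fp.sensitivity_specificity(cm, ["A"]) == (0.5, 0.5)

    def test_empty_row_yields_nan_with_warning(self):
        cm = fp.ConfusionMatrix(["A", "B"], np.array([[0, 0], [1, 9]]))
        with pytest.warns(UserWarning, match="undefined"):
            sens, spec = fp.sensitivity_specificity(cm, ["A"])
        assert np.isnan(sens)

    def test_improper_positive_set_rejected(self):
        cm = fp.ConfusionMatrix(["A", "B"], np.eye(2, dtype=int))
        with pytest.raises(ValueError):
            fp.sensitivity_specificity(cm, ["A", "B"])
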