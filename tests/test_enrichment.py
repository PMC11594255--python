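"""QEA: normalization, Globaltest Q, set ranking, Venn algebra, heatmaps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fluidprint as fp
from fluidprint.io import bundled_pathway_library


def make_table(X, names, biofluid="plasma", ids=None):
    return fp.MetaboliteTable(
        sample_ids=ids or [f"s{i}" for i in range(X.shape[0])],
        metabolite_names=names,
        concentrations=X,
        biofluid=biofluid,
    )


class TestNormalizeForQea:
    def test_autoscaled_columns_are_standardized(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.lognormal(size=(20, 4)), ["a", "b", "c", "d"])
        scaled, names = fp.normalize_for_qea(table)
        assert names == ["a", "b", "c", "d"]
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(scaled.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_creatinine_ratio_cancels_urine_dilution(self):
        base = np.array([[2.0, 4.0, 1.0], [1.0, 3.0, 2.0], [3.0, 1.0, 1.5]])
        doubled = base.copy()
        doubled[0] *= 2  # sample 0: all metabolites AND creatinine doubled
        names = ["alanine", "citrate", "creatinine"]
        s1, _ = fp.normalize_for_qea(make_table(base, names, "urine"))
        s2, _ = fp.normalize_for_qea(make_table(doubled, names, "urine"))
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_creatinine_column_is_consumed(self):
        table = make_table(np.abs(np.random.default_rng(1).normal(size=(6, 3))) + 0.1,
                           ["alanine", "citrate", "creatinine"], "urine")
        _, names = fp.normalize_for_qea(table)
        assert "creatinine" not in names

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(8), np.arange(8.0) + 1])
        table = make_table(X, ["flat", "varies"])
        with pytest.warns(UserWarning, match="flat"):
            scaled, names = fp.normalize_for_qea(table)
        assert names == ["varies"]
        assert scaled.shape == (8, 1)

    def test_missing_creatinine_rejected(self):
        table = make_table(np.ones((4, 2)) + np.eye(4, 2), ["a", "b"], "plasma")
        with pytest.raises(ValueError, match="creatinine"):
            fp.normalize_for_qea(table, biofluid="urine")


class TestGlobaltestQ:
    def test_zero_matrix_gives_zero_q_and_p_one(self):
        y = np.array(["A"] * 5 + ["B"] * 5)
        q, p, _ = fp.globaltest_q(np.zeros((10, 3)), y, n_permutations=99, rng=0)
        assert q == 0.0
        assert p == pytest.approx(1.0)

    def test_perfect_member_maxes_q_and_floors_p(self):
        rng = np.random.default_rng(2)
        y = np.array(["A"] * 10 + ["B"] * 10)
        z = np.where(y == "B", 1.0, -1.0)
        # among unit-variance single members, X = z/|z| attains the maximum
        # Q = (z'x)^2 / z2hat <= |z|^2 * |x|^2 / z2hat (Cauchy-Schwarz)
        X_perfect = (z / np.linalg.norm(z))[:, None]
        q_max, p, _ = fp.globaltest_q(X_perfect, y, n_permutations=199, rng=3)
        for _ in range(10):
            x = rng.normal(size=20)
            x = ((x - x.mean()) / np.linalg.norm(x - x.mean()))[:, None]
            q, _, _ = fp.globaltest_q(x, y, n_permutations=9, rng=4)
            assert q <= q_max + 1e-9
        assert p == pytest.approx(1.0 / 200.0)

    def test_q_invariant_to_member_order_and_sign(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(14, 4))
        y = np.array(["A"] * 7 + ["B"] * 7)
        q0, _, _ = fp.globaltest_q(X, y, n_permutations=9, rng=0)
        q_perm, _, _ = fp.globaltest_q(X[:, ::-1], y, n_permutations=9, rng=0)
        flipped = X.copy()
        flipped[:, 1] *= -1
        q_flip, _, _ = fp.globaltest_q(flipped, y, n_permutations=9, rng=0)
        assert q0 == pytest.approx(q_perm, rel=1e-12)
        assert q0 == pytest.approx(q_flip, rel=1e-12)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(6)
        y = np.array(["A"] * 10 + ["B"] * 10)
        n_reps, hits = 200, 0
        for _ in range(n_reps):
            X = rng.normal(size=(20, 4))
            _, p, _ = fp.globaltest_q(X, y, n_permutations=199, rng=rng)
            hits += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(hits / n_reps - 0.05) <= 3 * se

    def test_single_outcome_level_rejected(self):
        with pytest.raises(ValueError):
            fp.globaltest_q(np.ones((4, 2)), np.array(["A"] * 4), n_permutations=9)


class TestRunQea:
    def test_spiked_set_ranks_first(self):
        rng = np.random.default_rng(7)
        names = ["citrate", "succinate", "alanine", "glycine", "valine"]
        X = rng.lognormal(size=(30, 5))
        labels = np.array(["G12.0"] * 15 + ["G12.1"] * 15)
        X[labels == "G12.0", 0] *= 6.0  # citrate spike
        X[labels == "G12.0", 1] *= 6.0  # succinate spike
        table = make_table(X, names)
        library = fp.PathwayLibrary({
            "spiked pair": ["citrate", "succinate"],
            "decoy one": ["alanine", "glycine"],
            "decoy two": ["glycine", "valine"],
        })
        results = fp.run_qea(table, labels, library, n_permutations=499, seed=1)
        assert results[0].pathway_name == "spiked pair"
        assert results[0].enrichment_ratio > 1.5

    def test_name_matching_is_punctuation_insensitive(self):
        X = np.abs(np.random.default_rng(8).normal(size=(12, 2))) + 0.5
        X[:6] *= 3.0
        table = make_table(X, ["2-Oxoglutarate", "D-Glucose"])
        labels = ["G12.0"] * 6 + ["G12.1"] * 6
        library = fp.PathwayLibrary({"set": ["2 oxoglutarate", "d glucose"]})
        results = fp.run_qea(table, labels, library, n_permutations=99, seed=0)
        assert results[0].n_members_measured == 2

    def test_undersized_sets_skipped_with_warning(self):
        X = np.abs(np.random.default_rng(9).normal(size=(10, 2))) + 0.5
        table = make_table(X, ["alanine", "glycine"])
        labels = ["G12.0"] * 5 + ["G12.1"] * 5
        library = fp.PathwayLibrary({
            "ok": ["alanine", "glycine"],
            "unmeasured": ["caffeine", "xanthine"],
        })
        with pytest.warns(UserWarning, match="unmeasured"):
            results = fp.run_qea(table, labels, library, n_permutations=49, seed=0)
        assert [r.pathway_name for r in results] == ["ok"]

    def test_null_enrichment_ratio_near_one(self):
        rng = np.random.default_rng(10)
        ratios = []
        labels = ["G12.0"] * 10 + ["G12.1"] * 10
        library = fp.PathwayLibrary({"s1": ["m0", "m1"], "s2": ["m2", "m3", "m4"]})
        for rep in range(30):
            X = np.abs(rng.normal(size=(20, 5))) + 0.5
            table = make_table(X, [f"m{i}" for i in range(5)])
            res = fp.run_qea(table, labels, library, n_permutations=99, seed=rep)
            ratios.extend(r.enrichment_ratio for r in res)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)

    def test_bundled_library_loads(self):
        lib = bundled_pathway_library()
        assert "Citrate cycle (TCA cycle)" in lib.sets
        assert len(lib.sets) >= 23


class TestVennOverlap:
    def test_identical_collections_all_in_triple(self):
        names = {f"pathway {i}" for i in range(23)}
        regions = fp.venn_overlap({"urine": names, "plasma": set(names), "csf": set(names)})
        assert regions["all"]["count"] == 23
        assert all(v["count"] == 0 for k, v in regions.items() if k != "all")

    def test_disjoint_collections_have_empty_triple(self):
        regions = fp.venn_overlap({"urine": {"a"}, "plasma": {"b"}, "csf": {"c"}})
        assert regions["all"]["count"] == 0
        assert regions["urine"]["count"] == 1

    @given(
        st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15))
    )
    def test_region_counts_partition_the_union(self, a, b, c):
        regions = fp.venn_overlap({"u": a, "p": b, "c": c})
        total = sum(v["count"] for v in regions.values())
        assert total == len(a | b | c)
        # brute-force oracle: every union element falls in exactly one region
        for x in a | b | c:
            hits = sum(str(x) in v["members"] or x in [m for m in v["members"]]
                       for v in regions.values())
            assert hits == 1

    def test_requires_three_collections(self):
        with pytest.raises(ValueError):
            fp.venn_overlap({"u": set(), "p": set()})


class TestHeatmapOrder:
    def test_identical_columns_are_adjacent_with_zero_distance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=6)
        X = np.column_stack([x, rng.normal(size=6), x, rng.normal(size=6)])
        order, dist = fp.heatmap_order(X)
        assert dist[0, 2] == pytest.approx(0.0)
        pos = {c: i for i, c in enumerate(order)}
        assert abs(pos[0] - pos[2]) == 1

    def test_matches_brute_force_distance_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(5, 4))
        _, dist = fp.heatmap_order(X)
        for i in range(4):
            for j in range(4):
                expected = np.sqrt(np.sum((X[:, i] - X[:, j]) ** 2))
                assert dist[i, j] == pytest.approx(expected, rel=1e-12, abs=1e-12)
        # metric axioms
        assert np.allclose(dist, dist.T)
        assert np.all(np.diag(dist) == 0)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert dist[i, j] <= dist[i, k] + dist[k, j] + 1e-9
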