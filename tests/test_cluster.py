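"""k-means wrapper, internal validity metrics and downstream analyses."""

import itertools

import numpy as np
import pytest

from mscontab.cluster import (
    cluster_gene_sets,
    cluster_prototypes,
    cluster_spectra,
    cosine_matrix,
    gene_set_overlap,
    internal_metrics,
    kmeans_cluster,
    nearest_neighbors,
    project_2d,
    within_between_similarity,
)
from mscontab.signatures import build_chromosome_signature, build_gene_signature

from conftest import make_record

FIXTURE_1D = np.array([[0.0], [0.1], [10.0], [10.1]])


def exhaustive_min_wss_partition(X, k=2):
    """Oracle: brute-force minimum within-cluster sum of squares."""
    n = len(X)
    best, best_wss = None, np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        wss = sum(((X[np.array(assignment) == c]
                    - X[np.array(assignment) == c].mean(axis=0)) ** 2).sum()
                  for c in range(k))
        if wss < best_wss:
            best_wss, best = wss, np.array(assignment)
    return best, best_wss


class TestKmeans:
    def test_recovers_exhaustive_minimum_on_fixture(self):
        result = kmeans_cluster(FIXTURE_1D, k=2, seed=0)
        oracle, _ = exhaustive_min_wss_partition(FIXTURE_1D)
        assert (result.labels == oracle).all() or \
               (result.labels == 1 - oracle).all()

    def test_k_equals_n_zero_wss(self):
        result = kmeans_cluster(FIXTURE_1D, k=4, seed=0)
        assert sorted(result.labels) == [0, 1, 2, 3]

    def test_duplicated_dataset_same_partition(self):
        from sklearn.metrics import adjusted_rand_score

        base = kmeans_cluster(FIXTURE_1D, k=2, seed=0).labels
        doubled = kmeans_cluster(np.vstack([FIXTURE_1D, FIXTURE_1D]),
                                 k=2, seed=0).labels
        assert adjusted_rand_score(np.tile(base, 2), doubled) == 1.0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kmeans_cluster(FIXTURE_1D, k=5)


class TestInternalMetrics:
    def test_hand_derived_fixture_values(self):
        labels = np.array([0, 0, 1, 1])
        m = internal_metrics(FIXTURE_1D, labels)
        assert m.silhouette == pytest.approx(0.990, abs=5e-4)
        assert m.davies_bouldin == pytest.approx(0.01, abs=1e-12)
        assert m.calinski_harabasz == pytest.approx(20000, rel=1e-9)

    def test_identical_points_per_cluster(self):
        Z = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        m = internal_metrics(Z, np.array([0, 0, 1, 1]))
        assert m.silhouette == pytest.approx(1.0)
        assert m.davies_bouldin == pytest.approx(0.0)
        assert np.isinf(m.calinski_harabasz)

    def test_matches_sklearn_reference_on_random_data(self, rng):
        from sklearn.metrics import (
            calinski_harabasz_score,
            davies_bouldin_score,
            silhouette_score,
        )

        for _ in range(5):
            Z = rng.normal(size=(30, 6))
            labels = rng.integers(0, 3, size=30)
            if len(np.unique(labels)) < 2:
                continue
            m = internal_metrics(Z, labels)
            assert m.silhouette == pytest.approx(
                silhouette_score(Z, labels), abs=1e-9)
            assert m.davies_bouldin == pytest.approx(
                davies_bouldin_score(Z, labels), abs=1e-9)
            assert m.calinski_harabasz == pytest.approx(
                calinski_harabasz_score(Z, labels), rel=1e-9)

    def test_invariance_to_rigid_motion_and_scaling(self, rng):
        Z = rng.normal(size=(20, 3))
        labels = rng.integers(0, 2, size=20)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = Z @ q + np.array([5.0, -2.0, 1.0])
        m0, m1 = internal_metrics(Z, labels), internal_metrics(moved, labels)
        assert m0.silhouette == pytest.approx(m1.silhouette, abs=1e-9)
        assert m0.davies_bouldin == pytest.approx(m1.davies_bouldin, abs=1e-9)
        assert m0.calinski_harabasz == pytest.approx(
            m1.calinski_harabasz, rel=1e-9)
        scaled = internal_metrics(3.7 * Z, labels)
        assert scaled.silhouette == pytest.approx(m0.silhouette, abs=1e-9)
        assert scaled.davies_bouldin == pytest.approx(
            m0.davies_bouldin, abs=1e-9)
        assert scaled.calinski_harabasz == pytest.approx(
            m0.calinski_harabasz, rel=1e-9)

    def test_singleton_cluster_contributes_zero_silhouette(self):
        Z = np.array([[0.0], [0.1], [10.0]])
        m = internal_metrics(Z, np.array([0, 0, 1]))
        assert np.isfinite(m.silhouette)

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError):
            internal_metrics(FIXTURE_1D, np.zeros(4))


class TestCosineMatrix:
    def test_orthonormal_rows_identity(self):
        M = cosine_matrix(np.eye(4))
        np.testing.assert_allclose(M.values, np.eye(4), atol=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        Z = rng.normal(size=(8, 5))
        M = cosine_matrix(Z).values
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(M), 1.0)

    def test_cluster_ordering_and_block_structure(self):
        # unit circle at 0, 90, 5, 95 degrees; cluster pairs (0,5), (90,95)
        ang = np.deg2rad([0, 90, 5, 95])
        Z = np.column_stack([np.cos(ang), np.sin(ang)])
        names = ["a", "c", "b", "d"]
        labels = np.array([0, 1, 0, 1])
        M = cosine_matrix(Z, names, labels)
        assert list(M.index) == ["a", "b", "c", "d"]
        assert M.loc["a", "b"] == pytest.approx(np.cos(np.deg2rad(5)))
        assert M.loc["a", "c"] == pytest.approx(np.cos(np.deg2rad(90)), abs=1e-12)
        within = (M.loc["a", "b"] + M.loc["c", "d"]) / 2
        between = M.loc[["a", "b"], ["c", "d"]].values.mean()
        assert within > between

    def test_zero_row_raises(self):
        with pytest.raises(ValueError):
            cosine_matrix(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestPrototypesAndNeighbors:
    def test_prototype_majority_direction(self):
        u = np.array([1.0, 0.0])
        v = np.array([np.cos(1.0), np.sin(1.0)])
        Z = np.vstack([u, u, v])
        protos = cluster_prototypes(Z, np.zeros(3, int), ["x", "y", "z"])
        assert protos[0] in {"x", "y"}

    def test_singleton_is_its_own_prototype(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.9]])
        protos = cluster_prototypes(Z, np.array([0, 1, 1]), ["a", "b", "c"])
        assert protos[0] == "a"

    def test_tie_broken_alphabetically(self):
        u = np.array([0.3, 0.4])
        Z = np.vstack([u, u, u])
        protos = cluster_prototypes(Z, np.zeros(3, int), ["zeta", "beta", "alpha"])
        assert protos[0] == "alpha"

    def test_neighbors_match_brute_force(self, rng):
        Z = rng.normal(size=(10, 4))
        names = [f"c{i}" for i in range(10)]
        table = nearest_neighbors(Z, names, m=3)
        U = Z / np.linalg.norm(Z, axis=1, keepdims=True)
        S = U @ U.T
        for i in range(10):
            scores = [(S[i, j], names[j]) for j in range(10) if j != i]
            best = sorted(scores, key=lambda t: (-t[0], t[1]))[:3]
            row = table.iloc[i]
            assert [row[f"neighbor_{r}"] for r in (1, 2, 3)] == [b[1] for b in best]
            assert row["score_1"] >= row["score_2"] >= row["score_3"]
            assert row["cohort"] not in [row[f"neighbor_{r}"] for r in (1, 2, 3)]

    def test_duplicate_row_is_rank_one_neighbor(self):
        Z = np.array([[1.0, 2.0], [1.0, 2.0], [-3.0, 0.5], [0.0, 1.0]])
        table = nearest_neighbors(Z, ["a", "b", "c", "d"], m=3)
        assert table.iloc[0]["neighbor_1"] == "b"
        assert table.iloc[0]["score_1"] == pytest.approx(1.0)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            nearest_neighbors(np.eye(3), ["a", "b", "c"], m=3)


class TestSpectraAndOverlap:
    def _sigs(self, counts):
        gene_sigs, chrom_sigs = {}, {}
        for cohort, n_ct in counts.items():
            recs = [make_record(cohort=cohort, ref="C", alt="T")] * n_ct
            gene_sigs[cohort] = build_gene_signature(recs, cohort=cohort)
            chrom_sigs[cohort] = build_chromosome_signature(recs, cohort=cohort)
        return gene_sigs, chrom_sigs

    def test_cluster_mean_is_arithmetic_mean(self):
        gene_sigs, chrom_sigs = self._sigs({"a": 4, "b": 2})
        prof = cluster_spectra(gene_sigs, chrom_sigs, {"a": 0, "b": 0})
        assert prof.substitution_means.loc[0, "C>T"] == pytest.approx(3.0)

    def test_single_cohort_cluster_equals_own_totals(self):
        gene_sigs, chrom_sigs = self._sigs({"a": 5, "b": 2})
        prof = cluster_spectra(gene_sigs, chrom_sigs, {"a": 0, "b": 1})
        assert prof.substitution_means.loc[0, "C>T"] == 5.0
        assert prof.substitution_means.loc[1, "C>T"] == 2.0
        assert (prof.substitution_means.drop(columns="C>T") == 0).all().all()

    def test_missing_signature_raises(self):
        gene_sigs, chrom_sigs = self._sigs({"a": 1})
        with pytest.raises(ValueError):
            cluster_spectra(gene_sigs, chrom_sigs, {"a": 0, "ghost": 1})

    @pytest.mark.parametrize("a,b,expected", [
        ({"A", "B", "C"}, {"B", "C", "D"}, (2, 1, 1)),
        ({"A", "B"}, {"A", "B"}, (2, 0, 0)),
        ({"A"}, {"B"}, (0, 1, 1)),
    ])
    def test_overlap_counts(self, a, b, expected):
        out = gene_set_overlap(a, b)
        assert (out["n_shared"], out["n_unique_a"], out["n_unique_b"]) == expected

    def test_cluster_gene_sets_union(self, small_views):
        labels = {c: i % 2 for i, c in enumerate(small_views.cohorts)}
        sets = cluster_gene_sets(small_views.gene_signatures, labels)
        member = small_views.cohorts[0]
        assert set(small_views.gene_signatures[member].genes) <= sets[labels[member]]


class TestProjection:
    @pytest.mark.parametrize("method", ["umap", "tsne"])
    def test_shape_and_determinism(self, rng, method):
        Z = rng.normal(size=(25, 8))
        a = project_2d(Z, method=method, seed=7)
        b = project_2d(Z, method=method, seed=7)
        assert a.shape == (25, 2)
        np.testing.assert_array_equal(a, b)

    def test_too_small_input(self):
        with pytest.raises(ValueError):
            project_2d(np.eye(3), method="umap")

    def test_unknown_method(self, rng):
        with pytest.raises(ValueError):
            project_2d(rng.normal(size=(10, 3)), method="pca3d")


def test_within_between_similarity_signs():
    ang = np.deg2rad([0, 5, 180, 185])
    Z = np.column_stack([np.cos(ang), np.sin(ang)])
    out = within_between_similarity(Z, np.array([0, 0, 1, 1]))
    assert out["within_0"] > 0.99 and out["within_1"] > 0.99
    assert out["between"] < -0.99
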