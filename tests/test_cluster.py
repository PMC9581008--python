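"""UPGMA, k-means, PCA, and clustering quality indices."""

import itertools

import numpy as np
import pytest

import peparray as pa
from peparray.cluster import SampleVectors

from conftest import make_matrix


def points_1d(values, cohorts=None):
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    n = values.shape[0]
    return SampleVectors(
        sample_ids=[f"s{i}" for i in range(n)],
        cohorts=cohorts or ["control"] * n,
        peptide_ids=["P1"],
        coordinates=values,
    )


class TestUpgma:
    def test_hand_three_point_tree(self):
        # A=0, B=1, C=5: merge (A,B) at 1; then average of d(A,C)=5 and
        # d(B,C)=4 gives the root at 4.5; the cut separates {A,B} from {C}
        res = pa.upgma_tree(points_1d([0, 1, 5]))
        Z = res.linkage_tree
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(4.5)
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_hand_four_point_tree(self):
        # 0,1,10,11: merges at 1 and 1, then root at mean pairwise
        # cross-distance (10+11+9+10)/4 = 10
        res = pa.upgma_tree(points_1d([0, 1, 10, 11]))
        heights = sorted(res.linkage_tree[:, 2])
        assert heights == pytest.approx([1.0, 1.0, 10.0])
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]

    def test_coincident_points_merge_at_zero(self):
        res = pa.upgma_tree(points_1d([3, 3, 9]))
        assert res.linkage_tree[0, 2] == 0.0

    def test_heights_non_decreasing_and_permutation_invariant(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (8, 5))
        base = pa.upgma_tree(
            SampleVectors([f"s{i}" for i in range(8)], ["control"] * 8, list("abcde"), X)
        )
        h = base.linkage_tree[:, 2]
        assert (np.diff(h) >= -1e-12).all()
        perm = rng.permutation(8)
        shuffled = pa.upgma_tree(
            SampleVectors([f"s{i}" for i in perm], ["control"] * 8, list("abcde"), X[perm])
        )
        assert np.allclose(sorted(h), sorted(shuffled.linkage_tree[:, 2]))

    def test_two_points_required(self):
        with pytest.raises(ValueError):
            pa.upgma_tree(points_1d([1.0]))


class TestKmeans:
    def test_colinear_exhaustive_optimum(self):
        # all 2-partitions of (0, 1, 10, 11): the best has SS 0.5 + 0.5
        pts = points_1d([0, 1, 10, 11])
        res = pa.kmeans2(pts, seed=0)
        assert res.n_clusters == 2
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]
        best = min(
            sum(
                sum((v - np.mean(part)) ** 2 for v in part)
                for part in (group, [x for x in (0, 1, 10, 11) if x not in group])
            )
            for group in itertools.combinations((0, 1, 10, 11), 2)
        )
        assert res.inertia == pytest.approx(best) == pytest.approx(1.0)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-10, 0.5, (5, 3)), rng.normal(10, 0.5, (5, 3))])
        pts = SampleVectors(
            [f"s{i}" for i in range(10)], ["control"] * 5 + ["treatment"] * 5,
            list("abc"), X,
        )
        res = pa.kmeans2(pts, seed=1)
        assert len(set(res.labels[:5])) == 1 and len(set(res.labels[5:])) == 1
        assert res.labels[0] != res.labels[5]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        pts = points_1d(rng.normal(0, 1, 12))
        r1, r2 = pa.kmeans2(pts, seed=7), pa.kmeans2(pts, seed=7)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.centers, r2.centers)

    def test_degenerate_single_point_cloud(self):
        with pytest.warns(UserWarning, match="distinct"):
            res = pa.kmeans2(points_1d([2, 2, 2]), seed=0)
        assert res.n_clusters == 1

    def test_cohort_recovery_across_seeds(self):
        # strong cohort effect (>= 2 sigma on >= 5% of peptides): k-means
        # labels must match the true cohorts (up to swap) in >= 95% of runs
        spec = pa.SimSpec(
            seed=33, protein_length=815, n_control=5, n_treatment=5,
            differential_fraction=0.10, effect_size=3.0,
        )
        samples, _ = pa.simulate_samples(spec)
        matrix = pa.quantile_normalize(pa.assemble_matrix(samples))
        pts = pa.sample_vectors(matrix)
        truth = np.array([c == "treatment" for c in pts.cohorts], dtype=int)
        hits = 0
        for seed in range(20):
            labels = pa.kmeans2(pts, seed=seed).labels
            agree = max((labels == truth).mean(), (labels == 1 - truth).mean())
            hits += agree == 1.0
        assert hits >= 19


class TestPca:
    def test_rank_one_line(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(0, 1, 50)
        t = np.linspace(-2, 2, 6)
        pts = SampleVectors(
            [f"s{i}" for i in range(6)], ["control"] * 6,
            [f"p{i}" for i in range(50)], np.outer(t, direction),
        )
        coords, explained = pa.pca_embed(pts)
        assert explained[0] == pytest.approx(1.0)
        assert explained[1] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(coords[:, 1], 0.0)

    def test_scores_centered(self):
        rng = np.random.default_rng(2)
        pts = SampleVectors(
            [f"s{i}" for i in range(7)], ["control"] * 7, list("abcd"),
            rng.normal(0, 1, (7, 4)),
        )
        coords, _ = pa.pca_embed(pts)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_against_dense_eigendecomposition(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (5, 3))
        pts = SampleVectors([f"s{i}" for i in range(5)], ["control"] * 5, list("abc"), X)
        coords, explained = pa.pca_embed(pts)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        expected = Xc @ v[:, order[:2]]
        for k in range(2):  # eigenvector sign is arbitrary
            assert np.allclose(np.abs(coords[:, k]), np.abs(expected[:, k]), atol=1e-9)
        assert np.allclose(explained, w[order[:2]] / w.sum())


class TestQualityIndices:
    def test_silhouette_hand_computed(self):
        pts = points_1d([0, 1, 10, 11])
        qi = pa.quality_indices(pts, [0, 0, 1, 1])
        per_point = [9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5]
        assert qi.silhouette == pytest.approx(np.mean(per_point))
        assert qi.silhouette == pytest.approx(0.900, abs=5e-4)
        assert qi.davies_bouldin >= 0 and qi.calinski_harabasz >= 0

    def test_silhouette_approaches_one_with_separation(self):
        base = np.array([0.0, 1.0])
        prev = 0.0
        for gap in (10, 100, 1000):
            pts = points_1d(np.concatenate([base, base + gap]))
            s = pa.quality_indices(pts, [0, 0, 1, 1]).silhouette
            assert s > prev
            prev = s
        assert prev > 0.99

    def test_coincident_clusters_flagged(self):
        pts = points_1d([0, 1, 0, 1])
        qi = pa.quality_indices(pts, [0, 0, 1, 1])
        assert np.isnan(qi.davies_bouldin)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (10, 3))
        labels = [0] * 5 + [1] * 5
        Q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
        shift = rng.normal(0, 5, 3)
        a = pa.quality_indices(
            SampleVectors([str(i) for i in range(10)], ["control"] * 10, list("abc"), X),
            labels,
        )
        b = pa.quality_indices(
            SampleVectors([str(i) for i in range(10)], ["control"] * 10, list("abc"), X @ Q + shift),
            labels,
        )
        for name in ("davies_bouldin", "silhouette", "calinski_harabasz"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9)


class TestSampleVectors:
    def test_subset_restricts_dimension_and_order(self, small_table):
        sel = pa.select_subset(
            small_table, pa.SubsetSpec(cutoff=20, direction="any", fdr=0.25)
        )
        pts = pa.sample_vectors(small_table, peptide_subset=sel.by_p)
        assert pts.dimension == len(sel.by_p) == 20
        assert pts.peptide_ids == sel.by_p
        full = pa.sample_vectors(small_table)
        assert full.dimension == len(small_table)

    def test_missing_peptide_rejected(self, small_table):
        with pytest.raises(ValueError, match="nope"):
            pa.sample_vectors(small_table, peptide_subset=["nope"])
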