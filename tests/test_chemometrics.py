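"""PCA/HCA against brute-force oracles, plus matrix-building contracts."""

import numpy as np
import pytest

from voltscreen.chemometrics import (
    FeatureMatrix,
    build_matrix,
    cut_at,
    cut_by_gap,
    run_hca,
    run_pca,
)
from voltscreen.preprocess import preprocess_trace
from voltscreen.simulate import SimulationParams, simulate_voltammogram

NOISE_FREE = SimulationParams(noise_sd_fraction=0.0, potential_jitter_sd=0.0)


def _matrix_from_array(x):
    import pandas as pd

    n_cols = x.shape[1]
    cols = pd.MultiIndex.from_tuples(
        [("anodic", float(i)) for i in range(n_cols)], names=["scan", "potential_V"]
    )
    frame = pd.DataFrame(x, index=[f"r{i}" for i in range(len(x))], columns=cols)
    return FeatureMatrix(frame, np.arange(n_cols, dtype=float), np.array([]))


class TestBuildMatrix:
    def _pair(self, analyte, seed):
        anodic = simulate_voltammogram([(analyte, 100.0)], "anodic", seed=[seed, 0])
        cathodic = simulate_voltammogram([(analyte, 100.0)], "cathodic", seed=[seed, 1])
        return (
            preprocess_trace(anodic, normalized=True),
            preprocess_trace(cathodic, normalized=True),
            analyte,
        )

    def test_row_count_and_column_layout(self, standards_matrix):
        assert len(standards_matrix) == 45  # 15 analytes x 3 replicates
        n_cols = standards_matrix.values.shape[1]
        assert n_cols == len(standards_matrix.anodic_grid) + len(
            standards_matrix.cathodic_grid
        )

    def test_single_pair_gives_one_row(self):
        m = build_matrix([self._pair("MPHP", 1)])
        assert len(m) == 1

    def test_mismatched_grids_rejected(self):
        a1, c1, _ = self._pair("MPHP", 1)
        a2, c2, _ = self._pair("MDPV", 2)
        from voltscreen.preprocess import crop

        narrow = crop(a2, -1.0, 1.0)
        with pytest.raises(ValueError):
            build_matrix([(a1, c1, "x"), (narrow, c2, "y")])


class TestPCA:
    def test_collinear_rows_put_all_variance_on_pc1(self):
        t = np.linspace(-1, 1, 8)[:, None]
        x = 3.0 + t * np.array([[1.0, -2.0, 0.5, 4.0]])
        result = run_pca(_matrix_from_array(x), n_components=2)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)
        assert result.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_full_reconstruction(self, rng):
        x = rng.normal(size=(9, 6))
        result = run_pca(_matrix_from_array(x), n_components=6)
        np.testing.assert_allclose(result.reconstruct(), x, atol=1e-8)

    def test_matches_brute_force_covariance_eigendecomposition(self, rng):
        """Explained variances equal the eigenvalues of the covariance matrix."""
        x = rng.normal(size=(6, 4))
        result = run_pca(_matrix_from_array(x), n_components=3)
        cov = np.cov(x, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected_ratio = eigvals / eigvals.sum()
        np.testing.assert_allclose(
            result.explained_variance_ratio, expected_ratio[:3], atol=1e-10
        )

    def test_scores_translation_invariant(self, rng):
        x = rng.normal(size=(7, 5))
        shifted = x + rng.normal(size=(1, 5))
        a = run_pca(_matrix_from_array(x), 2)
        b = run_pca(_matrix_from_array(shifted), 2)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-9)

    def test_loadings_orthonormal_and_ratios_sorted(self, standards_matrix):
        result = run_pca(standards_matrix, n_components=4)
        gram = result.loadings @ result.loadings.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-9)
        evr = result.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-9

    def test_too_many_components_rejected(self, rng):
        x = rng.normal(size=(4, 10))
        with pytest.raises(ValueError):
            run_pca(_matrix_from_array(x), n_components=4)


def _naive_average_linkage(x):
    """O(n^3) agglomeration oracle: average linkage on Euclidean distances."""
    clusters = {i: [i] for i in range(len(x))}
    active = list(clusters)
    merges = []
    next_id = len(x)
    while len(active) > 1:
        best = None
        for i_pos, ci in enumerate(active):
            for cj in active[i_pos + 1:]:
                d = np.mean(
                    [
                        np.linalg.norm(x[a] - x[b])
                        for a in clusters[ci]
                        for b in clusters[cj]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, ci, cj)
        d, ci, cj = best
        merges.append(d)
        clusters[next_id] = clusters.pop(ci) + clusters.pop(cj)
        active = [c for c in active if c not in (ci, cj)] + [next_id]
        next_id += 1
    return np.array(merges)


class TestHCA:
    def test_two_separated_clouds_cut_to_two_clusters(self, rng):
        x = np.vstack(
            [rng.normal(0, 0.1, size=(6, 3)), rng.normal(8, 0.1, size=(6, 3))]
        )
        h = run_hca(_matrix_from_array(x))
        labels = cut_by_gap(h)
        assert labels.max() == 2
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1

    def test_merge_count_is_rows_minus_one(self, standards_matrix):
        h = run_hca(standards_matrix)
        assert h.merge_tree.shape[0] == len(standards_matrix) - 1
        assert np.all(np.diff(h.heights) >= -1e-12)

    def test_matches_naive_agglomeration_oracle(self, rng):
        x = rng.normal(size=(8, 3))
        h = run_hca(_matrix_from_array(x), "average")
        np.testing.assert_allclose(h.heights, _naive_average_linkage(x), atol=1e-10)

    def test_similarity_scale_spans_zero_to_hundred(self, standards_matrix):
        h = run_hca(standards_matrix)
        sim = h.similarity
        assert sim.min() == pytest.approx(0.0)  # the root merge
        assert np.all(sim <= 100.0)

    def test_unknown_linkage_or_metric_rejected(self, standards_matrix):
        with pytest.raises(ValueError):
            run_hca(standards_matrix, "wardest")
        with pytest.raises(ValueError):
            run_hca(standards_matrix, "average", "mahalanobis")


def test_six_cluster_cut_recovers_designed_groups(standards_matrix):
    """Cutting the Ward dendrogram at six clusters reproduces G1-G6 exactly."""
    from sklearn.metrics import adjusted_rand_score

    truth = [group for (_, group, _) in standards_matrix.row_labels]
    labels = cut_at(run_hca(standards_matrix), 6)
    assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)
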