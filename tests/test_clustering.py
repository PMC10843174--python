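"""Tests for correlation-distance clustering and the significance protocol."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nucphase.clustering import (
    balance_clusters,
    cluster_significance,
    inter_cluster_correlations,
    kmeans_correlation,
    pearson_matrix,
    select_k_silhouette,
    ward_euclidean_clusters,
)
from nucphase.profile_io import ProfileSet, WINDOW_LENGTH
from nucphase.synthetic import (
    ArchetypeSpec,
    SimulationConfig,
    generate_profiles,
    two_archetype_config,
)
from tests.conftest import rand_profiles


def scalar_loop_pearson(x, y):
    """Direct elementwise evaluation of the Pearson cross-correlation."""
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


class TestPearsonMatrix:
    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 20))
        R = pearson_matrix(X).values
        for i in range(5):
            for j in range(5):
                assert abs(R[i, j] - scalar_loop_pearson(X[i], X[j])) < 1e-10

    def test_self_correlation_and_anticorrelation(self):
        rng = np.random.default_rng(1)
        x = rng.random(50)
        R = pearson_matrix(np.vstack([x, 3.0 - x])).values
        assert R[0, 0] == pytest.approx(1.0)
        assert R[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_symmetry_unit_diagonal_and_range(self):
        rng = np.random.default_rng(2)
        R = pearson_matrix(rand_profiles(8, rng)).values
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert (np.abs(R) <= 1.0).all()

    def test_constant_row_excluded_with_warning(self, caplog):
        import logging

        X = np.vstack([np.ones(30), np.arange(30.0), np.cos(np.arange(30.0))])
        with caplog.at_level(logging.WARNING):
            corr = pearson_matrix(X)
        assert corr.n_genes == 2
        assert corr.excluded_gene_ids == ["0"]


class TestKmeansCorrelation:
    def test_recovers_noiseless_archetype_groups(self):
        cfg = SimulationConfig(
            n_genes=40,
            archetypes=(
                ArchetypeSpec(amplitude_trend=0.2),
                ArchetypeSpec(amplitude_trend=-0.2),
            ),
            mixture_weights=(0.5, 0.5),
            gene_length_distribution=("constant", {"length": 2000}),
            noise_sd=0.0,
            height_jitter_sd=0.0,
            seed=3,
        )
        profiles, labels, _ = generate_profiles(cfg)
        result = kmeans_correlation(profiles, k=2, n_init=5, seed=0)
        assert adjusted_rand_score(labels, result.labels) == 1.0

    def test_n_init_stability_on_separable_data(self, two_archetype_data):
        _, profiles, _, lengths = two_archetype_data
        sub = profiles.subset(lengths > 1000)
        one = kmeans_correlation(sub, k=2, n_init=1, seed=7)
        many = kmeans_correlation(sub, k=2, n_init=25, seed=7)
        assert adjusted_rand_score(one.labels, many.labels) == 1.0

    def test_labels_invariant_to_row_rescaling(self, two_archetype_data):
        _, profiles, _, lengths = two_archetype_data
        sub = profiles.subset(lengths > 1000)
        scaled = ProfileSet(
            values=sub.values * np.linspace(0.5, 8.0, sub.n_genes)[:, None],
            gene_ids=list(sub.gene_ids),
        )
        a = kmeans_correlation(sub, k=2, n_init=5, seed=1)
        b = kmeans_correlation(scaled, k=2, n_init=5, seed=1)
        assert adjusted_rand_score(a.labels, b.labels) == 1.0

    def test_k_out_of_range_rejected(self):
        rng = np.random.default_rng(4)
        X = rand_profiles(5, rng)
        with pytest.raises(ValueError):
            kmeans_correlation(X, k=5)
        with pytest.raises(ValueError):
            kmeans_correlation(X, k=1)


class TestSelectK:
    def test_trivial_single_candidate(self, two_archetype_data):
        _, profiles, _, lengths = two_archetype_data
        best, by_k = select_k_silhouette(profiles.subset(lengths > 1000), [2], n_init=5, seed=0)
        assert best == 2 and set(by_k) == {2}

    def test_two_archetypes_select_two(self, large_gene_two_archetype_data):
        profiles, _, _ = large_gene_two_archetype_data
        best, by_k = select_k_silhouette(profiles, range(2, 6), n_init=10, seed=1)
        assert best == 2

    def test_three_archetypes_select_three(self):
        cfg = SimulationConfig(
            n_genes=150,
            archetypes=(
                ArchetypeSpec(amplitude_trend=0.3),
                ArchetypeSpec(amplitude_trend=-0.3),
                ArchetypeSpec(phase_offset=80.0),
            ),
            mixture_weights=(1 / 3, 1 / 3, 1 / 3),
            gene_length_distribution=("constant", {"length": 2000}),
            noise_sd=0.1,
            height_jitter_sd=0.3,
            seed=5,
        )
        profiles, _, _ = generate_profiles(cfg)
        best, _ = select_k_silhouette(profiles, range(2, 6), n_init=10, seed=2)
        assert best == 3

    def test_single_archetype_silhouette_near_zero(self):
        cfg = SimulationConfig(
            n_genes=80,
            gene_length_distribution=("constant", {"length": 2000}),
            noise_sd=0.2,
            height_jitter_sd=0.0,
            seed=6,
        )
        profiles, _, _ = generate_profiles(cfg)
        _, by_k = select_k_silhouette(profiles, [2], n_init=5, seed=0)
        assert abs(by_k[2]) < 0.2

    def test_empty_k_range_rejected(self, two_archetype_data):
        _, profiles, _, _ = two_archetype_data
        with pytest.raises(ValueError):
            select_k_silhouette(profiles, [], n_init=1, seed=0)


class TestInterClusterCorrelations:
    def test_counts_and_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        X = rand_profiles(7, rng)
        corr = pearson_matrix(X)
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        vals = inter_cluster_correlations(corr, labels)
        assert vals.size == 3 * 4
        expected = sorted(
            abs(corr.values[i, j]) for i in range(3) for j in range(3, 7)
        )
        assert np.allclose(sorted(vals), expected)

    def test_single_pair(self):
        corr = pearson_matrix(rand_profiles(2, np.random.default_rng(8)))
        vals = inter_cluster_correlations(corr, np.array([0, 1]))
        assert vals.size == 1
        assert vals[0] == pytest.approx(abs(corr.values[0, 1]))

    def test_requires_exactly_two_clusters(self):
        corr = pearson_matrix(rand_profiles(4, np.random.default_rng(9)))
        with pytest.raises(ValueError):
            inter_cluster_correlations(corr, np.array([0, 1, 2, 0]))


class TestClusterSignificance:
    def test_separated_archetypes_significant(self, large_gene_two_archetype_data):
        profiles, labels, _ = large_gene_two_archetype_data
        corr = pearson_matrix(profiles)
        result = kmeans_correlation(profiles, k=2, n_init=5, seed=0)
        sig = cluster_significance(corr, result.labels, n_random=100, subsample=200, seed=1)
        assert sig.mean_p < 0.05
        assert sig.significant

    def test_random_labels_not_significant(self, large_gene_two_archetype_data):
        profiles, _, _ = large_gene_two_archetype_data
        corr = pearson_matrix(profiles)
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, profiles.n_genes)
        sig = cluster_significance(corr, labels, n_random=100, subsample=200, seed=3)
        assert 0.3 <= sig.mean_p <= 0.7
        assert not sig.significant

    def test_deterministic_for_fixed_seed(self, large_gene_two_archetype_data):
        profiles, labels, _ = large_gene_two_archetype_data
        corr = pearson_matrix(profiles)
        a = cluster_significance(corr, labels, n_random=20, subsample=50, seed=5)
        b = cluster_significance(corr, labels, n_random=20, subsample=50, seed=5)
        assert a.mean_p == b.mean_p


class TestBalanceClusters:
    def test_already_balanced_unchanged(self):
        corr = pearson_matrix(rand_profiles(6, np.random.default_rng(10)))
        labels = np.array([0, 1, 0, 1, 0, 1])
        assert np.array_equal(balance_clusters(corr, labels), labels)

    def test_sizes_six_four_move_one(self):
        corr = pearson_matrix(rand_profiles(10, np.random.default_rng(11)))
        labels = np.array([0] * 6 + [1] * 4)
        balanced = balance_clusters(corr, labels)
        assert sorted(np.bincount(balanced)) == [5, 5]

    def test_moved_genes_match_brute_force_ranking(self):
        rng = np.random.default_rng(12)
        corr = pearson_matrix(rand_profiles(12, rng))
        labels = np.array([0] * 8 + [1] * 4)
        balanced = balance_clusters(corr, labels)
        moved = np.flatnonzero((labels == 0) & (balanced == 1))
        mean_corr = corr.values[np.ix_(labels == 0, labels == 1)].mean(axis=1)
        expected = np.flatnonzero(labels == 0)[np.argsort(-mean_corr, kind="stable")[:2]]
        assert set(moved) == set(expected)

    @pytest.mark.parametrize("n0", [3, 7, 11, 15])
    def test_never_increases_imbalance(self, n0):
        rng = np.random.default_rng(n0)
        n = 18
        corr = pearson_matrix(rand_profiles(n, rng))
        labels = np.array([0] * n0 + [1] * (n - n0))
        balanced = balance_clusters(corr, labels)
        before = abs(2 * n0 - n)
        after = abs(int((balanced == 0).sum()) - int((balanced == 1).sum()))
        assert after <= max(before, 1)
        assert after <= 1


class TestWardValidation:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(13)
        blob1 = 1.0 + 0.05 * rng.standard_normal((15, WINDOW_LENGTH))
        blob2 = np.tile(np.linspace(1, 3, WINDOW_LENGTH), (15, 1))
        blob2 += 0.05 * rng.standard_normal(blob2.shape)
        X = np.clip(np.vstack([blob1, blob2]), 0, None)
        scores = np.zeros((30, 2))
        labels, kept = ward_euclidean_clusters(X, scores)
        assert kept.all()
        assert adjusted_rand_score([0] * 15 + [1] * 15, labels) == 1.0

    def test_score_outliers_removed(self):
        rng = np.random.default_rng(14)
        X = rand_profiles(10, rng)
        scores = np.zeros((10, 2))
        scores[3, 0] = 50.0
        labels, kept = ward_euclidean_clusters(X, scores)
        assert kept.sum() == 9 and not kept[3]
        assert labels.size == 9

    def test_infinite_threshold_keeps_all(self):
        rng = np.random.default_rng(15)
        X = rand_profiles(8, rng)
        scores = rng.normal(0, 30, (8, 2))
        _, kept = ward_euclidean_clusters(X, scores, outlier_threshold=np.inf)
        assert kept.all()
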