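import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from seascape_biogeo import (EnvTable, SyntheticSpec, TableValidationError,
                             assign_samples, assignment_series,
                             classify_habitats, cluster_codebook, generate_env,
                             name_habitats, standardize_env, train_som,
                             PipelineConfig)
from seascape_biogeo.seascape_som import SomModel, Standardization


def env_from_rows(rows):
    return EnvTable(pd.DataFrame(rows, columns=["sample_id", "temperature_c",
                                                "salinity_psu", "din_umol"]))


class TestStandardize:
    def test_constant_feature_rejected(self):
        env = env_from_rows([("s1", 10.0, 33.0, 0.5), ("s2", 10.0, 34.0, 0.7)])
        with pytest.raises(TableValidationError, match="temperature"):
            standardize_env(env)

    def test_two_sample_zscore_population_sd(self):
        env = env_from_rows([("s1", 10.0, 33.0, 0.5), ("s2", 20.0, 34.0, 0.7)])
        feats, const = standardize_env(env)
        np.testing.assert_allclose(feats[:, 0], [-0.70710678, 0.70710678])

    def test_stored_constants_reproduce_training_features(self):
        rng = np.random.default_rng(0)
        env = env_from_rows([(f"s{i}", 10 + rng.normal(), 33 + rng.normal(),
                              abs(rng.normal()) + 0.1) for i in range(20)])
        feats, const = standardize_env(env)
        np.testing.assert_allclose(const.apply(env), feats)


def three_blob_features(seed=0, n=30, spread=0.02):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 4]], float)
    feats = np.vstack([c + rng.normal(0, spread, size=(n, 3)) for c in centers])
    labels = np.repeat([0, 1, 2], n)
    return feats, labels


class TestTrainSom:
    def test_degenerate_grid_rejected(self):
        feats, _ = three_blob_features()
        with pytest.raises(TableValidationError, match="2x2"):
            train_som(feats, grid=(1, 5))

    def test_non_finite_feature_rejected(self):
        feats, _ = three_blob_features()
        feats[0, 0] = np.nan
        with pytest.raises(TableValidationError, match="finite"):
            train_som(feats)

    def test_quantization_error_below_cluster_separation(self):
        feats, _ = three_blob_features(seed=1)
        model = train_som(feats, grid=(4, 4), seed=1)
        # between-cluster separation is 4; a fitted map must quantize far finer
        assert model.quantization_error(feats) < 4.0 / 4

    def test_same_seed_identical_codebooks(self):
        feats, _ = three_blob_features(seed=2)
        m1 = train_som(feats, grid=(3, 3), seed=5)
        m2 = train_som(feats, grid=(3, 3), seed=5)
        np.testing.assert_array_equal(m1.codebook, m2.codebook)


def brute_force_ward(points, k):
    """Greedy Ward agglomeration by exhaustive best-merge search, using the
    ESS-increase merge cost |A||B|/(|A|+|B|)*||cA-cB||^2."""
    clusters = [[i] for i in range(len(points))]
    while len(clusters) > k:
        best, best_cost = None, np.inf
        for a, b in itertools.combinations(range(len(clusters)), 2):
            pa = points[clusters[a]].mean(axis=0)
            pb = points[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            cost = na * nb / (na + nb) * ((pa - pb) ** 2).sum()
            if cost < best_cost:
                best, best_cost = (a, b), cost
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(points), dtype=int)
    for lab, idx in enumerate(clusters):
        labels[idx] = lab
    return labels


def model_with_codebook(codebook, grid):
    return SomModel(grid, np.asarray(codebook, float),
                    Standardization(np.zeros(codebook.shape[1]),
                                    np.ones(codebook.shape[1]), False),
                    0, 0.5, 1.0)


class TestClusterCodebook:
    def test_k_equals_nodes_gives_singletons(self):
        cb = np.arange(8.0).reshape(4, 2)
        model = model_with_codebook(cb, (2, 2))
        labels = cluster_codebook(model, k=4)
        assert len(set(labels)) == 4

    def test_duplicate_vectors_cocluster(self):
        base = np.array([[0.0, 0], [5, 5], [9, 0]])
        cb = np.repeat(base, 3, axis=0)  # 9 nodes, three copies each
        model = model_with_codebook(cb, (3, 3))
        labels = cluster_codebook(model, k=3)
        for i in range(3):
            assert len(set(labels[3 * i:3 * i + 3])) == 1

    def test_matches_brute_force_ward_on_small_codebook(self):
        rng = np.random.default_rng(4)
        cb = rng.normal(size=(8, 3))
        model = model_with_codebook(cb, (2, 4))
        got = cluster_codebook(model, k=3)
        want = brute_force_ward(cb, 3)
        assert adjusted_rand_score(got, want) == 1.0

    def test_k_above_nodes_rejected(self):
        model = model_with_codebook(np.zeros((4, 2)), (2, 2))
        with pytest.raises(TableValidationError):
            cluster_codebook(model, k=5)


class TestAssignSamples:
    def test_sample_equal_to_codebook_vector(self):
        cb = np.array([[0.0, 0, 0], [10, 10, 10], [20, 20, 20], [30, 30, 30]])
        model = model_with_codebook(cb, (2, 2))
        env = env_from_rows([("s1", 10.0, 10.0, 10.0)])
        out = assign_samples(model, np.array([1, 2, 1, 2]), env)
        assert out.loc[0, "habitat"] == 2

    def test_duplicate_samples_identical_labels(self):
        cb = np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])
        model = model_with_codebook(cb, (2, 2))
        env = env_from_rows([("s1", 1.2, 1.2, 1.2), ("s2", 1.2, 1.2, 1.2)])
        out = assign_samples(model, np.array([1, 2, 1, 2]), env)
        assert out.loc[0, "habitat"] == out.loc[1, "habitat"]

    def test_synthetic_recovery_ari(self):
        spec = SyntheticSpec(seed=3)
        env, truth = generate_env(spec)
        cfg = PipelineConfig(base_seed=3)
        assignment = classify_habitats(env, cfg)
        series = assignment_series(assignment)
        ari = adjusted_rand_score(truth.loc[series.index].to_numpy(),
                                  series.to_numpy())
        assert ari >= 0.9


class TestNameHabitats:
    @staticmethod
    def _assignment_for_centroids(centroids):
        rows, hab = [], []
        for lab, (t, s, d) in enumerate(centroids, start=1):
            for j in range(2):
                rows.append((f"c{lab}_{j}", t, s, d))
                hab.append(lab)
        env = env_from_rows(rows)
        assignment = pd.DataFrame({"sample_id": env.sample_ids, "habitat": hab,
                                   "bmu_row": 0, "bmu_col": 0})
        return assignment, env

    def test_stated_centroid_rule(self):
        assignment, env = self._assignment_for_centroids(
            [(12, 32.8, 0.3), (19, 33.6, 0.2), (13, 33.5, 4.0)])
        named = name_habitats(assignment, env)
        by = named.drop_duplicates("habitat").set_index("habitat")["habitat_name"]
        assert by[1] == "PSUW" and by[2] == "ENPCW" and by[3] == "PEW"

    def test_identical_centroids_withhold_names(self):
        assignment, env = self._assignment_for_centroids(
            [(12, 33.0, 0.3)] * 3)
        named = name_habitats(assignment, env)
        assert "habitat_name" not in named.columns

    def test_conflicting_rules_withhold_names(self):
        # the non-PSUW cluster that is warmer is also DIN-richer
        assignment, env = self._assignment_for_centroids(
            [(12, 32.8, 0.3), (19, 33.6, 4.0), (13, 33.5, 0.2)])
        named = name_habitats(assignment, env)
        assert "habitat_name" not in named.columns

    def test_k2_keeps_numeric_labels(self):
        assignment, env = self._assignment_for_centroids(
            [(12, 32.8, 0.3), (19, 33.6, 0.2)])
        named = name_habitats(assignment, env)
        assert "habitat_name" not in named.columns
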