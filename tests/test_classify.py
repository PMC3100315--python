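"""Centroid training, dual classification routes, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from xsub import (
    CentroidModel,
    agreement,
    classify_correlation,
    classify_nearest_centroid,
    hierarchical_cluster,
    misclassification_rate,
    standardize,
    train_centroids,
)
from xsub.simulate import SimConfig, simulate_subtyped_cohort
from conftest import make_matrix


def std(values, **kw):
    return standardize(make_matrix(values, **kw))


def brute_pearson(x, y):
    """Direct covariance-formula oracle (population divisor)."""
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).mean() / np.sqrt((xc ** 2).mean() * (yc ** 2).mean()))


@pytest.fixture(scope="module")
def cohort():
    return simulate_subtyped_cohort(SimConfig(seed=11, n_genes=300, n_classifier_genes=200,
                                              samples_per_class=8))


@pytest.fixture(scope="module")
def model(cohort):
    train = standardize(cohort.train)
    return train_centroids(train, cohort.labels, cohort.classifier_genes,
                           class_names=["Proneural", "Neural", "Classical", "Mesenchymal"])


class TestTrainCentroids:
    def test_one_sample_per_class_centroid_equals_sample(self, rng):
        m = std(rng.normal(size=(10, 2)), samples=["a", "b"])
        model = train_centroids(m, {"a": "X", "b": "Y"}, m.gene_ids)
        np.testing.assert_array_equal(model.centroids["X"].to_numpy(), m.values[:, 0])
        np.testing.assert_array_equal(model.centroids["Y"].to_numpy(), m.values[:, 1])

    def test_mean_of_identical_samples_equals_either(self, rng):
        col = rng.normal(size=10)
        m = std(np.column_stack([col, col, rng.normal(size=10)]),
                samples=["a", "b", "c"])
        model = train_centroids(m, {"a": "X", "b": "X", "c": "Y"}, m.gene_ids)
        np.testing.assert_allclose(model.centroids["X"].to_numpy(), m.values[:, 0])

    def test_full_size_centroid_shape(self):
        cohort = simulate_subtyped_cohort(SimConfig(seed=3, samples_per_class=2))
        train = standardize(cohort.train)
        model = train_centroids(train, cohort.labels, cohort.classifier_genes)
        assert model.centroids.shape == (723, 4)

    def test_missing_classifier_gene_is_an_error(self, rng):
        m = std(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="ABSENT"):
            train_centroids(m, {s: "X" for s in m.sample_ids}, ["G0", "ABSENT"])

    def test_unstandardized_input_is_an_error(self, rng):
        m = make_matrix(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="standardized"):
            train_centroids(m, {s: "X" for s in m.sample_ids}, m.gene_ids)


class TestClassifyCorrelation:
    def test_query_equal_to_centroid_gets_r_one(self, model):
        q = model.centroids[["Proneural"]].copy()
        q.columns = ["q1"]
        query = make_matrix(q.to_numpy(), genes=list(q.index), samples=["q1"],
                            state="standardized")
        calls, corr = classify_correlation(query, model)
        assert calls[0].assigned_class == "Proneural"
        assert corr.loc["q1", "Proneural"] == pytest.approx(1.0, abs=1e-12)

    def test_negated_centroid_is_never_assigned_its_class(self, model):
        q = -model.centroids[["Neural"]].to_numpy()
        query = make_matrix(q, genes=model.classifier_genes, samples=["q1"],
                            state="standardized")
        calls, corr = classify_correlation(query, model)
        assert corr.loc["q1", "Neural"] == pytest.approx(-1.0, abs=1e-12)
        assert calls[0].assigned_class != "Neural"

    def test_correlations_match_brute_force_to_1e12(self, cohort, model):
        query = standardize(cohort.validation)
        calls, corr = classify_correlation(query, model)
        sub = query.data.loc[model.classifier_genes]
        for sample in query.sample_ids:
            for cls in model.class_names:
                expected = brute_pearson(sub[sample].to_numpy(),
                                         model.centroids[cls].to_numpy())
                assert corr.loc[sample, cls] == pytest.approx(expected, abs=1e-12)
        by_brute = {
            s: max(model.class_names,
                   key=lambda c: brute_pearson(sub[s].to_numpy(),
                                               model.centroids[c].to_numpy()))
            for s in query.sample_ids
        }
        assert {c.sample_id: c.assigned_class for c in calls} == by_brute

    def test_invariant_to_positive_affine_transform_of_query(self, cohort, model):
        query = standardize(cohort.validation)
        transformed = make_matrix(3.0 * query.values + 2.0, genes=query.gene_ids,
                                  samples=query.sample_ids, state="standardized")
        _, corr_a = classify_correlation(query, model)
        _, corr_b = classify_correlation(transformed, model)
        np.testing.assert_allclose(corr_a.to_numpy(), corr_b.to_numpy(), atol=1e-12)


class TestClassifyNearestCentroid:
    def test_query_equal_to_centroid_has_distance_zero(self, model):
        q = model.centroids[["Classical"]].to_numpy()
        query = make_matrix(q, genes=model.classifier_genes, samples=["q1"],
                            state="standardized")
        calls, dist = classify_nearest_centroid(query, model)
        assert calls[0].assigned_class == "Classical"
        assert dist.loc["q1", "Classical"] == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_tie_breaks_to_first_class_and_is_flagged(self):
        centroids = pd.DataFrame({"X": [1.0, 0.0], "Y": [-1.0, 0.0]}, index=["g1", "g2"])
        model = CentroidModel(centroids)
        query = make_matrix([[0.0], [5.0]], genes=["g1", "g2"], samples=["q"],
                            state="standardized")
        calls, _ = classify_nearest_centroid(query, model)
        assert calls[0].assigned_class == "X"
        assert calls[0].tie

    def test_distances_match_brute_force(self, cohort, model):
        query = standardize(cohort.validation)
        _, dist = classify_nearest_centroid(query, model)
        sub = query.data.loc[model.classifier_genes]
        for sample in query.sample_ids[:10]:
            for cls in model.class_names:
                expected = np.sqrt(((sub[sample].to_numpy()
                                     - model.centroids[cls].to_numpy()) ** 2).sum())
                assert dist.loc[sample, cls] == pytest.approx(expected, abs=1e-9)


class TestCallMetrics:
    def _calls(self, assignments, method="correlation"):
        from xsub.classify import SubtypeCall
        return [SubtypeCall(s, c, {}, method) for s, c in assignments.items()]

    def test_misclassification_endpoints(self):
        truth = {f"s{i}": "X" for i in range(20)}
        all_right = self._calls({s: "X" for s in truth})
        assert misclassification_rate(all_right, truth) == 0.0
        all_wrong = self._calls({s: "Y" for s in truth})
        assert misclassification_rate(all_wrong, truth) == 1.0
        two_wrong = self._calls({s: ("Y" if i < 2 else "X") for i, s in enumerate(truth)})
        assert misclassification_rate(two_wrong, truth) == pytest.approx(0.10)

    def test_missing_truth_label_is_an_error(self):
        with pytest.raises(ValueError, match="truth"):
            misclassification_rate(self._calls({"s1": "X"}), {})

    def test_agreement_endpoints_and_sample_mismatch(self):
        a = self._calls({"s1": "X", "s2": "Y"})
        assert agreement(a, a) == 1.0
        b = self._calls({"s1": "Y", "s2": "X"})
        assert agreement(a, b) == 0.0
        with pytest.raises(ValueError, match="sample sets"):
            agreement(a, self._calls({"s3": "X"}))


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_height_zero(self, rng):
        col = rng.normal(size=10)
        m = make_matrix(np.column_stack([col, col, rng.normal(size=10)]))
        Z, _ = hierarchical_cluster(m)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_affine_transform_of_a_sample_is_at_distance_zero(self, rng):
        col = rng.normal(size=10)
        m = make_matrix(np.column_stack([col, 4.0 * col + 1.0, rng.normal(size=10)]))
        Z, _ = hierarchical_cluster(m)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_cluster_partition_is_recovered(self, rng):
        center_a, center_b = rng.normal(size=30), rng.normal(size=30)
        cols = ([center_a + 0.2 * rng.normal(size=30) for _ in range(6)]
                + [center_b + 0.2 * rng.normal(size=30) for _ in range(6)])
        m = make_matrix(np.column_stack(cols))
        Z, samples = hierarchical_cluster(m)
        groups = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(groups[:6])) == 1
        assert len(set(groups[6:])) == 1
        assert groups[0] != groups[6]
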