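import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import irsurv.classify as classify_module
from _oracles import auroc_bruteforce, logistic_grid_oracle
from irsurv.classify import (
    auroc,
    bootstrap_evaluate,
    logistic_fit,
    patient_scores,
    pca_fit,
    pca_transform,
    sensitivity_specificity,
)
from irsurv.errors import ConfigError, DataError, DegenerateInputError
from irsurv.preprocess import SpectralDataset
from irsurv.stratify import label_endpoint


class TestPCA:
    def test_rank_one_matrix_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        direction = rng.random(12)
        matrix = np.outer(rng.random(10), direction) + 0.3
        model = pca_fit(matrix, k=1)
        assert model.explained_variance[0] > 0
        residual = (matrix - matrix.mean(0)) - pca_transform(model, matrix) @ model.components
        assert np.abs(residual).max() < 1e-10

    def test_full_rank_reconstruction_is_complete(self):
        rng = np.random.default_rng(1)
        matrix = rng.random((9, 5))
        model = pca_fit(matrix, k=5)
        recon = pca_transform(model, matrix) @ model.components + model.mean_spectrum
        np.testing.assert_allclose(recon, matrix, atol=1e-8)

    def test_components_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        matrix = rng.random((10, 12))
        model = pca_fit(matrix, k=7)
        centred = matrix - matrix.mean(0)
        eigenvalues, eigenvectors = np.linalg.eigh(centred.T @ centred / 9)
        order = np.argsort(eigenvalues)[::-1]
        np.testing.assert_allclose(model.explained_variance, eigenvalues[order][:7], atol=1e-10)
        for i in range(7):
            dot = abs(model.components[i] @ eigenvectors[:, order[i]])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_components_are_orthonormal(self):
        rng = np.random.default_rng(3)
        model = pca_fit(rng.random((30, 20)), k=7)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(7), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_rank_deficit_reported(self):
        matrix = np.tile(np.arange(5.0), (6, 1))  # rank 1 after centring
        with pytest.raises(DataError, match="rank"):
            pca_fit(matrix, k=3)


class TestLogisticFit:
    def test_symmetric_null_problem_gives_zero_coefficients(self):
        scores = np.zeros((8, 3))
        labels = np.array([0, 1] * 4)
        model = logistic_fit(scores, labels, ridge_penalty=1e-4)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-8)

    def test_penalised_gradient_vanishes_at_optimum(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 3))
        y = (x[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        model = logistic_fit(x, y, ridge_penalty=0.1)
        design = np.column_stack([np.ones(40), x])
        beta = np.concatenate([[model.intercept], model.weights])
        mu = 1 / (1 + np.exp(-design @ beta))
        gradient = design.T @ (y - mu) - np.concatenate([[0.0], 0.1 * model.weights])
        assert np.abs(gradient).max() < 1e-8

    def test_separable_toy_matches_grid_search_oracle(self):
        x = np.array([[-2.0, -1.5], [-1.8, -0.5], [-1.0, -1.0], [1.2, 0.8], [1.5, 1.7], [2.0, 0.4]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = logistic_fit(x, y, ridge_penalty=1.0)
        oracle = logistic_grid_oracle(x, y, ridge=1.0)
        np.testing.assert_allclose(
            np.concatenate([[model.intercept], model.weights]), oracle, atol=1e-3
        )

    def test_single_class_labels_rejected(self):
        with pytest.raises(DataError):
            logistic_fit(np.ones((4, 2)), np.ones(4))


class TestPatientScores:
    def test_median_rules(self):
        meta = pd.DataFrame({"patient_id": ["a"] + ["b"] * 3 + ["c"] * 4})
        probabilities = [0.73, 0.2, 0.4, 0.9, 0.2, 0.4, 0.6, 1.0]
        scores = patient_scores(np.array(probabilities), meta)
        assert scores["a"] == pytest.approx(0.73)
        assert scores["b"] == pytest.approx(0.4)
        assert scores["c"] == pytest.approx(0.5)  # even count → midpoint


class TestMetrics:
    def test_perfect_separation_and_total_ties(self):
        labels = np.array([1, 1, 0, 0])
        assert auroc(np.array([0.9, 0.8, 0.2, 0.1]), labels) == 1.0
        assert auroc(np.array([0.5, 0.5, 0.5, 0.5]), labels) == 0.5

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=40)
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) == pytest.approx(auroc_bruteforce(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=5.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, power, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(20)
        labels = np.concatenate([np.ones(10, int), np.zeros(10, int)])
        assert auroc(scores, labels) == pytest.approx(auroc(scores**power, labels), abs=1e-12)

    def test_sensitivity_specificity_at_threshold(self):
        scores = np.array([0.9, 0.6, 0.4, 0.2, 0.5])
        labels = np.array([1, 1, 1, 0, 0])
        sens, spec = sensitivity_specificity(scores, labels, threshold=0.5)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(1 / 2)  # 0.5 counts as positive call


def toy_dataset(n_patients=8, per_patient=6, n_features=10, effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = pd.Series(
        ([1, 0] * n_patients)[:n_patients],
        index=pd.Index([f"P{i}" for i in range(n_patients)], name="patient_id"),
    )
    rows, meta = [], []
    for pid, label in labels.items():
        base = rng.normal(size=n_features)
        for j in range(per_patient):
            spectrum = base + rng.normal(scale=0.5, size=n_features)
            spectrum[2] += effect * label
            rows.append(spectrum)
            meta.append({"patient_id": pid, "row": 0, "col": j})
    return (
        SpectralDataset(
            matrix=np.array(rows), axis=np.arange(n_features, dtype=float), meta=pd.DataFrame(meta)
        ),
        labels,
    )


class TestBootstrapEvaluate:
    def test_same_seed_reproduces_summary_exactly(self):
        dataset, labels = toy_dataset()
        a, scores_a = bootstrap_evaluate(dataset, labels, n_replicates=25, seed=9, n_components=3)
        b, scores_b = bootstrap_evaluate(dataset, labels, n_replicates=25, seed=9, n_components=3)
        pd.testing.assert_frame_equal(a.per_replicate, b.per_replicate)
        pd.testing.assert_series_equal(scores_a, scores_b)
        assert a.median_auroc == a.per_replicate["auroc"].median()

    def test_out_of_bag_rows_never_enter_fitting(self, monkeypatch):
        dataset, labels = toy_dataset(n_patients=10)
        # tag every datapoint with its patient index in a dedicated feature,
        # then intercept each replicate's fit to assert train/test disjointness
        tagged = dataset.matrix.copy()
        patient_index = {p: i for i, p in enumerate(labels.index)}
        tags = dataset.meta["patient_id"].map(patient_index).to_numpy(float)
        tagged[:, -1] = tags
        dataset = SpectralDataset(matrix=tagged, axis=dataset.axis, meta=dataset.meta)

        original = classify_module._fit_and_score
        seen = []

        def spy(train_matrix, train_labels, test_matrix, n_components, ridge_penalty):
            seen.append((set(train_matrix[:, -1]), set(test_matrix[:, -1])))
            return original(train_matrix, train_labels, test_matrix, n_components, ridge_penalty)

        monkeypatch.setattr(classify_module, "_fit_and_score", spy)
        bootstrap_evaluate(dataset, labels, n_replicates=20, seed=1, n_components=3)
        replicate_calls = seen[:-1]  # last call is the full-data model
        assert len(replicate_calls) == 20
        for train_tags, test_tags in replicate_calls:
            assert train_tags.isdisjoint(test_tags)

    def test_planted_signal_localised_by_largest_weight_component(self):
        dataset, labels = toy_dataset(n_patients=12, per_patient=8, effect=4.0, seed=3)
        model = pca_fit(dataset.matrix, k=5)
        scores = pca_transform(model, dataset.matrix)
        row_labels = dataset.meta["patient_id"].map(labels).to_numpy()
        logistic = logistic_fit(scores, row_labels, ridge_penalty=1e-2)
        top = int(np.argmax(np.abs(logistic.weights)))
        assert int(np.argmax(np.abs(model.components[top]))) == 2  # planted feature

    def test_too_few_replicates_rejected(self):
        dataset, labels = toy_dataset()
        with pytest.raises(ConfigError):
            bootstrap_evaluate(dataset, labels, n_replicates=5)

    def test_single_class_labels_rejected(self):
        dataset, labels = toy_dataset()
        with pytest.raises(DegenerateInputError):
            bootstrap_evaluate(dataset, labels * 0, n_replicates=20)

    def test_label_excluded_patients_still_scored(self):
        dataset, labels = toy_dataset(n_patients=8)
        _, scores = bootstrap_evaluate(dataset, labels.drop("P7"), n_replicates=15, seed=2, n_components=3)
        assert "P7" in scores.index
        assert 0.0 <= scores["P7"] <= 1.0


class TestEndpointIntegration:
    def test_outcome_labels_feed_classifier(self, small_cohort, preprocessed_small):
        dataset, _ = preprocessed_small
        labels = label_endpoint(small_cohort.cohort, 11.0)
        if labels.nunique() < 2 or labels.value_counts().min() < 2:
            pytest.skip("degenerate endpoint split for this fixture seed")
        summary, scores = bootstrap_evaluate(dataset, labels, n_replicates=15, seed=4)
        assert 0.0 <= summary.median_auroc <= 1.0
        assert set(scores.index) == set(dataset.meta["patient_id"].unique())
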