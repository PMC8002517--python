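import numpy as np
import pytest

import eegident as ei


def gaussian_space(n_classes=4, n_per_class=9, dim=10, separation=50.0, seed=0):
    """Well-separated Gaussian blobs, one per subject."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k in range(n_classes):
        center = np.zeros(dim)
        center[k % dim] = separation
        rows.append(center + rng.standard_normal((n_per_class, dim)))
        labels += [k + 1] * n_per_class
    return ei.FeatureSpace(np.vstack(rows), np.array(labels), config_id="blob")


class TestSubset:
    def test_full_label_set_is_identity(self):
        space = gaussian_space()
        sub = ei.subset_features(space, {1, 2, 3, 4})
        np.testing.assert_array_equal(sub.matrix, space.matrix)

    def test_row_count_is_classes_times_vectors(self):
        space = gaussian_space(n_classes=8, n_per_class=19)
        sub = ei.subset_features(space, {2, 4, 6, 7, 8})
        assert sub.n_rows == 5 * 19
        assert set(sub.labels) == {2, 4, 6, 7, 8}

    def test_order_preserved(self):
        space = gaussian_space()
        sub = ei.subset_features(space, {1, 3})
        mask = np.isin(space.labels, [1, 3])
        np.testing.assert_array_equal(sub.matrix, space.matrix[mask])

    def test_empty_and_unknown_labels_rejected(self):
        space = gaussian_space()
        with pytest.raises(ValueError):
            ei.subset_features(space, set())
        with pytest.raises(KeyError):
            ei.subset_features(space, {1, 99})


class TestEvaluateStep:
    def test_separable_classes_classified_perfectly(self):
        space = gaussian_space(separation=50.0)
        result = ei.evaluate_step(space, ei.ClassifierSpec(), kfold=3, seed=0)
        assert result.accuracy == 1.0
        assert result.n_classes == 4
        np.testing.assert_allclose(result.fold_accuracies, 1.0)

    def test_accuracy_is_mean_of_fold_accuracies(self):
        space = gaussian_space(separation=2.0, seed=3)
        result = ei.evaluate_step(space, ei.ClassifierSpec(), kfold=3, seed=1)
        assert result.accuracy == pytest.approx(result.fold_accuracies.mean())

    def test_deterministic_given_seed(self):
        space = gaussian_space(separation=2.0)
        a = ei.evaluate_step(space, ei.ClassifierSpec(), 3, seed=7)
        b = ei.evaluate_step(space, ei.ClassifierSpec(), 3, seed=7)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_kfold_exceeding_class_rows_rejected(self):
        space = gaussian_space(n_per_class=2)
        with pytest.raises(ValueError, match="kfold"):
            ei.evaluate_step(space, ei.ClassifierSpec(), kfold=3, seed=0)

    @pytest.mark.parametrize("kind", ["knn", "naive_bayes", "decision_tree", "lda"])
    def test_all_classifier_kinds_plug_compatible(self, kind):
        space = gaussian_space(separation=50.0)
        spec = ei.ClassifierSpec(kind=kind)
        result = ei.evaluate_step(space, spec, kfold=3, seed=0)
        assert 0.9 <= result.accuracy <= 1.0


@pytest.fixture(scope="module")
def sim():
    cfg = ei.OpennessConfig(n_subjects=8, first_size=3, last_size=7,
                            n_steps=3, n_sequences=4, seed=2)
    return ei.simulate_openness(cfg)


class TestRunOpenness:
    def test_matrix_shape_and_mean_identity(self, sim):
        space = gaussian_space(n_classes=8, n_per_class=9, separation=3.0)
        oa = ei.run_openness(space, sim, ei.ClassifierSpec(), 3, seed=0)
        assert oa.per_sequence.shape == (4, 3)
        np.testing.assert_allclose(oa.mean, oa.per_sequence.mean(axis=0))

    def test_single_sequence_mean_equals_row(self):
        cfg = ei.OpennessConfig(n_subjects=8, first_size=3, last_size=7,
                                n_steps=3, n_sequences=1, seed=2)
        sim = ei.simulate_openness(cfg)
        space = gaussian_space(n_classes=8, n_per_class=9, separation=3.0)
        oa = ei.run_openness(space, sim, ei.ClassifierSpec(), 3, seed=0)
        np.testing.assert_array_equal(oa.mean, oa.per_sequence[0])

    def test_missing_simulation_labels_rejected(self, sim):
        space = gaussian_space(n_classes=4)  # labels 1..4 < population 8
        with pytest.raises(KeyError):
            ei.run_openness(space, sim, ei.ClassifierSpec(), 3, seed=0)

    def test_results_csv_roundtrip(self, sim, tmp_path):
        from eegident.evaluation import read_results, write_results

        space = gaussian_space(n_classes=8, n_per_class=9, separation=3.0)
        oa = ei.run_openness(space, sim, ei.ClassifierSpec(), 3, seed=0)
        path = write_results(oa, sim, "blob", tmp_path)
        cid, back = read_results(path)
        assert cid == "blob"
        np.testing.assert_allclose(back.per_sequence, oa.per_sequence)
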