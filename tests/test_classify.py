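import numpy as np
import pytest

from msigrade.classify import (PixelClassifier, SpectralLibrary,
                               build_spectral_library,
                               cross_validate_components,
                               library_from_annotations, one_hot,
                               predict_histology, subsample_library,
                               train_necrosis_subtyper, train_plsda,
                               train_two_stage)
from msigrade.core import (POSITIVE, FeatureDescriptor, HistologyLabel,
                           PeakMatrix, PixelGrid)
from msigrade.segment import SegmentationMap, map_segments_to_histology
from msigrade.synthetic import default_signature_table

H = HistologyLabel


def _separable_library(n=20, seed=0):
    """Two classes that differ only in one feature (disjoint supports)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(1.0, 2.0, (2 * n, 3))
    X[:n, 0] += 10.0
    labels = [H.TUMOR] * n + [H.FIBROSIS] * n
    return SpectralLibrary(X, labels, ["f0", "f1", "f2"])


class TestTraining:
    def test_separable_single_component(self):
        lib = _separable_library()
        model = train_plsda(lib, 1)
        assert model.predict_labels(lib.X) == lib.labels

    def test_full_components_equal_least_squares(self):
        """With A = rank(X), PLS scores equal the normal-equations
        regression of one-hot labels on centered X."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        labels = [H.TUMOR, H.TUMOR, H.FIBROSIS, H.FIBROSIS,
                  H.ADJACENT_LIVER, H.ADJACENT_LIVER]
        lib = SpectralLibrary(X, labels, [f"f{j}" for j in range(4)])
        model = train_plsda(lib, 4)
        Y = one_hot(labels, lib.classes)
        Xc = X - X.mean(axis=0)
        B = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)[0]
        oracle = Xc @ B + Y.mean(axis=0)
        np.testing.assert_allclose(model.predict_scores(X), oracle,
                                   atol=1e-10)

    def test_centering_invariance(self):
        """Adding a constant to one feature leaves predictions unchanged."""
        lib = _separable_library()
        base = train_plsda(lib, 2).predict_scores(lib.X)
        shifted = lib.X.copy()
        shifted[:, 1] += 57.0
        lib2 = SpectralLibrary(shifted, lib.labels, lib.feature_names)
        out = train_plsda(lib2, 2).predict_scores(shifted)
        np.testing.assert_allclose(out, base, atol=1e-8)

    def test_row_order_invariance(self):
        lib = _separable_library()
        perm = np.random.default_rng(1).permutation(len(lib.labels))
        lib2 = SpectralLibrary(lib.X[perm], [lib.labels[i] for i in perm],
                               lib.feature_names)
        a = train_plsda(lib, 2)
        b = train_plsda(lib2, 2)
        np.testing.assert_allclose(a.predict_scores(lib.X),
                                   b.predict_scores(lib.X), atol=1e-8)

    def test_single_class_errors(self):
        lib = _separable_library()
        mono = SpectralLibrary(lib.X, [H.TUMOR] * len(lib.labels),
                               lib.feature_names)
        with pytest.raises(ValueError):
            train_plsda(mono, 1)

    def test_excess_components_error(self):
        lib = _separable_library(n=3)
        with pytest.raises(ValueError):
            train_plsda(lib, 10)


class TestCrossValidation:
    def test_single_candidate_returned(self):
        lib = _separable_library()
        chosen, _ = cross_validate_components(lib, [1], folds=4, seed=0)
        assert chosen == 1

    def test_one_standard_error_rule_prefers_small(self):
        """On separable data every A is perfect, so A=1 is chosen."""
        lib = _separable_library(n=30)
        chosen, results = cross_validate_components(lib, [1, 2, 3],
                                                    folds=5, seed=0)
        assert chosen == 1
        assert all(acc == 1.0 for acc, _ in results.values())

    def test_deterministic_given_seed(self):
        lib = _separable_library(n=15, seed=3)
        a = cross_validate_components(lib, [1, 2], folds=3, seed=7)
        b = cross_validate_components(lib, [1, 2], folds=3, seed=7)
        assert a == b

    def test_small_class_errors(self):
        lib = _separable_library(n=2)
        with pytest.raises(ValueError, match="fewer rows"):
            cross_validate_components(lib, [1], folds=5)


class TestPrediction:
    def test_training_rows_reproduced(self):
        lib = _separable_library()
        model = train_plsda(lib, 1)
        grid = PixelGrid.full_raster(len(lib.labels), 1)
        feats = [FeatureDescriptor(POSITIVE, 500.0 + j) for j in range(3)]
        pm = PeakMatrix(grid, feats, lib.X)
        model.feature_names = pm.feature_names
        labels, scores = predict_histology(model, pm)
        assert labels == lib.labels
        assert scores.shape == (len(lib.labels), 2)

    def test_missing_feature_named_in_error(self):
        lib = _separable_library()
        model = train_plsda(lib, 1)
        model.feature_names = ["POS_500.00", "POS_501.00", "POS_502.00"]
        grid = PixelGrid.full_raster(2, 1)
        pm = PeakMatrix(grid, [FeatureDescriptor(POSITIVE, 500.0)],
                        np.ones((2, 1)))
        with pytest.raises(ValueError, match="POS_501.00"):
            predict_histology(model, pm)


class TestLibraryBuilding:
    def _seg_dataset(self, seed=0):
        pm, truth = _toy_annotated(seed)
        seg = SegmentationMap(truth, k=2, r=0, seed=0, inertia=0.0,
                              grid=pm.grid)
        annotation = [H.TUMOR if t else H.FIBROSIS for t in truth]
        mapping = map_segments_to_histology(seg, annotation)
        return pm, seg, mapping

    def test_rows_pooled_across_samples(self):
        d1 = self._seg_dataset(0)
        d2 = self._seg_dataset(1)
        lib = build_spectral_library([d1, d2])
        assert lib.X.shape[0] == 20
        counts = lib.class_counts()
        assert counts[H.TUMOR] == 10 and counts[H.FIBROSIS] == 10
        assert set(lib.sample_ids) == {0, 1}

    def test_empty_feature_intersection_errors(self):
        pm1, seg, mapping = self._seg_dataset(0)
        pm2 = PeakMatrix(pm1.grid,
                         [FeatureDescriptor(POSITIVE, 900.0),
                          FeatureDescriptor(POSITIVE, 901.0)],
                         pm1.values)
        with pytest.raises(ValueError, match="intersection"):
            build_spectral_library([(pm1, seg, mapping), (pm2, seg, mapping)])

    def test_subsampling_caps_class_size(self):
        lib = _separable_library(n=20)
        sub = subsample_library(lib, 5, seed=0)
        assert all(v == 5 for v in sub.class_counts().values())


def _toy_annotated(seed=0):
    rng = np.random.default_rng(seed)
    grid = PixelGrid.full_raster(2, 5)
    truth = (grid.coords[:, 0] >= 1).astype(int)
    base = np.where(truth[:, None], [8.0, 1.0], [1.0, 8.0])
    values = base * np.exp(rng.normal(0, 0.1, base.shape))
    feats = [FeatureDescriptor(POSITIVE, 700.0),
             FeatureDescriptor(POSITIVE, 800.0)]
    return PeakMatrix(grid, feats, values), truth


class TestNecrosisSubtyping:
    def test_un_vs_iln_recovered_from_published_folds(self):
        """Two-class log-normal data generated with the published UN and
        ILN marker fold changes is subtyped with >= 0.9 accuracy."""
        sig = default_signature_table()
        rng = np.random.default_rng(5)
        n = 300
        rows, labels = [], []
        for lab in (H.USUAL_NECROSIS, H.INFARCT_LIKE_NECROSIS):
            base = sig.row(lab)
            rows.append(base * np.exp(rng.normal(0, 0.944, (n, base.size))))
            labels += [lab] * n
        lib = SpectralLibrary(np.log(np.vstack(rows)), labels,
                              sig.feature_names)
        model = train_necrosis_subtyper(lib, 2)
        pred = model.predict_labels(lib.X)
        acc = np.mean([p == t for p, t in zip(pred, labels)])
        assert acc >= 0.9

    def test_two_stage_routes_necrosis(self):
        sig = default_signature_table()
        rng = np.random.default_rng(8)
        n = 60
        rows, labels = [], []
        for lab in (H.TUMOR, H.FIBROSIS, H.USUAL_NECROSIS,
                    H.INFARCT_LIKE_NECROSIS):
            base = sig.row(lab)
            rows.append(base * np.exp(rng.normal(0, 0.3, (n, base.size))))
            labels += [lab] * n
        lib = SpectralLibrary(np.log(np.vstack(rows)), labels,
                              sig.feature_names)
        clf = train_two_stage(lib, n_components=6)
        pred = clf.predict_labels(lib.X)
        acc = np.mean([p == t for p, t in zip(pred, labels)])
        assert acc >= 0.95
        assert H.NECROSIS_UNSPECIFIED not in set(pred)


@pytest.fixture(scope="module")
def phantom_classification(default_phantom, default_matrix):
    """Fitted classifier predictions on the default phantom (shared)."""
    clf = PixelClassifier(spatial_r=1, n_components=16, include_mucin=False)
    clf.fit([(default_matrix, default_phantom.labels)])
    pred, _ = clf.classify(default_matrix)
    return pred


class TestPixelClassifier:
    def test_phantom_accuracy(self, default_phantom, phantom_classification):
        """Six-class per-pixel accuracy on the default phantom reaches
        0.90 through the spatially augmented representation."""
        truth = default_phantom.labels
        keep = [i for i, t in enumerate(truth) if t != H.MUCIN_MATRIX]
        acc = np.mean([phantom_classification[i] == truth[i] for i in keep])
        assert acc >= 0.90

    def test_beats_best_single_feature_threshold(self, default_phantom,
                                                 default_matrix,
                                                 phantom_classification):
        """Multivariate PLS-DA dominates the best single-feature threshold
        rule (one class above a cut, one below) on the same pixels."""
        truth = np.array([t.value for t in default_phantom.labels])
        keep = truth != H.MUCIN_MATRIX.value
        X = default_matrix.values[keep]
        y = truth[keep]
        classes = np.unique(y)
        onehot = (y[:, None] == classes[None, :]).astype(int)
        totals = onehot.sum(axis=0)
        best_single = 0.0
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            below = np.vstack([np.zeros(len(classes), dtype=int),
                               np.cumsum(onehot[order], axis=0)])
            above = totals[None, :] - below
            score = (below.max(axis=1) + above.max(axis=1)).max() / len(y)
            best_single = max(best_single, score)
        predk = [phantom_classification[i] for i in np.flatnonzero(keep)]
        yk = [default_phantom.labels[i] for i in np.flatnonzero(keep)]
        acc = np.mean([p == t for p, t in zip(predk, yk)])
        assert acc >= best_single

    def test_model_serialization_round_trip(self, tmp_path):
        from msigrade.classify import load_model, save_model
        lib = _separable_library()
        model = train_plsda(lib, 2)
        path = str(tmp_path / "model.joblib")
        save_model(model, path)
        back = load_model(path)
        assert back.class_order == model.class_order
        assert back.feature_names == model.feature_names
        np.testing.assert_allclose(back.predict_scores(lib.X),
                                   model.predict_scores(lib.X))

    def test_unlabelled_library_errors(self, default_matrix):
        with pytest.raises(ValueError):
            library_from_annotations(default_matrix,
                                     [None] * len(default_matrix.grid))
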