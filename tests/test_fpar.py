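"""FPAR estimation: normalization, RFE, model training, empirical stretch."""

import numpy as np
import pytest

from cropnpp.errors import (DegenerateBoundsError, FeatureMismatchError,
                            TrainingError)
from cropnpp.fpar import (CnnConfig, EmpiricalFparParams, FeatureMatrix,
                          apply_scaling, empirical_fpar, invert_scaling,
                          load_model, normalize_features, predict_fpar,
                          rfe_rank, save_model, train_cnn,
                          train_tree_baseline)
from cropnpp.grids import Grid
from cropnpp.indices import INDEX_NAMES, compute_all


class TestNormalize:
    def test_minmax_definition(self):
        m = normalize_features(FeatureMatrix(np.array([[2.0], [4.0], [6.0]]), ["a"]))
        np.testing.assert_allclose(m.values[:, 0], [0, 0.5, 1])
        assert m.scaling["a"] == (2.0, 6.0)

    def test_constant_feature_dropped_with_warning(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant feature"):
            m = normalize_features(FeatureMatrix(X, ["const", "var"]))
        assert m.feature_names == ["var"]

    def test_scaling_roundtrip(self, rng):
        X = rng.uniform(-3, 7, (30, 4))
        names = list("abcd")
        m = normalize_features(FeatureMatrix(X, names))
        new = rng.uniform(-3, 7, (10, 4))
        back = invert_scaling(apply_scaling(new, names, m.scaling), names, m.scaling)
        np.testing.assert_allclose(back, new, atol=1e-12)


class TestRfe:
    def test_dominant_feature_recovered(self, rng):
        X = rng.uniform(0, 1, (300, 15))
        y = np.clip(0.1 + 0.8 * X[:, INDEX_NAMES.index("DVI")]
                    + rng.normal(0, 0.005, 300), 0, 1)
        res = rfe_rank(FeatureMatrix(X, list(INDEX_NAMES)), y, n_keep=4,
                       seed=0, cv=0)
        assert res.ranking["DVI"] == 1

    def test_keep_all_is_identity(self, rng):
        X = rng.uniform(0, 1, (100, 5))
        y = np.clip(X.mean(axis=1), 0, 1)
        res = rfe_rank(FeatureMatrix(X, list("abcde")), y, n_keep=5, cv=0)
        assert sorted(res.selected) == list("abcde")
        assert sorted(res.ranking.values()) == [1, 2, 3, 4, 5]

    def test_duplicate_feature_eliminated(self, rng):
        base = rng.uniform(0, 1, 200)
        X = np.column_stack([base, base, rng.uniform(0, 1, 200)])
        y = np.clip(0.2 + 0.6 * base, 0, 1)
        res = rfe_rank(FeatureMatrix(X, ["dup1", "dup2", "noise"]), y,
                       n_keep=1, cv=0)
        assert res.selected[0] in ("dup1", "dup2")

    def test_n_keep_out_of_range(self, rng):
        m = FeatureMatrix(rng.uniform(0, 1, (50, 3)), list("abc"))
        with pytest.raises(ValueError, match="n_keep"):
            rfe_rank(m, np.full(50, 0.5), n_keep=0)

    def test_cv_scores_recorded_per_step(self, rng):
        X = rng.uniform(0, 1, (120, 4))
        y = np.clip(X[:, 0], 0, 1)
        res = rfe_rank(FeatureMatrix(X, list("abcd")), y, n_keep=2, cv=3)
        assert len(res.scores) == 3  # 4 -> 3 -> 2 features: 3 fits scored


class TestCnnTraining:
    def test_constant_target(self, rng):
        X = rng.uniform(0, 1, (200, 15))
        model = train_cnn(FeatureMatrix(X, list(INDEX_NAMES)),
                          np.full(200, 0.5), CnnConfig(seed=1))
        assert model.training_report.mae <= 0.01

    def test_seeded_determinism(self, rng):
        X = rng.uniform(0, 1, (150, 15))
        y = np.clip(X[:, 0], 0, 1)
        m1 = train_cnn(FeatureMatrix(X, list(INDEX_NAMES)), y,
                       CnnConfig(epochs=2, seed=5))
        m2 = train_cnn(FeatureMatrix(X, list(INDEX_NAMES)), y,
                       CnnConfig(epochs=2, seed=5))
        assert m1.training_report.to_dict() == m2.training_report.to_dict()

    def test_too_few_samples(self, rng):
        m = FeatureMatrix(rng.uniform(0, 1, (50, 15)), list(INDEX_NAMES))
        with pytest.raises(TrainingError):
            train_cnn(m, np.full(50, 0.5))


class TestTreeBaselines:
    @pytest.mark.parametrize("kind", ["gbdt", "xgb"])
    def test_linear_recovery_and_determinism(self, kind, rng):
        X = rng.uniform(0, 1, (400, 5))
        y = np.clip(0.1 + 0.7 * X[:, 2] + rng.normal(0, 0.01, 400), 0, 1)
        m = FeatureMatrix(X, list("abcde"))
        r1 = train_tree_baseline(m, y, kind=kind, seed=0).training_report
        r2 = train_tree_baseline(m, y, kind=kind, seed=0).training_report
        assert r1.r2 >= 0.95
        assert r1.to_dict() == r2.to_dict()

    def test_constant_target(self, rng):
        m = FeatureMatrix(rng.uniform(0, 1, (120, 3)), list("abc"))
        rep = train_tree_baseline(m, np.full(120, 0.4)).training_report
        assert rep.mae == pytest.approx(0.0, abs=1e-6)


class TestPrediction:
    def test_clipping_to_unit_interval(self, rng):
        X = rng.uniform(0, 1, (150, 15))
        y = np.clip(X[:, 0], 0, 1)
        model = train_cnn(FeatureMatrix(X, list(INDEX_NAMES)), y,
                          CnnConfig(epochs=1, seed=2))
        pred = predict_fpar(model, FeatureMatrix(rng.uniform(-5, 5, (20, 15)),
                                                 list(INDEX_NAMES)))
        assert (pred >= 0).all() and (pred <= 1).all()

    def test_feature_mismatch_error_lists_names(self, rng):
        X = rng.uniform(0, 1, (150, 15))
        model = train_cnn(FeatureMatrix(X, list(INDEX_NAMES)),
                          np.clip(X[:, 0], 0, 1), CnnConfig(epochs=1, seed=2))
        bad = FeatureMatrix(rng.uniform(0, 1, (5, 2)), ["NDVI", "bogus"])
        with pytest.raises(FeatureMismatchError, match="RVI"):
            predict_fpar(model, bad)

    def test_grid_prediction_equals_vector_prediction(self, small_scene):
        from cropnpp.scene import scene_training_samples

        X, y = scene_training_samples(small_scene, n_samples=400)
        model = train_cnn(normalize_features(X), y, CnnConfig(epochs=2, seed=3))
        cube = compute_all(small_scene.stacks[7])
        grid_pred = predict_fpar(model, cube)
        mat, valid = cube.to_matrix(model.feature_names)
        vec_pred = predict_fpar(
            model, FeatureMatrix(mat, list(model.feature_names)))
        np.testing.assert_allclose(grid_pred.values[valid], vec_pred, atol=1e-12)
        assert (grid_pred.mask == ~valid).all()


class TestEmpiricalFpar:
    def grids(self, ndvi, rvi):
        return Grid(np.asarray(ndvi, float)), Grid(np.asarray(rvi, float))

    def test_upper_and_lower_stretch_bounds(self):
        p = EmpiricalFparParams(ndvi_min=0.1, ndvi_max=0.8, sr_min=1.0, sr_max=8.0)
        ndvi, rvi = self.grids([[0.8]] * 2, [[8.0]] * 2)
        assert empirical_fpar(ndvi, rvi, p).values[0, 0] == pytest.approx(0.95)
        ndvi, rvi = self.grids([[0.1]] * 2, [[1.0]] * 2)
        assert empirical_fpar(ndvi, rvi, p).values[0, 0] == pytest.approx(0.001)

    def test_alpha_one_is_pure_ndvi_stretch(self):
        p = EmpiricalFparParams(ndvi_min=0.0, ndvi_max=1.0, sr_min=0.0,
                                sr_max=10.0, alpha=1.0)
        ndvi, rvi = self.grids([[0.5, 0.25]], [[9.0, 1.0]])
        out = empirical_fpar(ndvi, rvi, p).values
        want = 0.5 * (0.95 - 0.001) + 0.001
        assert out[0, 0] == pytest.approx(want)

    def test_output_always_in_unit_interval(self, rng):
        ndvi = Grid(rng.uniform(-0.5, 1.0, (10, 10)))
        rvi = Grid(rng.uniform(0.1, 20.0, (10, 10)))
        out = empirical_fpar(ndvi, rvi)
        v = out.valid_values()
        assert (v >= 0).all() and (v <= 1).all()

    def test_degenerate_bounds_raise(self):
        p = EmpiricalFparParams(ndvi_min=0.5, ndvi_max=0.5, sr_min=0, sr_max=1)
        ndvi, rvi = self.grids([[0.5]] * 2, [[1.0]] * 2)
        with pytest.raises(DegenerateBoundsError):
            empirical_fpar(ndvi, rvi, p)


def test_model_archive_roundtrip(tmp_path, rng):
    X = rng.uniform(0, 1, (150, 15))
    y = np.clip(X[:, 0], 0, 1)
    model = train_cnn(normalize_features(FeatureMatrix(X, list(INDEX_NAMES))),
                      y, CnnConfig(epochs=1, seed=4))
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    assert back.feature_names == model.feature_names
    new = FeatureMatrix(rng.uniform(0, 1, (12, 15)), list(INDEX_NAMES))
    np.testing.assert_allclose(predict_fpar(back, new),
                               predict_fpar(model, new), atol=1e-12)
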