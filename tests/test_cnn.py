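import numpy as np
import pytest

from lsphen.cnn import (
    CVScheme,
    ModelSpec,
    TrainConfig,
    build_model,
    crossvalidate,
    evaluate_metrics,
    extract_features,
    mse,
    pearson,
    stack_inputs,
    train_model,
)
from lsphen.exceptions import (
    ShapeError,
    TrainingDivergedError,
    UndefinedCorrelationError,
)


def _tiny_model(variant="rgb_dsm", hw=(32, 32), seed=0):
    return build_model(ModelSpec(variant=variant), hw, seed=seed)


def _tiny_data(n=12, c=4, hw=(32, 32), seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, c, *hw)).astype(np.float32)
    y = rng.standard_normal((n, 5)).astype(np.float32)
    return x, y


# ---------------------------------------------------------------------------
# model construction / forward contracts
# ---------------------------------------------------------------------------


class TestBuildModel:
    def test_shape_contract(self):
        model = _tiny_model()
        x, _ = _tiny_data(n=2)
        features, estimates = model.forward(x)
        assert features.shape == (2, 30)
        assert estimates.shape == (2, 5)

    def test_fourteen_weighted_layers(self):
        assert _tiny_model().n_weighted_layers == 14

    def test_zero_weight_head_returns_bias(self):
        model = _tiny_model()
        model.head.params["W"][:] = 0.0
        model.head.params["b"][:] = np.arange(5, dtype=np.float32)
        x, _ = _tiny_data(n=3)
        _, est = model.forward(x)
        np.testing.assert_allclose(est, np.tile(np.arange(5), (3, 1)), atol=1e-6)

    def test_rgb_dsm_rejects_three_channels(self):
        model = _tiny_model("rgb_dsm")
        with pytest.raises(ShapeError, match="4 channels"):
            model.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))

    @pytest.mark.parametrize("variant,channels", [("rgb", 3), ("dsm", 1), ("rgb_dsm", 4)])
    def test_variant_channels(self, variant, channels):
        model = _tiny_model(variant)
        assert model.spec.input_channels == channels
        x = np.zeros((1, channels, 32, 32), dtype=np.float32)
        model.forward(x)

    def test_incompatible_input_size_names_block(self):
        with pytest.raises(ShapeError, match="conv block"):
            build_model(ModelSpec(), (33, 33))

    def test_matrix_form_matches_per_trait_equations(self):
        """Stacking the per-trait linear equations equals X W + 1 b^T exactly."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((7, 30))
        W = rng.standard_normal((30, 5))
        b = rng.standard_normal(5)
        matrix_form = X @ W + b
        per_trait = np.column_stack(
            [[W[:, i] @ X[k] + b[i] for k in range(7)] for i in range(5)]
        )
        np.testing.assert_allclose(matrix_form, per_trait, rtol=1e-12)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class TestTrainModel:
    def test_constant_zero_targets_drive_mse_down(self):
        x, _ = _tiny_data(n=16)
        y = np.zeros((16, 5), dtype=np.float32)
        model = _tiny_model()
        res = train_model(
            model, (x, y), (x, y), TrainConfig(epochs=40, batch_size=8, seed=0)
        )
        assert res.best_val_mse < 0.5
        assert res.best_val_mse < 0.01 * res.log["val_mse"].iloc[0]

    def test_deterministic_given_seed(self):
        x, y = _tiny_data(n=16, seed=2)
        cfgs = TrainConfig(epochs=2, batch_size=8, seed=5)
        r1 = train_model(_tiny_model(seed=3), (x[:12], y[:12]), (x[12:], y[12:]), cfgs)
        r2 = train_model(_tiny_model(seed=3), (x[:12], y[:12]), (x[12:], y[12:]), cfgs)
        assert r1.best_val_mse == r2.best_val_mse
        np.testing.assert_array_equal(r1.model.W, r2.model.W)

    def test_checkpoint_no_worse_than_final_epoch(self):
        x, y = _tiny_data(n=20, seed=3)
        res = train_model(
            _tiny_model(), (x[:16], y[:16]), (x[16:], y[16:]),
            TrainConfig(epochs=5, batch_size=8, seed=1),
        )
        assert res.best_val_mse <= res.log["val_mse"].iloc[-1] + 1e-12

    def test_nonfinite_loss_aborts_with_diagnostics(self):
        x, y = _tiny_data(n=8)
        y = y.copy()
        y[0, 0] = np.nan
        with pytest.raises(TrainingDivergedError, match="epoch"):
            train_model(
                _tiny_model(), (x, y), (x, y), TrainConfig(epochs=1, batch_size=8, seed=0)
            )

    def test_empty_sets_rejected(self):
        x, y = _tiny_data(n=4)
        with pytest.raises(ValueError):
            train_model(_tiny_model(), (x[:0], y[:0]), (x, y), TrainConfig(epochs=1))

    def test_lr_schedule_reduces_on_plateau(self):
        from types import SimpleNamespace

        from lsphen.cnn.train import ReduceLROnPlateau

        opt = SimpleNamespace(lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=2, min_lr=1e-6)
        assert not sched.step(1.0)  # new best
        for _ in range(2):
            assert not sched.step(1.0)  # within patience
        assert sched.step(1.0)  # patience exceeded -> reduce
        assert opt.lr == pytest.approx(5e-4)
        # never below min_lr
        for _ in range(100):
            sched.step(1.0)
        assert opt.lr >= 1e-6

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(lr=1e-7, min_lr=1e-6)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


class TestExtractFeatures:
    def test_head_consistency(self):
        x, y = _tiny_data(n=10)
        res = train_model(
            _tiny_model(), (x[:8], y[:8]), (x[8:], y[8:]), TrainConfig(epochs=2, batch_size=8)
        )
        feats = extract_features(res.model, x)
        _, est = res.model.forward(x)
        est_from_head = feats.X @ res.model.W + res.model.b
        assert np.abs(est - est_from_head).max() < 1e-6

    def test_scaled_columns_standardised(self):
        x, _ = _tiny_data(n=20)
        model = _tiny_model()
        feats = extract_features(model, x)
        scaled = feats.scaled()
        assert np.abs(scaled.mean(axis=0)).max() < 1e-8
        np.testing.assert_allclose(scaled.std(axis=0, ddof=0), 1.0, atol=1e-8)

    def test_row_count_matches_input(self):
        x, _ = _tiny_data(n=40)
        feats = extract_features(_tiny_model(), x)
        assert feats.X.shape == (40, 30)

    def test_reference_set_controls_scaling(self):
        x, _ = _tiny_data(n=20)
        model = _tiny_model()
        feats = extract_features(model, x, reference=x[:10])
        ref_feats = extract_features(model, x[:10])
        np.testing.assert_allclose(feats.scaling_mean, ref_feats.scaling_mean)


# ---------------------------------------------------------------------------
# pearson + metrics
# ---------------------------------------------------------------------------


class TestPearson:
    def test_identity(self):
        a = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(a, a) == pytest.approx(1.0)

    def test_negation(self):
        a = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_hand_computed(self):
        # by hand: devs a=(-1,0,1), b=(-1/3,-4/3,5/3); cov*n = 2,
        # |a| = sqrt(2), |b| = sqrt(42)/3 -> r = 6/sqrt(84)
        assert pearson([1, 2, 3], [2, 1, 4]) == pytest.approx(6 / np.sqrt(84))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        assert pearson(a, 2 * b + 5) == pytest.approx(pearson(a, b))

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 2], [3, 4])

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 30))
        assert pearson(a, b) == pytest.approx(stats.pearsonr(a, b).statistic)


class TestEvaluateMetrics:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((20, 5))
        df = evaluate_metrics(y, y)
        assert np.allclose(df["r"], 1.0)

    def test_shuffled_predictions_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((2000, 5))
        df = evaluate_metrics(y, y[rng.permutation(len(y))])
        assert np.abs(df["r"]).max() < 0.08

    def test_subgroups_reported(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((30, 5))
        treatments = np.array(["control"] * 15 + ["drought"] * 15)
        df = evaluate_metrics(y, y, treatments)
        assert set(df["subgroup"]) == {"all", "control", "drought"}

    def test_small_subgroup_excluded(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((10, 5))
        treatments = np.array(["control"] * 8 + ["drought"] * 2)
        df = evaluate_metrics(y, y + 0.1 * rng.standard_normal((10, 5)), treatments)
        assert "drought" not in set(df["subgroup"])


# ---------------------------------------------------------------------------
# CV scheme and crossvalidate
# ---------------------------------------------------------------------------


class TestCVScheme:
    def test_folds_partition_units(self):
        scheme = CVScheme(k=5, repetitions=3, seed=0)
        units = list(range(47))
        for fold_of in scheme.assignments(units):
            assert sorted(fold_of) == units
            sizes = np.bincount(list(fold_of.values()), minlength=5)
            assert sizes.min() >= 9 and sizes.max() <= 10

    def test_deterministic(self):
        s = CVScheme(k=4, repetitions=2, seed=9)
        assert s.assignments(list(range(20))) == s.assignments(list(range(20)))

    def test_invalid(self):
        with pytest.raises(ValueError):
            CVScheme(unit="block")
        with pytest.raises(ValueError):
            CVScheme(k=1)


class TestCrossvalidate:
    def test_tiny_cv_runs_and_reports(self):
        x, y = _tiny_data(n=12, seed=4)
        res = crossvalidate(
            x, y, ModelSpec(), TrainConfig(epochs=1, batch_size=8, seed=0),
            CVScheme(k=3, repetitions=1, seed=0), augment_train=False,
        )
        assert set(res.summary["subgroup"]) == {"all"}
        assert len(res.summary) == 5  # one row per trait

    def test_augment_before_split_quadruples_rows(self):
        x, y = _tiny_data(n=8, seed=5)
        res = crossvalidate(
            x, y, ModelSpec(), TrainConfig(epochs=1, batch_size=8, seed=0),
            CVScheme(k=2, repetitions=1, seed=0),
            augment_before_split=True, keep_models=True,
        )
        total_test = sum(m["test_mask"].sum() for m in res.models)
        assert total_test == 32  # 4 x 8 plots, each held out once

    def test_accession_unit_requires_mapping(self):
        x, y = _tiny_data(n=8)
        with pytest.raises(ValueError, match="accession"):
            crossvalidate(
                x, y, ModelSpec(), TrainConfig(epochs=1),
                CVScheme(k=2, repetitions=1, unit="accession"),
            )


class TestStackInputs:
    def test_rgb_dsm_channel_order(self):
        rgb = np.full((2, 4, 4, 3), 255, dtype=np.uint8)
        dsm = np.full((2, 4, 4), 2.0, dtype=np.float32)
        x = stack_inputs(rgb, dsm, "rgb_dsm", dsm_scale=2.0)
        assert x.shape == (2, 4, 4, 4)
        np.testing.assert_allclose(x[:, :3], 1.0)
        np.testing.assert_allclose(x[:, 3], 1.0)

    def test_missing_input_raises(self):
        with pytest.raises(ValueError):
            stack_inputs(None, np.zeros((1, 4, 4)), "rgb")


def test_mse_definition():
    est = np.array([[1.0, 2.0], [3.0, 4.0]])
    obs = np.zeros((2, 2))
    assert mse(est, obs) == pytest.approx((1 + 4 + 9 + 16) / 2)
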