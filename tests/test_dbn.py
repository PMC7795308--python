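import numpy as np
import pytest

from dbnscreen import (
    DBNModel,
    RBMParameters,
    TrainConfig,
    fine_tune,
    iterative_feature_learning,
    pretrain,
    reconstruct,
)
from dbnscreen.dbn import _loss_and_gradients, reconstruction_loss

from conftest import planted_single


def toy_cfg(**kw):
    base = dict(learning_rate=0.05, epochs=6, batch_size=32, gibbs_steps=1,
                seed=0, convergence_tolerance=1e-3)
    base.update(kw)
    return TrainConfig(**base)


def toy_data(seed=0, n=100, m=64):
    fp, _, _ = planted_single(seed, n_features=m)
    return fp.values[:n]


class TestPretrain:
    def test_requires_one_hidden_layer(self):
        with pytest.raises(ValueError, match="at least one RBM"):
            pretrain(np.zeros((4, 8)), [8], toy_cfg())

    def test_rejects_width_mismatch(self):
        with pytest.raises(ValueError, match="does not match"):
            pretrain(np.zeros((4, 8)), [6, 3], toy_cfg())

    def test_rejects_empty_data(self):
        with pytest.raises(ValueError, match="empty"):
            pretrain(np.empty((0, 8)), [8, 4], toy_cfg())

    def test_deterministic_under_seed(self):
        X = toy_data()
        m1 = pretrain(X, [64, 16, 8], toy_cfg(seed=5))
        m2 = pretrain(X, [64, 16, 8], toy_cfg(seed=5))
        for a, b in zip(m1.layers, m2.layers):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.a, b.a)
            np.testing.assert_array_equal(a.b, b.b)

    def test_training_reduces_reconstruction_error(self):
        # stochastic: majority over 5 seeds
        wins = 0
        for seed in range(5):
            X = toy_data(seed)
            cfg = toy_cfg(seed=seed, epochs=0)
            init = pretrain(X, [64, 32], cfg)
            err0 = reconstruct(init, X).per_molecule_error.mean()
            trained = pretrain(X, [64, 32], toy_cfg(seed=seed, epochs=10))
            err1 = reconstruct(trained, X).per_molecule_error.mean()
            wins += int(err1 < err0)
        assert wins >= 3


class TestFineTune:
    def test_zero_epochs_changes_only_flag(self):
        X = toy_data()
        model = pretrain(X, [64, 16], toy_cfg(epochs=2))
        W_before = [l.W.copy() for l in model.layers]
        out = fine_tune(model, X, toy_cfg(epochs=0))
        assert out.fine_tuned
        for l, W in zip(out.layers, W_before):
            np.testing.assert_array_equal(l.W, W)

    def test_reduces_reconstruction_loss(self):
        wins = 0
        for seed in range(5):
            X = toy_data(seed)
            model = pretrain(X, [64, 32, 16], toy_cfg(seed=seed, epochs=5))
            before = reconstruction_loss(model, X)
            fine_tune(model, X, toy_cfg(seed=seed, epochs=15))
            after = reconstruction_loss(model, X)
            wins += int(after <= before)
        assert wins >= 3

    def test_gradient_matches_finite_differences(self):
        # 6-4-3 stack unrolled to 6-4-3-4-6; relative error <= 1e-4
        rng = np.random.default_rng(12)
        layers = [
            RBMParameters(rng.normal(scale=0.5, size=(6, 4)),
                          rng.normal(scale=0.3, size=6),
                          rng.normal(scale=0.3, size=4)),
            RBMParameters(rng.normal(scale=0.5, size=(4, 3)),
                          rng.normal(scale=0.3, size=4),
                          rng.normal(scale=0.3, size=3)),
        ]
        model = DBNModel(layers=layers, layer_sizes=[6, 4, 3])
        X = (rng.random((5, 6)) < 0.5).astype(float)
        _, g_enc, g_dec = _loss_and_gradients(model, X)

        h = 1e-6

        def numeric(get, set_):
            ref = get().copy()
            grad = np.zeros_like(ref)
            it = np.nditer(ref, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                pert = ref.copy()
                pert[idx] = ref[idx] + h
                set_(pert)
                up = reconstruction_loss(model, X)
                pert[idx] = ref[idx] - h
                set_(pert)
                down = reconstruction_loss(model, X)
                grad[idx] = (up - down) / (2 * h)
            set_(ref)
            return grad

        for li, layer in enumerate(model.layers):
            for attr, analytic in (("W", g_enc[li][0]), ("b", g_enc[li][1])):
                num = numeric(lambda a=attr, l=layer: getattr(l, a),
                              lambda v, a=attr, l=layer: setattr(l, a, v))
                denom = max(np.abs(num).max(), np.abs(analytic).max(), 1e-8)
                assert np.abs(num - analytic).max() / denom < 1e-4

        for li in range(len(model.decoder)):
            for part, analytic in ((0, g_dec[li][0]), (1, g_dec[li][1])):
                def get(li=li, part=part):
                    return model.decoder[li][part]

                def set_(v, li=li, part=part):
                    pair = list(model.decoder[li])
                    pair[part] = v
                    model.decoder[li] = tuple(pair)

                num = numeric(get, set_)
                denom = max(np.abs(num).max(), np.abs(analytic).max(), 1e-8)
                assert np.abs(num - analytic).max() / denom < 1e-4


class TestReconstruct:
    def test_deterministic_and_error_consistent(self):
        X = toy_data()
        model = pretrain(X, [64, 16], toy_cfg(epochs=3))
        r1 = reconstruct(model, X)
        r2 = reconstruct(model, X)
        np.testing.assert_array_equal(r1.Y, r2.Y)
        assert np.all(r1.E >= 0)
        assert np.all((r1.Y >= 0) & (r1.Y <= 1))
        # e_i^2 == sum_j E_ij^2 for every row
        np.testing.assert_allclose(
            r1.per_molecule_error ** 2, (r1.E ** 2).sum(axis=1), rtol=1e-12)

    def test_l1_norm_switch(self):
        X = toy_data()
        model = pretrain(X, [64, 16], toy_cfg(epochs=2))
        r = reconstruct(model, X, norm="l1")
        np.testing.assert_allclose(r.per_molecule_error, r.E.sum(axis=1))

    def test_perfect_reconstruction_gives_zero_error(self):
        # sharpen one identity-like layer: huge symmetric weights pin each
        # hidden unit to its visible partner and back
        big = 1000.0
        W = big * np.eye(3)
        layer = RBMParameters(W, np.full(3, -big / 2), np.full(3, -big / 2))
        model = DBNModel(layers=[layer], layer_sizes=[3, 3])
        X = np.array([[1.0, 0.0, 1.0]])
        r = reconstruct(model, X)
        np.testing.assert_allclose(r.E, 0.0, atol=1e-9)
        assert r.per_molecule_error[0] == pytest.approx(0.0, abs=1e-9)

    def test_planted_outliers_have_largest_column_errors(self):
        wins = 0
        for seed in range(5):
            fp, signal, outliers = planted_single(seed)
            cfg = toy_cfg(seed=seed, epochs=8)
            model = pretrain(fp, [64, 32, 16], cfg)
            fine_tune(model, fp, cfg.with_(epochs=25))
            col = reconstruct(model, fp).per_feature_error
            wins += int(col[outliers].mean() > col[signal].mean())
        assert wins >= 3


class TestIterativeFeatureLearning:
    def test_zero_fraction_single_round_no_removals(self):
        X = toy_data()
        model, result, removed = iterative_feature_learning(
            X, [64, 16], toy_cfg(epochs=2), 0.0)
        assert removed == []
        assert result.E.shape == X.shape

    def test_infinite_tolerance_stops_after_first_round(self):
        X = toy_data()
        _, _, removed = iterative_feature_learning(
            X, [64, 16], toy_cfg(epochs=2, convergence_tolerance=np.inf),
            0.25)
        assert removed == []

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError, match="outlier_fraction"):
            iterative_feature_learning(np.zeros((4, 8)), [8, 4], toy_cfg(), 0.6)

    def test_recovers_planted_outliers(self):
        wins = 0
        for seed in range(5):
            fp, _, outliers = planted_single(seed + 100)
            cfg = toy_cfg(seed=seed, epochs=8)
            _, _, removed = iterative_feature_learning(
                fp, [64, 32, 16], cfg, outlier_fraction=8 / 64,
                max_rounds=2, fine_tune_cfg=cfg.with_(epochs=25))
            assert len(removed) == 8
            wins += int(len(set(removed) & set(outliers)) >= 6)
        assert wins >= 3

    def test_removed_indices_reported_in_original_coordinates(self):
        fp, _, outliers = planted_single(7)
        cfg = toy_cfg(epochs=8)
        _, result, removed = iterative_feature_learning(
            fp, [64, 32, 16], cfg, outlier_fraction=8 / 64,
            max_rounds=2, fine_tune_cfg=cfg.with_(epochs=25))
        assert all(0 <= i < 64 for i in removed)
        assert len(set(removed)) == len(removed)
        # final reconstruction covers exactly the surviving columns
        assert result.E.shape[1] == 64 - len(removed)
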