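import numpy as np
import pytest

from seasonsdm import (MLP, ChainedSeasonData, SEASONS, TrainConfig,
                       chain_seasons_for, mask_chain_inputs, train_concatenated,
                       train_seasonal_independent, train_static)
from seasonsdm.models import (TrainingError, _chain_forward, load_model_set,
                              mean_bce, save_model_set)


def _separable(n=60, d=3, seed=0):
    """Presences clustered at +1, background at -1 on every feature."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(1, 0.1, (n // 2, d)), rng.normal(-1, 0.1, (n // 2, d))])
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    return X, y


class TestMLP:
    @pytest.mark.parametrize("input_dim", [4, 11, 33, 35])
    def test_parameter_count_formula(self, input_dim):
        model = MLP.init(input_dim, (40, 40), seed=0)
        assert model.n_params == (input_dim + 1) * 40 + 41 * 40 + 41

    def test_zero_weights_predict_half(self):
        model = MLP.init(5, seed=0)
        for p in model.params:
            p[...] = 0.0
        np.testing.assert_array_equal(model.forward(np.random.normal(size=(7, 5))), 0.5)

    def test_outputs_in_open_unit_interval(self):
        model = MLP.init(6, seed=1)
        p = model.forward(np.random.default_rng(0).normal(size=(100, 6)) * 50)
        assert np.all(p > 0) and np.all(p < 1)

    def test_gradients_match_finite_differences(self):
        """Backprop agrees with central finite differences on every parameter."""
        rng = np.random.default_rng(2)
        model = MLP.init(3, (4, 4), seed=3)
        X = rng.normal(size=(12, 3))
        y = rng.integers(0, 2, 12).astype(float)
        _, grads = model.loss_and_grads(X, y)
        eps = 1e-6
        for p, g in zip(model.params, grads):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = mean_bce(model.forward(X), y)
            p[idx] = orig - eps
            lm = mean_bce(model.forward(X), y)
            p[idx] = orig
            assert abs((lp - lm) / (2 * eps) - g[idx]) < 1e-6


class TestTrainStatic:
    def test_separable_data_learned(self):
        X, y = _separable()
        Xv, yv = _separable(seed=1)
        ms = train_static(X, y, Xv, yv, TrainConfig(seed=0, max_epochs=100))
        hist = np.array(ms.history["static"])
        assert np.all(np.diff(hist[:10, 0]) < 0)          # loss decreasing early
        assert np.mean((ms.models["static"].forward(X) >= 0.5) == y) == 1.0

    def test_single_epoch_history(self):
        X, y = _separable()
        ms = train_static(X, y, X, y, TrainConfig(seed=0, max_epochs=1))
        assert len(ms.history["static"]) == 1 and ms.best_epoch["static"] == 1

    def test_identical_seeds_bit_identical(self):
        X, y = _separable()
        a = train_static(X, y, X, y, TrainConfig(seed=5, max_epochs=30))
        b = train_static(X, y, X, y, TrainConfig(seed=5, max_epochs=30))
        for pa, pb in zip(a.models["static"].params, b.models["static"].params):
            np.testing.assert_array_equal(pa, pb)

    def test_single_class_rejected(self):
        X = np.random.normal(size=(10, 2))
        with pytest.raises(TrainingError):
            train_static(X, np.ones(10), X, np.ones(10), TrainConfig(max_epochs=2))

    def test_early_stopping_reports_minimum(self):
        X, y = _separable()
        Xv, yv = _separable(seed=9)
        ms = train_static(X, y, Xv, yv, TrainConfig(seed=0, max_epochs=60))
        val = [v for _, v in ms.history["static"]]
        assert val[ms.best_epoch["static"] - 1] == min(val)


def _seasonal_separable(seed=0, d=6, n=40):
    train, val = {}, {}
    for i, s in enumerate(SEASONS):
        X, y = _separable(n=n, d=d, seed=seed + i)
        Xv, yv = _separable(n=n, d=d, seed=seed + 10 + i)
        train[s], val[s] = (X, y), (Xv, yv)
    return train, val


class TestTrainSeasonalIndependent:
    def test_per_season_accuracy_on_separable_signal(self):
        train, val = _seasonal_separable()
        ms = train_seasonal_independent(train, val, TrainConfig(seed=0, max_epochs=80))
        for s in SEASONS:
            X, y = train[s]
            assert np.mean((ms.models[s].forward(X) >= 0.5) == y) == 1.0

    def test_null_signal_gives_chance_auc(self):
        from seasonsdm import auc_roc
        rng = np.random.default_rng(0)
        train = {s: (rng.normal(size=(200, 4)), rng.integers(0, 2, 200)) for s in SEASONS}
        val = {s: (rng.normal(size=(200, 4)), rng.integers(0, 2, 200)) for s in SEASONS}
        ms = train_seasonal_independent(train, val, TrainConfig(seed=0, max_epochs=40))
        aucs = [auc_roc(ms.models[s].forward(val[s][0]), val[s][1]) for s in SEASONS]
        assert 0.35 < np.mean(aucs) < 0.65

    def test_histories_independent_of_other_seasons(self):
        train, val = _seasonal_separable()
        full = train_seasonal_independent(train, val, TrainConfig(seed=0, max_epochs=20))
        # retrain with a different summer: spring history must not change
        train2 = dict(train)
        train2["summer"] = _separable(n=40, d=6, seed=99)
        alt = train_seasonal_independent(train2, val, TrainConfig(seed=0, max_epochs=20))
        assert full.history["spring"] == alt.history["spring"]

    def test_empty_season_named_in_error(self):
        train, val = _seasonal_separable()
        train = {s: v for s, v in train.items() if s != "fall"}
        with pytest.raises(TrainingError, match="fall"):
            train_seasonal_independent(train, val, TrainConfig(max_epochs=2))


def _chained_toy(seed=0, d=4, n=48):
    """Chained data where each season's own climate block carries the signal."""
    rng = np.random.default_rng(seed)
    y = {s: rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)]) for s in SEASONS}
    Z = {}
    for s in SEASONS:
        Z[s] = {}
        for t in SEASONS:
            base = rng.normal(size=(n, d))
            if t == s:
                base = base + (2 * y[s][:, None] - 1) * 1.5
            Z[s][t] = base
    return ChainedSeasonData(y=y, Z=Z)


class TestTrainConcatenated:
    def test_deterministic_per_seed(self):
        train = _chained_toy(0)
        val = _chained_toy(1)
        a = train_concatenated(train, val, TrainConfig(seed=4, max_epochs=15))
        b = train_concatenated(train, val, TrainConfig(seed=4, max_epochs=15))
        assert a.history["global"] == b.history["global"]
        for s in SEASONS:
            for pa, pb in zip(a.models[s].params, b.models[s].params):
                np.testing.assert_array_equal(pa, pb)

    def test_best_epoch_minimizes_global_validation_loss(self):
        ms = train_concatenated(_chained_toy(0), _chained_toy(1),
                                TrainConfig(seed=0, max_epochs=40))
        val = [v for _, v in ms.history["global"]]
        assert val[ms.best_epoch["global"] - 1] == min(val)

    def test_learns_separable_seasonal_signal(self):
        train = _chained_toy(0)
        ms = train_concatenated(train, _chained_toy(1),
                                TrainConfig(seed=0, max_epochs=120))
        for s in SEASONS:
            p = _chain_forward(ms.models, train.Z[s], chain_seasons_for(s))
            assert np.mean((p >= 0.5) == train.y[s]) > 0.9

    def test_single_class_season_rejected(self):
        bad = _chained_toy(0)
        bad.y["winter"] = np.ones_like(bad.y["winter"])
        with pytest.raises(TrainingError, match="winter"):
            train_concatenated(bad, _chained_toy(1), TrainConfig(max_epochs=2))


class TestChainedPrediction:
    def test_masked_chain_inputs_reduce_to_seasonal_model(self):
        """Zeroing the two chain-input weight rows makes the season model a pure
        function of its climate block, equal to a 3V-input forward pass."""
        rng = np.random.default_rng(0)
        m2 = MLP.init(12 + 2, seed=1)
        masked = mask_chain_inputs(m2)
        m1_equiv = MLP([masked.W1[:-2].copy(), masked.b1, masked.W2, masked.b2,
                        masked.W3, masked.b3])
        Z = rng.normal(size=(20, 12))
        chain_inputs = rng.uniform(0, 1, (20, 2))
        np.testing.assert_allclose(
            masked.forward(np.column_stack([Z, chain_inputs])),
            m1_equiv.forward(Z), atol=1e-14)

    def test_chain_equals_hand_unrolled_four_season_pass(self):
        """The chained prediction for a target season equals an explicitly
        unrolled 4-model forward computation on 3 points."""
        rng = np.random.default_rng(5)
        d = 6
        models = {s: MLP.init(d + 2, seed=i) for i, s in enumerate(SEASONS)}
        Z = {t: rng.normal(size=(3, d)) for t in SEASONS}

        got = _chain_forward(models, Z, chain_seasons_for("winter"))

        # manual unroll: winter chain starts at spring with (0.5, 0)
        p = models["spring"].forward(np.column_stack([Z["spring"], [0.5] * 3, [0] * 3]))
        p = models["summer"].forward(np.column_stack([Z["summer"], p, [1] * 3]))
        p = models["fall"].forward(np.column_stack([Z["fall"], p, [1] * 3]))
        expected = models["winter"].forward(np.column_stack([Z["winter"], p, [1] * 3]))
        np.testing.assert_allclose(got, expected, atol=1e-14)

    @pytest.mark.parametrize("target", SEASONS)
    def test_chain_order_cyclic_and_ends_at_target(self, target):
        chain = chain_seasons_for(target)
        assert len(chain) == 4 and chain[-1] == target
        idx = [SEASONS.index(s) for s in chain]
        assert all((b - a) % 4 == 1 for a, b in zip(idx, idx[1:]))


def test_checkpoint_roundtrip(tmp_path):
    """Saved and reloaded model sets give identical predictions."""
    from seasonsdm import Standardizer

    X, y = _separable()
    ms = train_static(X, y, X, y, TrainConfig(seed=0, max_epochs=10))
    ms.standardizers = {"static": Standardizer.fit(X)}
    ms.thresholds = {"static": 0.4}
    save_model_set(ms, tmp_path / "ckpt")
    again = load_model_set(tmp_path / "ckpt")
    np.testing.assert_array_equal(ms.models["static"].forward(X),
                                  again.models["static"].forward(X))
    assert again.family == "M0" and again.thresholds == {"static": 0.4}
    assert (tmp_path / "ckpt" / "history.csv").exists()
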