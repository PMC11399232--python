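"""Architecture contract, censoring, normalization, training, evaluation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bifurcell.nn import (
    DegenerateSegmentError,
    Ensemble,
    NetworkSpec,
    build_network,
    censor,
    censor_batch,
    count_parameters,
    evaluate,
    normalize_and_pad,
    train,
)
from bifurcell.nn.network import BifurcationNet


class TestParameterCount:
    def test_variant1_total(self):
        assert count_parameters(NetworkSpec.variant1()) == 100_864

    def test_variant2_total(self):
        assert count_parameters(NetworkSpec.variant2()) == 157_364

    def test_dense_layer_term(self):
        # final dense layer alone: (U2 + 1) * 4 = 84
        spec = NetworkSpec.variant1()
        assert (spec.lstm2_units + 1) * spec.n_classes == 84

    @pytest.mark.parametrize("spec", [
        NetworkSpec.variant1(), NetworkSpec.variant2(),
        NetworkSpec.scaled(1), NetworkSpec.scaled(2),
    ], ids=["v1", "v2", "v1-scaled", "v2-scaled"])
    def test_built_network_matches_formula(self, spec):
        assert build_network(spec, seed=0).n_params == count_parameters(spec)


class TestBuildNetwork:
    def test_same_seed_same_weights(self):
        spec = NetworkSpec.scaled(1)
        a, b = build_network(spec, 5), build_network(spec, 5)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_different_seed_differs(self):
        spec = NetworkSpec.scaled(1)
        a, b = build_network(spec, 5), build_network(spec, 6)
        assert any(not np.array_equal(wa, wb)
                   for wa, wb in zip(a.get_weights(), b.get_weights()))

    def test_output_on_simplex(self):
        net = build_network(NetworkSpec.scaled(2), 0)
        x = np.random.default_rng(0).standard_normal((7, 500))
        p = net.predict_proba(x)
        assert p.shape == (7, 4)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_padding_independent_of_batching(self):
        # a padded series predicts the same alone or inside a batch
        net = build_network(NetworkSpec.scaled(1), 0)
        rng = np.random.default_rng(1)
        x = normalize_and_pad(rng.standard_normal(200))
        alone = net.predict_proba(x[None, :])
        batch = np.vstack([x, rng.standard_normal((3, 500))])
        together = net.predict_proba(batch)[0]
        np.testing.assert_allclose(alone[0], together, atol=1e-5)

    def test_gradient_matches_numerical_directional_derivative(self):
        spec = NetworkSpec(variant=1, conv_filters=3, lstm1_units=4,
                           lstm2_units=3, kernel_width=4,
                           dropout_fraction=0.0, input_length=20)
        net = BifurcationNet(spec, seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 20)).astype(np.float32)
        y = rng.integers(0, 4, 5)
        onehot = np.zeros((5, 4), dtype=np.float32)
        onehot[np.arange(5), y] = 1.0

        def loss():
            p = net.forward(x).astype(np.float64)
            return float(-np.mean(np.log(p[np.arange(5), y])))

        net.backward(net.forward(x), onehot)
        params = net.parameters()
        g = np.concatenate([gr.ravel().astype(np.float64) for _, gr in params])
        d = np.random.default_rng(5).standard_normal(g.size)
        d /= np.linalg.norm(d)
        eps = 1e-2
        orig = [p.copy() for p, _ in params]
        for sgn, store in ((+1, "lp"), (-1, "lm")):
            off = 0
            for (p, _), p0 in zip(params, orig):
                p[...] = (p0.ravel() + sgn * eps * d[off:off + p.size]
                          ).reshape(p.shape).astype(np.float32)
                off += p.size
            if sgn > 0:
                lp = loss()
            else:
                lm = loss()
        numeric = (lp - lm) / (2 * eps)
        analytic = float(g @ d)
        assert numeric == pytest.approx(analytic, rel=5e-3, abs=1e-6)


class TestCensoring:
    def test_variant2_full_length_start_zero(self):
        series = np.arange(500.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            seg, start = censor(series, 2, rng)
            assert start == 500 - len(seg)
            assert 50 <= len(seg) <= 500
            np.testing.assert_array_equal(seg, series[start:start + len(seg)])

    def test_variant1_start_within_bounds(self):
        series = np.arange(500.0)
        rng = np.random.default_rng(1)
        starts_seen = set()
        for _ in range(200):
            seg, start = censor(series, 1, rng)
            assert 0 <= start <= 500 - len(seg)
            starts_seen.add(start)
        assert len(starts_seen) > 1  # start actually varies

    def test_batch_segments_have_unit_mean_abs(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 500)) + 2.0
        out = censor_batch(X, 2, np.random.default_rng(3))
        for row in out:
            nz = np.flatnonzero(row != 0.0)
            seg = row[nz[0]:]
            assert np.mean(np.abs(seg)) == pytest.approx(1.0, abs=1e-5)
            assert np.all(row[:nz[0]] == 0.0)
            assert 50 <= len(seg) <= 500


class TestNormalizeAndPad:
    def test_example_values(self):
        out = normalize_and_pad(np.array([2.0, -2.0, 4.0]))
        assert len(out) == 500
        np.testing.assert_allclose(out[-3:], [0.75, -0.75, 1.5])
        assert np.all(out[:-3] == 0.0)

    def test_unit_mean_abs_identity(self):
        seg = np.array([1.0, -1.0, 1.0, -1.0])
        np.testing.assert_allclose(normalize_and_pad(seg)[-4:], seg)

    def test_all_zero_segment_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            normalize_and_pad(np.zeros(100))


class _StubNet:
    def __init__(self, vec):
        self.vec = np.asarray(vec, dtype=float)

    def predict_proba(self, X):
        return np.tile(self.vec, (np.atleast_2d(X).shape[0], 1))


class TestEnsemble:
    def test_identical_members_pass_through(self):
        v = [0.1, 0.2, 0.3, 0.4]
        ens = Ensemble([_StubNet(v), _StubNet(v)])
        np.testing.assert_allclose(ens.predict_proba(np.zeros((2, 500))),
                                   np.tile(v, (2, 1)))

    def test_arithmetic_mean_of_members(self):
        ens = Ensemble([_StubNet([0.6, 0.4, 0, 0]), _StubNet([0.2, 0.8, 0, 0])])
        out = ens.predict_proba(np.zeros((1, 500)))[0]
        np.testing.assert_allclose(out, [0.4, 0.6, 0, 0])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            Ensemble([])

    def test_save_load_roundtrip(self, tmp_path):
        net = build_network(NetworkSpec.scaled(1), 3)
        Ensemble([net]).save(tmp_path / "ens")
        back = Ensemble.load(tmp_path / "ens")
        x = np.random.default_rng(0).standard_normal((2, 500))
        np.testing.assert_allclose(back.predict_proba(x),
                                   net.predict_proba(x), atol=1e-6)


class TestTraining:
    def test_smoke_run_history_and_checkpoint(self, tiny_dataset):
        spec = NetworkSpec(variant=2, conv_filters=4, lstm1_units=4,
                           lstm2_units=4)
        net, hist = train(tiny_dataset, spec, seed=0, epochs_max=2,
                          batch_size=64, patience=5)
        assert len(hist.train_loss) == 2
        assert len(hist.val_loss) == 2
        assert np.all(np.isfinite(hist.train_loss))
        assert hist.best_val_loss <= hist.val_loss[-1] + 1e-9

    def test_training_reduces_loss(self, scaled_nets):
        for variant, (net, hist) in scaled_nets.items():
            assert hist.train_loss[-1] < hist.train_loss[0]
            assert hist.best_val_loss < hist.val_loss[0]


class TestEvaluate:
    def test_perfect_predictor(self):
        y = np.array([0, 1, 2, 3] * 5)

        def predictor(X):
            return np.eye(4)[y]

        res = evaluate(predictor, np.zeros((20, 500)), y)
        assert res.f1_multiclass == pytest.approx(1.0)
        assert res.f1_binary == pytest.approx(1.0)
        np.testing.assert_allclose(res.confusion, np.eye(4))

    def test_constant_predictor_macro_f1(self):
        # always class 0 on a balanced 4-class set: per-class F1 (0.4,0,0,0)
        y = np.array([0, 1, 2, 3] * 10)

        def predictor(X):
            return np.tile([1.0, 0, 0, 0], (len(X), 1))

        res = evaluate(predictor, np.zeros((40, 500)), y)
        assert res.f1_multiclass == pytest.approx(0.1)

    def test_binary_f1_matches_hand_computation(self):
        # truth: 6 bifurcation, 4 null; predictions give TP=4, FP=2, FN=2
        y = np.array([1, 2, 3, 1, 2, 3, 0, 0, 0, 0])
        pred = np.array([1, 2, 3, 0, 0, 3, 1, 2, 0, 0])

        def predictor(X):
            return np.eye(4)[pred]

        res = evaluate(predictor, np.zeros((10, 500)), y)
        precision, recall = 4 / 6, 4 / 6
        assert res.f1_binary == pytest.approx(
            2 * precision * recall / (precision + recall))
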