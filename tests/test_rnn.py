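"""Architecture arithmetic, gradients, training and ensembling."""

import numpy as np
import pytest

import restsal as rs
from restsal import rnn
from restsal._kernels import HAVE_NUMBA
from restsal.rnn import (
    ArchitectureSpec,
    TrainingConfig,
    backward_batch,
    count_parameters,
    ensemble_predict,
    forward_batch,
    init_ensemble,
    input_gradients,
    predict_matrix,
    train_ensemble,
)


class TestParameterAccounting:
    def test_full_scale_counts(self):
        pc = count_parameters(ArchitectureSpec(input_dim=360, hidden_dim=256))
        assert pc.per_direction_lstm_layer1 == 632_320
        assert pc.per_direction_lstm_layer2 == 525_824
        assert pc.affine == 257
        assert pc.total == 2_316_545

    @pytest.mark.parametrize(
        "d,h,layer1,total",
        [(1, 1, 14, 58), (2, 3, 78, None)],
    )
    def test_tiny_formula_cases(self, d, h, layer1, total):
        pc = count_parameters(ArchitectureSpec(input_dim=d, hidden_dim=h))
        assert pc.per_direction_lstm_layer1 == layer1
        if total is not None:
            assert pc.total == total

    def test_total_identity_and_actual_arrays_match(self):
        spec = ArchitectureSpec(input_dim=5, hidden_dim=4)
        pc = count_parameters(spec)
        assert pc.total == 2 * pc.per_direction_lstm_layer1 + \
            2 * pc.per_direction_lstm_layer2 + pc.affine
        params = init_ensemble(spec, [0])
        assert params.n_parameters() == pc.total


class TestForward:
    def test_zero_network_outputs_zero(self, tiny_params, rng):
        p = tiny_params.members(0)
        zeroed = rs.EnsembleParams(
            p.spec, {k: np.zeros_like(v) for k, v in p.arrays.items()}
        )
        X = rng.standard_normal((3, 8, 4))
        assert np.allclose(predict_matrix(zeroed, X), 0.0)

    def test_zero_head_weights_give_bias(self, tiny_params, rng):
        p = tiny_params.members(0)
        arrays = {k: v.copy() for k, v in p.arrays.items()}
        arrays["head_w"][:] = 0.0
        arrays["head_b"][:] = 2.5
        biased = rs.EnsembleParams(p.spec, arrays)
        X = rng.standard_normal((3, 8, 4))
        assert np.allclose(predict_matrix(biased, X), 2.5)

    def test_member_specific_inputs_match_shared(self, tiny_params, rng):
        X = rng.standard_normal((3, 8, 4))
        shared = predict_matrix(tiny_params, X)
        Xm = np.stack([X, X])
        per_member, _ = forward_batch(tiny_params, Xm)
        assert np.allclose(shared, per_member, atol=1e-12)

    def test_dimension_mismatch_raises(self, tiny_params, rng):
        with pytest.raises(ValueError):
            forward_batch(tiny_params, rng.standard_normal((2, 8, 5)))


class TestGradients:
    def test_input_gradient_matches_finite_differences(self, tiny_params, rng):
        X = rng.standard_normal((2, 7, 4))
        g = input_gradients(tiny_params, X)
        eps = 1e-6
        worst = 0.0
        for b in range(2):
            for t in range(7):
                for r in range(4):
                    Xp, Xm = X.copy(), X.copy()
                    Xp[b, t, r] += eps
                    Xm[b, t, r] -= eps
                    fd = (
                        forward_batch(tiny_params, Xp)[0]
                        - forward_batch(tiny_params, Xm)[0]
                    ) / (2 * eps)
                    scale = max(1.0, abs(g[:, b, t, r]).max())
                    worst = max(worst, abs(fd[:, b] - g[:, b, t, r]).max() / scale)
        assert worst < 1e-4

    def test_parameter_gradients_match_finite_differences(self, tiny_params, rng):
        X = rng.standard_normal((2, 7, 4))
        pred, cache = forward_batch(tiny_params, X)
        grads, _ = backward_batch(tiny_params, cache, np.ones_like(pred))
        eps = 1e-6
        for key, arr in tiny_params.arrays.items():
            flat = arr.reshape(arr.shape[0], -1)
            gflat = grads[key].reshape(arr.shape[0], -1)
            for m in range(arr.shape[0]):
                j = int(rng.integers(flat.shape[1]))
                orig = flat[m, j]
                flat[m, j] = orig + eps
                fp = forward_batch(tiny_params, X)[0][m].sum()
                flat[m, j] = orig - eps
                fm = forward_batch(tiny_params, X)[0][m].sum()
                flat[m, j] = orig
                fd = (fp - fm) / (2 * eps)
                assert fd == pytest.approx(gflat[m, j], rel=1e-4, abs=1e-8), key

    @pytest.mark.skipif(not HAVE_NUMBA, reason="numba unavailable")
    def test_compiled_backward_matches_reference(self, tiny_params, rng):
        X = rng.standard_normal((3, 9, 4))
        pred, cache = forward_batch(tiny_params, X)
        dpred = rng.standard_normal(pred.shape)
        a = tiny_params.arrays
        h = tiny_params.spec.hidden_dim
        W2, _, _, _ = rnn._stack_directions(a, 2)
        dH = rng.standard_normal((4, 9, 3, h))
        fast = rnn._lstm_backward(W2, _cache_for(tiny_params, X), dH, h, use_numba=True)
        slow = rnn._lstm_backward(W2, _cache_for(tiny_params, X), dH, h, use_numba=False)
        for x, y in zip(fast, slow):
            assert np.allclose(x, y, atol=1e-10)


def _cache_for(params, X):
    _, cache = forward_batch(params, X)
    return cache["c2"]


class TestTraining:
    def test_same_seed_is_bit_identical(self, rng):
        spec = ArchitectureSpec(input_dim=3, hidden_dim=4)
        X = rng.standard_normal((12, 10, 3))
        y = rng.standard_normal(12)
        cfg = TrainingConfig.desk_scale(seed=5, ensemble_size=2, epochs=3,
                                        max_crop=2, batch_size=4)
        p1, l1 = train_ensemble(spec, X, y, cfg)
        p2, l2 = train_ensemble(spec, X, y, cfg)
        assert np.array_equal(l1, l2)
        for k in p1.arrays:
            assert np.array_equal(p1.arrays[k], p2.arrays[k])

    def test_learns_planted_linear_signal(self):
        gen = np.random.default_rng(3)
        n, t, r = 200, 20, 5
        X = gen.standard_normal((n, t, r))
        y = X[:, :, 0].mean(axis=1)  # target: mean activity of region 0
        spec = ArchitectureSpec(input_dim=r, hidden_dim=8)
        cfg = TrainingConfig.desk_scale(seed=1, ensemble_size=2, epochs=40,
                                        max_crop=2, batch_size=32)
        params, losses = train_ensemble(spec, X, y, cfg)
        yhat = predict_matrix(params, X).mean(axis=0)
        ss = 1 - np.mean((y - yhat) ** 2) / y.var()
        assert ss > 0.9
        # loss trend non-increasing on a 5-epoch moving average
        ma = np.convolve(losses, np.ones(5) / 5, mode="valid")
        assert ma[-1] < ma[0]
        assert np.all(np.diff(ma) < 0.05)

    def test_constant_zero_target_shrinks_predictions(self, rng):
        spec = ArchitectureSpec(input_dim=3, hidden_dim=4)
        X = rng.standard_normal((16, 12, 3))
        cfg = TrainingConfig.desk_scale(seed=2, ensemble_size=1, epochs=25,
                                        max_crop=0, batch_size=8)
        params, _ = train_ensemble(spec, X, np.zeros(16), cfg)
        assert np.abs(predict_matrix(params, X)).mean() < 0.1

    def test_invalid_crop_raises(self, rng):
        spec = ArchitectureSpec(input_dim=3, hidden_dim=4)
        X = rng.standard_normal((8, 10, 3))
        cfg = TrainingConfig.desk_scale(seed=2, ensemble_size=1, epochs=1,
                                        max_crop=5, batch_size=4)
        with pytest.raises(ValueError):
            train_ensemble(spec, X, np.zeros(8), cfg)


class TestEnsemblePrediction:
    def test_single_member_single_session_equals_forward(self, tiny_params, rng):
        x = rng.standard_normal((9, 4))
        one = tiny_params.members(0)
        direct = forward_batch(one, x[None])[0][0, 0]
        assert ensemble_predict(one, [x]) == pytest.approx(float(direct))

    def test_flat_mean_over_members(self, tiny_params, rng):
        """Members forced to constant outputs 1 and 3 average to 2."""
        arrays = {k: np.zeros_like(v) for k, v in tiny_params.arrays.items()}
        arrays["head_b"] = np.array([1.0, 3.0])
        consts = rs.EnsembleParams(tiny_params.spec, arrays)
        x = rng.standard_normal((5, 4))
        assert ensemble_predict(consts, [x, x]) == pytest.approx(2.0)

    def test_ensemble_error_never_exceeds_mean_member_error(self, tiny_params, rng):
        X = rng.standard_normal((20, 8, 4))
        y = rng.standard_normal(20)
        preds = predict_matrix(tiny_params, X)
        ens_err = np.mean((preds.mean(axis=0) - y) ** 2)
        mem_err = np.mean((preds - y[None]) ** 2)
        assert ens_err <= mem_err + 1e-12
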