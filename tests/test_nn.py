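"""Fusion-network components: LSTM recursion, gradients, loss, pooling."""

import numpy as np
import pytest

from histofusion.nn import (FusionConfig, FusionModel, GenomicMLP, LSTMState,
                            PeepholeLSTM, chunk_sequence, desk_config,
                            init_lstm_params, lstm_step, multitask_loss,
                            one_hot, sequence_biomarker, zero_state)
from histofusion.nn.layers import Conv2d, Linear, MaxPool2


def reference_lstm_recursion(X, params):
    """Independently coded scalar-by-scalar recursion (oracle)."""
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    T, D = X.shape
    H = params["b_i"].shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    outs = []
    for t in range(T):
        x = X[t]
        i = sig(x @ params["W_xi"] + h @ params["W_hi"]
                + params["w_ci"] * c + params["b_i"])
        f = sig(x @ params["W_xf"] + h @ params["W_hf"]
                + params["w_cf"] * c + params["b_f"])
        c = f * c + i * np.tanh(x @ params["W_xc"] + h @ params["W_hc"]
                                + params["b_c"])
        o = sig(x @ params["W_xo"] + h @ params["W_ho"]
                + params["w_co"] * c + params["b_o"])
        h = o * np.tanh(c)
        outs.append(h.copy())
    return np.array(outs)


class TestLSTMStep:
    def test_zero_params_give_half_gates_zero_state(self):
        params = {k: np.zeros_like(v) for k, v in
                  init_lstm_params(3, 4, np.random.default_rng(0)).items()}
        st = lstm_step(np.ones(3), zero_state(4), params)
        assert np.allclose(st.i, 0.5) and np.allclose(st.f, 0.5)
        assert np.allclose(st.o, 0.5)
        assert np.allclose(st.c, 0.0) and np.allclose(st.h, 0.0)

    def test_matches_reference_recursion(self, rng):
        for _ in range(10):
            D, H, T = rng.integers(1, 8, size=3)
            params = init_lstm_params(D, H, rng, scale=0.8)
            X = rng.normal(size=(T, D))
            ref = reference_lstm_recursion(X, params)
            st = zero_state(H)
            for t in range(T):
                st = lstm_step(X[t], st, params)
            assert np.allclose(st.h[0], ref[-1], atol=1e-10)

    def test_gate_ranges(self, rng):
        params = init_lstm_params(5, 6, rng, scale=1.0)
        st = lstm_step(rng.normal(size=5), zero_state(6), params)
        for g in (st.i, st.f, st.o):
            assert ((g > 0) & (g < 1)).all()
        assert (np.abs(st.h) < 1).all()

    def test_shape_mismatch_rejected(self, rng):
        params = init_lstm_params(3, 4, rng)
        with pytest.raises(ValueError, match="input dim"):
            lstm_step(np.ones(5), zero_state(4), params)


class TestBackprop:
    """Finite-difference checks of the hand-derived gradients."""

    def _fd(self, f, arr, idx, eps=1e-6):
        orig = arr[idx]
        arr[idx] = orig + eps
        lp = f()
        arr[idx] = orig - eps
        lm = f()
        arr[idx] = orig
        return (lp - lm) / (2 * eps)

    def test_lstm_bptt_matches_finite_differences(self, rng):
        lstm = PeepholeLSTM(4, 5, rng)
        X = rng.normal(size=(3, 6, 4))
        mask = np.ones((3, 6))
        mask[2, 4:] = 0  # include a padded tail
        R = rng.normal(size=(3, 6, 5))

        def loss():
            return float((lstm.forward(X, mask) * R).sum())

        loss()
        dX = lstm.backward(R)
        for name in ("W_xi", "W_hf", "W_xc", "W_ho", "w_ci", "w_cf",
                     "w_co", "b_c"):
            p = lstm.p[name]
            idx = tuple(0 for _ in p.value.shape)
            assert self._fd(loss, p.value, idx) == \
                pytest.approx(p.grad[idx], abs=1e-6)
        assert self._fd(loss, X, (1, 3, 2)) == \
            pytest.approx(dX[1, 3, 2], abs=1e-6)

    def test_conv_and_pool_gradients(self, rng):
        conv = Conv2d(2, 3, 3, rng, stride=1, pad=1)
        pool = MaxPool2()
        x = rng.normal(size=(2, 2, 8, 8))
        R = rng.normal(size=(2, 3, 4, 4))

        def loss():
            return float((pool.forward(conv.forward(x)) * R).sum())

        loss()
        dx = conv.backward(pool.backward(R))
        idx = (1, 0, 1, 2)
        assert self._fd(loss, conv.W.value, idx) == \
            pytest.approx(conv.W.grad[idx], abs=1e-6)
        assert self._fd(loss, x, (0, 1, 3, 3)) == \
            pytest.approx(dx[0, 1, 3, 3], abs=1e-6)

    def test_linear_gradients(self, rng):
        lin = Linear(4, 3, rng)
        x = rng.normal(size=(5, 4))
        R = rng.normal(size=(5, 3))

        def loss():
            return float((lin.forward(x) * R).sum())

        loss()
        lin.backward(R)
        assert self._fd(loss, lin.W.value, (2, 1)) == \
            pytest.approx(lin.W.grad[2, 1], abs=1e-7)


class TestMultitaskLoss:
    def test_perfect_prediction_zero_loss(self):
        t_p = np.array([[1.0, 0.0]])
        t_s = np.array([[0.0, 1.0, 0.0]])
        assert multitask_loss(t_p, t_s, t_p, t_s) == 0.0

    def test_uniform_predictions_closed_form(self):
        pred_p = np.full((1, 2), 0.5)
        pred_s = np.full((1, 3), 1 / 3)
        t_p = np.array([[1.0, 0.0]])
        t_s = np.array([[0.0, 0.0, 1.0]])
        loss = multitask_loss(pred_p, pred_s, t_p, t_s)
        assert loss == pytest.approx(np.log(2) + np.log(3), abs=1e-9)

    def test_batch_additivity(self, rng):
        p1, p2 = rng.dirichlet(np.ones(2), size=2)
        s1, s2 = rng.dirichlet(np.ones(3), size=2)
        tp = one_hot([3, 4], (3, 4))
        ts = one_hot([6, 8], (6, 7, 8))
        joint = multitask_loss(np.vstack([p1, p2]), np.vstack([s1, s2]),
                               tp, ts)
        single = multitask_loss(p1, s1, tp[:1], ts[:1]) + \
            multitask_loss(p2, s2, tp[1:], ts[1:])
        assert joint == pytest.approx(single, rel=1e-12)

    def test_zero_probability_clamped_with_warning(self):
        pred_p = np.array([[0.0, 1.0]])
        t_p = np.array([[1.0, 0.0]])
        t_s = np.array([[1.0]])
        with pytest.warns(UserWarning, match="clamped"):
            loss = multitask_loss(pred_p, np.array([[1.0]]), t_p, t_s)
        assert np.isfinite(loss) and loss > 0

    def test_nonnegative_and_matches_independent_cross_entropies(self, rng):
        pred_p = rng.dirichlet(np.ones(2), size=6)
        pred_s = rng.dirichlet(np.ones(3), size=6)
        t_p = one_hot(rng.choice([3, 4], 6), (3, 4))
        t_s = one_hot(rng.choice([6, 7, 8], 6), (6, 7, 8))
        loss = multitask_loss(pred_p, pred_s, t_p, t_s)
        ce = -np.log(pred_p[t_p.astype(bool)]).sum() \
            - np.log(pred_s[t_s.astype(bool)]).sum()
        assert loss >= 0
        assert loss == pytest.approx(ce)


class TestModelPieces:
    def _cfg(self, **kw):
        return desk_config(patch_px=16, mlp_hidden=(8, 6, 4), lstm_hidden=5,
                           fusion_fc_dim=6, n_signatures=10, **kw)

    def test_mlp_output_dims_and_length_check(self, rng):
        mlp = GenomicMLP(10, (8, 6, 4), rng)
        out = mlp.forward(rng.normal(size=(3, 10)))
        assert out.shape == (3, 4)
        with pytest.raises(ValueError, match="panel size"):
            mlp.forward(rng.normal(size=(3, 7)))

    def test_mlp_zero_weights_zero_output(self, rng):
        mlp = GenomicMLP(5, (4,), rng)
        for p in mlp.params():
            p.value[...] = 0.0
        assert (mlp.forward(np.ones((2, 5))) == 0).all()

    def test_default_mlp_ends_at_256_units(self, rng):
        mlp = GenomicMLP(265, FusionConfig().mlp_hidden, rng)
        assert mlp.out_dim == 256

    def test_fuse_concatenates_then_projects(self, rng):
        model = FusionModel(self._cfg(), rng)
        img = rng.normal(size=(2, model.cnn.feature_dim))
        gen = rng.normal(size=(2, model.mlp.out_dim))
        out = model.fuse(img, gen)
        assert out.shape == (2, 6)
        assert model.fusion_fc.W.value.shape[0] == \
            model.cnn.feature_dim + model.mlp.out_dim
        with pytest.raises(ValueError, match="genomic"):
            model.fuse(img, None)

    def test_image_only_mode_ignores_genomics(self, rng):
        cfg = self._cfg()
        cfg.n_signatures = None
        model = FusionModel(cfg, rng)
        img = rng.normal(size=(1, model.cnn.feature_dim))
        assert model.fuse(img, None).shape == (1, 6)

    def test_cnn_batch_independence_and_determinism(self, rng):
        model = FusionModel(self._cfg(), np.random.default_rng(3))
        imgs = rng.random(size=(8, 3, 16, 16))
        full = model.cnn.features(imgs)
        single = model.cnn.features(imgs[4:5])
        assert np.allclose(full[4], single[0], atol=1e-12)
        model2 = FusionModel(self._cfg(), np.random.default_rng(3))
        assert np.array_equal(full, model2.cnn.features(imgs))

    def test_cnn_wrong_shape_rejected(self, rng):
        model = FusionModel(self._cfg(), rng)
        with pytest.raises(ValueError, match="shape"):
            model.cnn.features(rng.random(size=(2, 3, 8, 8)))


class TestSequenceBiomarker:
    def test_chunking_pads_final_chunk(self, rng):
        feats = rng.normal(size=(10, 4))
        chunks, mask = chunk_sequence(feats, 7)
        assert chunks.shape == (2, 7, 4)
        assert mask.sum() == 10
        assert (chunks[1, 3:] == 0).all()

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chunk_sequence(np.zeros((0, 4)), 7)

    def test_biomarker_is_mean_of_hidden_outputs(self, rng):
        cfg = desk_config(patch_px=16, lstm_hidden=5, fusion_fc_dim=6,
                          n_signatures=None)
        model = FusionModel(cfg, rng)
        feats = rng.normal(size=(7, model.cnn.feature_dim))
        bio = sequence_biomarker(model, feats, None)
        assert bio.shape == (5,)
        # oracle: run the LSTM directly on the fused inputs, average h_t
        u = model.fusion_relu.forward(model.fusion_fc.forward(feats))
        H = model.lstm.forward(u[None, :, :], np.ones((1, 7)))
        assert np.allclose(bio, H[0].mean(axis=0), atol=1e-12)

    def test_chunk_permutation_invariance(self, rng):
        cfg = desk_config(patch_px=16, lstm_hidden=4, fusion_fc_dim=5,
                          unroll_length=3, n_signatures=None)
        model = FusionModel(cfg, rng)
        feats = rng.normal(size=(9, model.cnn.feature_dim))  # 3 full chunks
        bio = sequence_biomarker(model, feats, None)
        perm_feats = np.concatenate([feats[6:9], feats[0:3], feats[3:6]])
        bio_perm = sequence_biomarker(model, perm_feats, None)
        assert np.allclose(bio, bio_perm, atol=1e-12)
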