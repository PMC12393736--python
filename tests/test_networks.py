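import numpy as np
import pytest

from spadama.autograd import Tensor
from spadama.networks import (
    ModelConfig,
    SpaDAMAModel,
    bce,
    classifier_loss,
    discriminator_loss,
    predictor_loss,
)


def small_model(n_genes=12, n_types=3, seed=0, **kw) -> SpaDAMAModel:
    cfg = ModelConfig(latent_dim=8, enc_hidden=16, dec_hidden=(8, 16),
                      clf_hidden=6, pred_hidden=6, seed=seed, **kw)
    return SpaDAMAModel(cfg, [f"g{j}" for j in range(n_genes)],
                        [f"t{k}" for k in range(n_types)])


rng = np.random.default_rng(1)


class TestForwardContracts:
    def test_encode_shape_and_determinism(self):
        m = small_model()
        x = rng.normal(size=(5, 12))
        h1 = m.encode(x, training=False)
        h2 = m.encode(x, training=False)
        assert h1.H.shape == (5, 8)
        np.testing.assert_array_equal(h1.H.data, h2.H.data)

    def test_encode_rejects_wrong_gene_count(self):
        with pytest.raises(ValueError, match="genes"):
            small_model().encode(np.zeros((2, 5)))

    def test_decode_shape_and_width_check(self):
        m = small_model()
        x = rng.normal(size=(4, 12))
        out = m.decode(m.encode(x, training=False), training=False)
        assert out.shape == (4, 12)
        with pytest.raises(ValueError, match="latent"):
            m.decode(np.zeros((2, 5)))

    def test_encode_decode_row_equivariance(self):
        """Identical input rows produce identical reconstruction rows."""
        m = small_model()
        row = rng.normal(size=12)
        x = np.tile(row, (4, 1))
        out = m.decode(m.encode(x, training=False), training=False).data
        for i in range(1, 4):
            np.testing.assert_allclose(out[i], out[0], atol=1e-12)

    def test_latent_split_is_contiguous_and_exact(self):
        m = small_model()
        h = m.encode(rng.normal(size=(3, 12)), training=False)
        np.testing.assert_array_equal(
            np.hstack([h.first_half.data, h.second_half.data]), h.H.data
        )
        assert h.first_half.shape[1] == h.second_half.shape[1] == 4

    def test_odd_latent_split_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(latent_dim=9, latent_split=0.5)

    @pytest.mark.parametrize("head", ["classify", "discriminate"])
    def test_heads_output_open_unit_interval(self, head):
        m = small_model()
        out = getattr(m, head)(rng.normal(size=(20, 4)) * 10).data
        assert ((out > 0) & (out < 1)).all()

    @pytest.mark.parametrize("head", ["classify", "discriminate"])
    def test_zero_weights_give_half(self, head):
        m = small_model()
        for layer in (m.clf0, m.clf1, m.dis0, m.dis1):
            layer.W.data[...] = 0.0
            layer.b.data[...] = 0.0
        out = getattr(m, head)(rng.normal(size=(5, 4))).data
        np.testing.assert_allclose(out, 0.5)

    def test_head_width_mismatch(self):
        with pytest.raises(ValueError):
            small_model().classify(np.zeros((2, 5)))

    def test_predictor_rows_on_simplex(self):
        m = small_model()
        h = rng.normal(size=(10, 8)) * 3
        y = m.predict_proportions(h, training=False).data
        assert (y >= 0).all()
        np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-6)

    def test_predictor_uniform_at_zero_logits(self):
        m = small_model()
        m.pred1.W.data[...] = 0.0
        m.pred1.b.data[...] = 0.0
        y = m.predict_proportions(rng.normal(size=(4, 8)), training=False).data
        np.testing.assert_allclose(y, 1.0 / 3.0)

    def test_softmax_shift_invariance(self):
        m = small_model()
        h = rng.normal(size=(4, 8))
        y1 = m.predict_proportions(h, training=False).data
        m.pred1.b.data += 7.3  # constant shift of every logit
        y2 = m.predict_proportions(h, training=False).data
        np.testing.assert_allclose(y1, y2, atol=1e-12)


class TestGradientChecks:
    def _numeric(self, f, arr, eps=1e-6):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            hi = f()
            arr[i] = orig - eps
            lo = f()
            arr[i] = orig
            g[i] = (hi - lo) / (2 * eps)
        return g

    def test_encoder_weight_gradient(self):
        m = small_model()
        x = rng.normal(size=(3, 12))

        def loss():
            return float((m.encode(x, training=False).H ** 2).sum().data)

        for p in m.all_params():
            p.grad = None
        out = (m.encode(x, training=False).H ** 2).sum()
        out.backward()
        num = self._numeric(loss, m.enc0.W.data)
        np.testing.assert_allclose(m.enc0.W.grad, num, rtol=1e-4, atol=1e-8)

    def test_classifier_weight_gradient(self):
        m = small_model()
        h = rng.normal(size=(4, 4))

        def loss():
            return float(bce(np.ones(4), m.classify(h)).data)

        for p in m.all_params():
            p.grad = None
        bce(np.ones(4), m.classify(Tensor(h))).backward()
        num = self._numeric(loss, m.clf0.W.data)
        np.testing.assert_allclose(m.clf0.W.grad, num, rtol=1e-4, atol=1e-8)

    def test_discriminator_weight_gradient(self):
        m = small_model()
        h = rng.normal(size=(4, 4))

        def loss():
            return float(bce(np.zeros(4), m.discriminate(h)).data)

        for p in m.all_params():
            p.grad = None
        bce(np.zeros(4), m.discriminate(Tensor(h))).backward()
        num = self._numeric(loss, m.dis1.W.data)
        np.testing.assert_allclose(m.dis1.W.grad, num, rtol=1e-4, atol=1e-8)


class TestLosses:
    def test_bce_perfect_prediction_near_zero(self):
        assert bce(np.array([1.0]), np.array([1.0 - 1e-7])) == pytest.approx(0.0, abs=1e-6)

    def test_bce_half_is_ln2(self):
        assert bce(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(np.log(2))

    def test_bce_label_flip_symmetry(self):
        y = np.array([1.0, 0.0, 1.0])
        y_hat = np.array([0.8, 0.3, 0.6])
        assert bce(y, y_hat) == pytest.approx(bce(1 - y, 1 - y_hat))

    def test_bce_matches_brute_force_transcription(self):
        r = np.random.default_rng(2)
        for _ in range(100):
            n = int(r.integers(1, 8))
            y = r.integers(0, 2, size=n).astype(float)
            p = r.uniform(0.01, 0.99, size=n)
            expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
            assert bce(y, p) == pytest.approx(expected, abs=1e-10)

    def test_bce_length_mismatch(self):
        with pytest.raises(ValueError):
            bce(np.ones(2), np.full(3, 0.5))

    def test_adversarial_losses_at_half_are_2ln2(self):
        half = np.full(4, 0.5)
        assert classifier_loss(half, half) == pytest.approx(2 * np.log(2))
        assert discriminator_loss(half, half) == pytest.approx(2 * np.log(2))

    def test_correct_classifier_low_loss_high_discriminator_loss(self):
        real = np.full(5, 1 - 1e-7)
        pseudo = np.full(5, 1e-7)
        assert classifier_loss(real, pseudo) == pytest.approx(0.0, abs=1e-5)
        assert discriminator_loss(real, pseudo) > 10.0

    def test_label_swap_maps_classifier_to_discriminator_loss(self):
        r = np.random.default_rng(3)
        o_r, o_s = r.uniform(0.1, 0.9, 6), r.uniform(0.1, 0.9, 6)
        assert classifier_loss(o_r, o_s) == pytest.approx(discriminator_loss(o_s, o_r))

    def test_predictor_loss_zero_and_max(self):
        y = np.array([[1.0, 0.0]])
        yr = np.array([[0.0, 1.0]])
        assert predictor_loss(y, y) == 0.0
        assert predictor_loss(y, yr) == pytest.approx(2.0)

    def test_predictor_loss_bounded_by_two_on_simplex(self):
        r = np.random.default_rng(4)
        y = r.dirichlet(np.ones(5), size=50)
        yr = r.dirichlet(np.ones(5), size=50)
        assert predictor_loss(y, yr) <= 2.0 + 1e-12

    def test_predictor_loss_matches_brute_force(self):
        r = np.random.default_rng(5)
        for _ in range(100):
            y = r.dirichlet(np.ones(4), size=6)
            yr = r.dirichlet(np.ones(4), size=6)
            expected = np.mean([np.sum((y[i] - yr[i]) ** 2) for i in range(6)])
            assert predictor_loss(y, yr) == pytest.approx(expected, abs=1e-10)

    def test_losses_finite_at_extreme_predictions(self):
        assert np.isfinite(bce(np.array([1.0, 0.0]), np.array([0.0, 1.0])))


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        m = small_model(seed=3)
        x = rng.normal(size=(4, 12))
        y1 = m.predict_proportions(m.encode(x, training=False), training=False).data
        path = tmp_path / "model.ckpt"
        m.save(path)
        m2 = SpaDAMAModel.load(path)
        y2 = m2.predict_proportions(m2.encode(x, training=False), training=False).data
        np.testing.assert_array_equal(y1, y2)
        assert m2.gene_ids == m.gene_ids
        assert m2.type_names == m.type_names

    def test_gene_panel_mismatch_refused(self, tmp_path):
        from spadama import ExpressionMatrix
        from spadama.training import infer

        m = small_model()
        path = tmp_path / "model.ckpt"
        m.save(path)
        m2 = SpaDAMAModel.load(path)
        st = ExpressionMatrix(np.ones((2, 3)), ["a", "b"], ["x1", "x2", "x3"])
        with pytest.raises(ValueError, match="gene panel"):
            infer(st, m2)
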