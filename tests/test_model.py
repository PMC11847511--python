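import numpy as np
import pytest

from deca import ModelConfig, build_patches
from deca.autodiff import Tensor
from deca.model import (
    DecaModel,
    decode_signature,
    embed_patches,
    encoder_forward,
    forward,
    load_model,
    proportion_head,
    reconstruct_bulk,
    save_model,
    self_attention,
)


@pytest.fixture
def x60(rng):
    return rng.uniform(0, 1, size=(2, 60))


class TestEmbedPatches:
    def test_shape_contract(self, tiny_model, small_layout, x60):
        X0 = embed_patches(x60[:1], small_layout, tiny_model)
        assert X0.shape == (1, 1 + small_layout.n_patches, 16)

    def test_same_patch_same_embedding(self, tiny_model, small_layout, x60):
        X0a = embed_patches(x60[:1], small_layout, tiny_model)
        X0b = embed_patches(x60[:1], small_layout, tiny_model)
        np.testing.assert_array_equal(X0a.data, X0b.data)

    def test_distinct_projections_differ_across_patch_index(self, tiny_model, small_layout):
        # identical patch content fed to different theta_j gives different tokens
        x = np.tile(np.linspace(0, 1, 12), 5)[None, :]
        X0 = embed_patches(x, small_layout, tiny_model)
        tokens = X0.data[0, 1:]
        assert not np.allclose(tokens[0], tokens[1])


class TestSelfAttention:
    def test_single_token_output_is_value(self, rng):
        q = Tensor(rng.normal(size=(1, 1, 4)))
        k = Tensor(rng.normal(size=(1, 1, 4)))
        v = Tensor(rng.normal(size=(1, 1, 4)))
        out, att = self_attention(q, k, v)
        np.testing.assert_allclose(att.data, 1.0)
        np.testing.assert_allclose(out.data, v.data)

    def test_attention_rows_are_stochastic(self, rng):
        q = Tensor(rng.normal(size=(2, 5, 8)))
        k = Tensor(rng.normal(size=(2, 5, 8)))
        v = Tensor(rng.normal(size=(2, 5, 8)))
        _, att = self_attention(q, k, v)
        np.testing.assert_allclose(att.data.sum(-1), 1.0, atol=1e-6)

    def test_two_token_closed_form_softmax(self):
        # hand-computed 2-token example with dh=1: scores s_ij = q_i k_j
        q = Tensor(np.array([[[1.0], [2.0]]]))
        k = Tensor(np.array([[[0.5], [-0.5]]]))
        v = Tensor(np.array([[[1.0], [0.0]]]))
        _, att = self_attention(q, k, v)
        s = np.array([[0.5, -0.5], [1.0, -1.0]])  # already scaled: sqrt(1)=1
        expect = np.exp(s) / np.exp(s).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(att.data[0], expect, atol=1e-12)


class TestEncoder:
    def test_L0_is_identity(self, small_layout, x60):
        cfg = ModelConfig(k=3, n_peaks=60, patch_size=12, d=16, L=0, h=2,
                          decoder_dims=[8, 8, 8, 8], seed=1)
        model = DecaModel(cfg, small_layout)
        X0 = embed_patches(x60[:1], small_layout, model)
        XL = encoder_forward(X0, model)
        np.testing.assert_array_equal(XL.data, X0.data)

    def test_zero_weights_residual_passthrough(self, small_layout, x60):
        cfg = ModelConfig(k=3, n_peaks=60, patch_size=12, d=16, L=2, h=2,
                          decoder_dims=[8, 8, 8, 8], seed=1)
        model = DecaModel(cfg, small_layout)
        for grp in model.alpha + model.beta:
            for key in ("Wqkv", "Wo", "bo", "W1", "b1", "W2", "b2"):
                if key in grp:
                    grp[key].data[...] = 0.0
        X0 = embed_patches(x60[:1], small_layout, model)
        XL = encoder_forward(X0, model)
        np.testing.assert_allclose(XL.data, X0.data, atol=1e-12)

    def test_finite_outputs_across_seeds(self, small_layout):
        for seed in range(20):
            cfg = ModelConfig(k=3, n_peaks=60, patch_size=12, d=16, L=2, h=4,
                              decoder_dims=[8, 8, 8, 8], seed=seed)
            model = DecaModel(cfg, small_layout)
            x = np.random.default_rng(seed).uniform(0, 1, (1, 60))
            out = forward(model, x)
            assert np.all(np.isfinite(out["P_hat"].data))

    def test_permutation_equivariance_of_msa(self, tiny_model, rng):
        # permuting non-class tokens permutes MSA outputs identically
        from deca.model import _affine_ln, msa
        X = rng.normal(size=(1, 6, 16))
        perm = np.array([0, 3, 1, 2, 5, 4])
        grp = tiny_model.alpha[0]
        out1, _ = msa(_affine_ln(Tensor(X), grp), grp, tiny_model.config.h)
        out2, _ = msa(_affine_ln(Tensor(X[:, perm]), grp), grp, tiny_model.config.h)
        np.testing.assert_allclose(out1.data[:, perm], out2.data, atol=1e-10)

    def test_attention_row_stochastic_every_layer_head(self, tiny_model, x60):
        out = forward(tiny_model, x60, capture_attention=True)
        for att in out["attentions"]:
            np.testing.assert_allclose(att.sum(-1), 1.0, atol=1e-6)


class TestProportionHead:
    def test_zeroed_head_gives_uniform_simplex(self, tiny_model, small_layout, x60):
        for key in ("W1", "b1", "W2", "b2"):
            tiny_model.omega[key].data[...] = 0.0
        out = forward(tiny_model, x60[:1])
        np.testing.assert_allclose(out["raw"].data, 0.5)
        np.testing.assert_allclose(out["P_hat"].data, 1.0 / 3.0)

    def test_raw_strictly_in_unit_interval(self, tiny_model, x60):
        out = forward(tiny_model, x60)
        assert np.all(out["raw"].data > 0) and np.all(out["raw"].data < 1)

    def test_k1_always_certain(self, small_layout, x60):
        cfg = ModelConfig(k=1, n_peaks=60, patch_size=12, d=16, L=1, h=2,
                          decoder_dims=[4, 4, 4, 4], seed=0)
        model = DecaModel(cfg, small_layout)
        out = forward(model, x60)
        np.testing.assert_allclose(out["P_hat"].data, 1.0)

    def test_rows_sum_to_one(self, tiny_model, x60):
        out = forward(tiny_model, x60)
        np.testing.assert_allclose(out["P_hat"].data.sum(1), 1.0, atol=1e-6)


class TestDecoder:
    def test_signature_nonnegative(self, tiny_model):
        assert decode_signature(tiny_model).data.min() >= 0

    def test_relu_is_identity_on_nonneg_product(self, tiny_model):
        g = tiny_model.gamma
        raw = (g["W1"].data @ g["W2"].data @ g["W3"].data @ g["W4"].data @ g["W5"].data)
        if raw.min() >= 0:
            np.testing.assert_array_equal(decode_signature(tiny_model).data, raw)

    def test_rank_bounded_by_decoder_dims(self, small_layout, rng):
        cfg = ModelConfig(k=3, n_peaks=60, patch_size=12, d=16, L=1, h=2,
                          decoder_dims=[2, 8, 8, 8], seed=5)
        model = DecaModel(cfg, small_layout)
        g = model.gamma
        raw = g["W1"].data @ g["W2"].data @ g["W3"].data @ g["W4"].data @ g["W5"].data
        assert np.linalg.matrix_rank(raw) <= 2


class TestReconstruct:
    def test_one_hot_selects_signature_row(self, rng):
        M = rng.uniform(size=(3, 10))
        P = np.array([[0.0, 1.0, 0.0]])
        np.testing.assert_allclose(reconstruct_bulk(P, M), M[1][None, :])

    def test_convex_mixture(self, rng):
        M = rng.uniform(size=(2, 6))
        out = reconstruct_bulk(np.array([[0.5, 0.5]]), M)
        np.testing.assert_allclose(out, (M[0] + M[1])[None, :] / 2)


class TestDeterminismAndSerialization:
    def test_forward_determinism_across_runs(self, small_layout, x60):
        cfg = ModelConfig(k=3, n_peaks=60, patch_size=12, d=16, L=2, h=2,
                          decoder_dims=[8, 8, 8, 8], seed=21)
        a = forward(DecaModel(cfg, small_layout), x60)["P_hat"].data
        b = forward(DecaModel(cfg, small_layout), x60)["P_hat"].data
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip(self, tiny_model, x60, tmp_path):
        before = forward(tiny_model, x60)["P_hat"].data
        path = tmp_path / "m.deca"
        save_model(tiny_model, path)
        restored = load_model(path)
        after = forward(restored, x60)["P_hat"].data
        np.testing.assert_array_equal(before, after)


class TestGradients:
    def test_finite_difference_gradcheck_full_loss(self, rng):
        """Backprop matches central differences on a tiny model (j=3, d=8, L=1, h=2)."""
        from deca import PeakSet
        recs = [("chr1", i * 1000, i * 1000 + 500) for i in range(30)]
        layout = build_patches(PeakSet.from_records(recs), 10)
        cfg = ModelConfig(k=3, n_peaks=30, patch_size=10, d=8, L=1, h=2,
                          decoder_dims=[6, 6, 6, 6], seed=2)
        model = DecaModel(cfg, layout)
        x = rng.uniform(0, 1, (2, 30))
        P_t = rng.dirichlet(np.ones(3), 2)
        M_t = rng.uniform(0, 1, (3, 30))

        def loss_graph():
            out = forward(model, x)
            return (
                ((out["P_hat"] - Tensor(P_t)).pow(2.0)).mean()
                + ((out["M_hat"] - Tensor(M_t)).pow(2.0)).mean()
                + ((out["B_hat"] - Tensor(x)).pow(2.0)).mean()
            )

        L = loss_graph()
        for p in model.all_params():
            p.grad = None
        L.backward()
        worst = 0.0
        for name, p in model.named_params().items():
            picks = min(4, p.data.size)
            flat_idx = rng.choice(p.data.size, size=picks, replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, p.data.shape)
                eps, orig = 1e-6, p.data[ix]
                p.data[ix] = orig + eps
                lp = float(loss_graph().data)
                p.data[ix] = orig - eps
                lm = float(loss_graph().data)
                p.data[ix] = orig
                fd = (lp - lm) / (2 * eps)
                bp = p.grad[ix]
                denom = max(1e-8, abs(fd) + abs(bp))
                worst = max(worst, abs(fd - bp) / denom)
        assert worst <= 1e-4
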