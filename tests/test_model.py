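"""The network modules: axial attention, adaptive merging, the band-split
feed-forward, assembly and complexity accounting."""

import numpy as np
import pytest

from caprilung.model import (
    ASAPMerging,
    AxialDecomposedAttention,
    FrequencyAwareMLP,
    ModelConfig,
    band_heights,
    build_model,
    count_parameters,
    estimate_flops,
    reduced_config,
    window_partition,
    window_reverse,
)
from caprilung.nn import Tensor
from tests.oracles import ada_reference, standard_mha_reference


class TestAxialAttention:
    @pytest.mark.parametrize("shape,heads", [((1, 4, 5, 8), 2), ((2, 3, 3, 6), 3),
                                             ((1, 6, 2, 4), 1), ((3, 2, 4, 12), 4)])
    def test_matches_nested_loop_reference(self, shape, heads):
        rng = np.random.default_rng(hash((shape, heads)) % 2**31)
        ada = AxialDecomposedAttention(shape[-1], heads, rng)
        for _ in range(5):
            x = rng.standard_normal(shape)
            got = ada(Tensor(x)).data
            want = ada_reference(
                x, ada.qkv.weight.data, ada.qkv.bias.data,
                ada.proj.weight.data, ada.proj.bias.data, heads,
            )
            assert np.allclose(got, want, atol=1e-5)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        ada = AxialDecomposedAttention(8, 2, rng)
        x = Tensor(rng.standard_normal((2, 4, 4, 8)))
        qkv = ada.qkv(x)
        q = qkv[..., :8].reshape(2, 4, 4, 2, 4).transpose(0, 1, 3, 2, 4)
        k = qkv[..., 8:16].reshape(2, 4, 4, 2, 4).transpose(0, 1, 3, 2, 4)
        weights = ((q * ada.scale) @ k.transpose(0, 1, 2, 4, 3)).softmax(-1)
        assert np.allclose(weights.data.sum(-1), 1.0, atol=1e-6)

    def test_single_row_temporal_branch_is_standard_attention(self):
        """With H = 1 the temporal branch degenerates to plain multi-head
        attention over the W positions."""
        rng = np.random.default_rng(1)
        c, heads, w = 8, 2, 6
        ada = AxialDecomposedAttention(c, heads, rng)
        x = rng.standard_normal((1, 1, w, c))
        ref_t = standard_mha_reference(
            x[0, 0], ada.qkv.weight.data, ada.qkv.bias.data, heads
        )
        # frequency branch over a single row is the identity on V
        qkv = x @ ada.qkv.weight.data + ada.qkv.bias.data
        ref_f = qkv[0, 0, :, 2 * c :]
        want = (
            np.concatenate([ref_t, ref_f], axis=-1) @ ada.proj.weight.data
            + ada.proj.bias.data
        )
        assert np.allclose(ada(Tensor(x)).data[0, 0], want, atol=1e-10)

    def test_time_permutation_equivariance(self):
        """Permuting the time columns of a window permutes the output
        identically: no cross-column leakage before fusion."""
        rng = np.random.default_rng(2)
        ada = AxialDecomposedAttention(12, 3, rng)
        x = rng.standard_normal((2, 5, 7, 12))
        perm = rng.permutation(7)
        direct = ada(Tensor(x[:, :, perm, :])).data
        permuted = ada(Tensor(x)).data[:, :, perm, :]
        assert np.allclose(direct, permuted, atol=1e-12)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            AxialDecomposedAttention(10, 3, np.random.default_rng(0))


class TestASAP:
    def test_shape_contract(self):
        rng = np.random.default_rng(3)
        asap = ASAPMerging(8, rng)
        x = Tensor(rng.standard_normal((2, 6 * 4, 8)))
        out = asap(x, (6, 4))
        assert out.shape == (2, 3 * 2, 16)

    def test_saturated_mask_equals_pool_then_expand(self):
        """alpha -> -1e3 saturates the mask at 1, so the module reduces to
        2x2 average pooling followed by the 1x1 channel expansion."""
        rng = np.random.default_rng(4)
        asap = ASAPMerging(6, rng, alpha_init=-1e3)
        x = rng.standard_normal((3, 8 * 8, 6))
        got = asap(Tensor(x), (8, 8)).data
        raw = x.reshape(3, 8, 8, 6)
        pooled = raw.reshape(3, 4, 2, 4, 2, 6).mean(axis=(2, 4))
        want = pooled @ asap.expand.weight.data + asap.expand.bias.data
        assert np.allclose(got, want.reshape(3, 16, 12), atol=1e-5)

    def test_mask_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(5)
        asap = ASAPMerging(4, rng)
        x = Tensor(rng.standard_normal((2, 16, 4)))
        sal = asap.salience(x, (4, 4))
        mask = ((sal - asap.alpha) * asap.slope).sigmoid().data
        assert np.all((mask > 0) & (mask < 1))
        assert np.all((sal.data > 0) & (sal.data < 1))

    def test_gradient_reaches_threshold(self):
        rng = np.random.default_rng(6)
        asap = ASAPMerging(4, rng)
        x = Tensor(rng.standard_normal((1, 16, 4)))
        asap(x, (4, 4)).sum().backward()
        assert asap.alpha.grad is not None
        assert np.isfinite(asap.alpha.grad).all()
        assert abs(float(asap.alpha.grad)) > 0

    def test_odd_dims_rejected(self):
        rng = np.random.default_rng(7)
        asap = ASAPMerging(4, rng)
        with pytest.raises(ValueError):
            asap(Tensor(np.zeros((1, 15, 4))), (5, 3))


class TestFAM:
    @pytest.mark.parametrize("h,expected", [(7, (2, 2, 3)), (14, (4, 4, 6)),
                                            (28, (9, 9, 10)), (56, (18, 18, 20))])
    def test_band_heights(self, h, expected):
        assert band_heights(h) == expected
        assert sum(band_heights(h)) == h

    @pytest.mark.parametrize("h", [7, 14, 28, 56])
    def test_shape_preserved(self, h):
        rng = np.random.default_rng(h)
        fam = FrequencyAwareMLP(8, rng)
        x = rng.standard_normal((2, h * 4, 8))
        assert fam(Tensor(x), (h, 4)).shape == (2, h * 4, 8)

    def test_zero_propagates_with_zero_biases(self):
        rng = np.random.default_rng(8)
        fam = FrequencyAwareMLP(8, rng)
        for p in fam.parameters():
            if p.data.ndim == 1:  # biases
                p.data[:] = 0.0
        out = fam(Tensor(np.zeros((1, 12 * 3, 8))), (12, 3))
        assert np.allclose(out.data, 0.0)

    def test_height_below_three_rejected(self):
        with pytest.raises(ValueError):
            band_heights(2)


class TestAssembly:
    def test_window_partition_roundtrip(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((2, 8, 8, 5))
        w = window_partition(Tensor(x), 4)
        assert w.shape == (2 * 4, 4, 4, 5)
        back = window_reverse(w, 4, 8, 8)
        assert np.array_equal(back.data, x)

    def test_forward_logits_shape(self, small_image_batch):
        x, _ = small_image_batch
        net = build_model(reduced_config(use_ada=True, use_asap=True, use_fam=True), seed=0)
        logits = net.forward(x[:2])
        assert logits.shape == (2, 4)

    def test_eval_forward_deterministic(self, small_image_batch):
        x, _ = small_image_batch
        net = build_model(reduced_config(), seed=3)
        a = net.predict(x)
        b = net.predict(x)
        assert np.array_equal(a, b)
        net2 = build_model(reduced_config(), seed=3)
        assert np.array_equal(net2.predict(x), a)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_side=100)  # not divisible by patch * 8
        with pytest.raises(ValueError):
            ModelConfig(heads=(5, 6, 12, 24))  # 5 does not divide 96
        with pytest.raises(ValueError):
            reduced_config(use_fam=True, input_side=64)  # last stage too short

    def test_state_dict_roundtrip(self, small_image_batch):
        x, _ = small_image_batch
        net = build_model(reduced_config(), seed=0)
        state = net.state_dict()
        net2 = build_model(reduced_config(), seed=99)
        net2.load_state_dict(state)
        assert np.array_equal(net.predict(x), net2.predict(x))

    def test_checkpoint_roundtrip(self, small_image_batch, tmp_path):
        from caprilung.model import load_checkpoint, save_checkpoint

        x, _ = small_image_batch
        net = build_model(reduced_config(use_ada=True), seed=0)
        save_checkpoint(net, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        assert back.cfg == net.cfg
        assert np.array_equal(back.predict(x), net.predict(x))


class TestComplexity:
    def test_ada_parameter_delta_is_exact(self):
        """Enabling axial attention changes each block by C^2 (2C->C instead
        of C->C output projection) minus the dropped (2w-1)^2 * heads bias
        table."""
        cfg = ModelConfig()
        base = build_model(cfg, 0).num_parameters()
        ada = build_model(ModelConfig(use_ada=True), 0).num_parameters()
        expected = 0
        for i, depth in enumerate(cfg.depths):
            c, h, w = cfg.stage_dim(i), cfg.heads[i], cfg.stage_window(i)
            expected += depth * (c * c - (2 * w - 1) ** 2 * h)
        assert ada - base == expected

    def test_asap_parameter_delta_is_exact(self):
        cfg = ModelConfig()
        base = build_model(cfg, 0).num_parameters()
        asap = build_model(ModelConfig(use_asap=True), 0).num_parameters()
        expected = 0
        for i in range(cfg.n_stages - 1):
            c = cfg.stage_dim(i)
            merging = 8 * c * c + 8 * c  # LN(4C) + 4C->2C reduction
            adaptive = (2 * c + 10 * c + c + 1) + (2 * c * c + 2 * c) + 1
            expected += adaptive - merging
        assert asap - base == expected

    def test_flops_near_published_baseline(self):
        net = build_model(ModelConfig(), 0)
        assert estimate_flops(net) == pytest.approx(4.37, rel=0.10)

    def test_flops_monotone_in_depth(self):
        shallow = build_model(ModelConfig(depths=(2, 2, 3, 2)), 0)
        full = build_model(ModelConfig(), 0)
        assert estimate_flops(shallow) < estimate_flops(full)

    def test_ada_increases_flops(self):
        base = build_model(ModelConfig(), 0)
        ada = build_model(ModelConfig(use_ada=True), 0)
        assert estimate_flops(ada) > estimate_flops(base)

    def test_count_parameters_scale(self):
        net = build_model(reduced_config(), 0)
        assert count_parameters(net) == net.num_parameters() / 1e6
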