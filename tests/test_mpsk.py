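"""MPSK local-feature components: branches, pyramid pooling, SK attention,
residual blocks and the 4-stage pyramid."""

import numpy as np
import pytest

import kneemamba as km
from kneemamba.mpsk import (MPSKConfig, MultiScaleBranches, SKSelect,
                            PyramidPool, MPSKBlock, MPSKPyramid)
from kneemamba.nn import Tensor
from kneemamba.types import FeatureMap


def rng_():
    return np.random.default_rng(7)


class TestMultiScaleBranches:
    def test_identity_1x1_kernel_reproduces_input(self):
        mod = MultiScaleBranches(1, rng_(), norm_act=False).eval()
        mod.b1.weight.data[...] = 1.0
        for b in (mod.b1, mod.b3, mod.b5):
            b.bias.data[...] = 0.0
        f = FeatureMap(np.abs(rng_().normal(size=(1, 6, 6))))
        s1, s2, s3 = km.multi_scale_branches(f, mod)
        np.testing.assert_allclose(s1.values, f.values, atol=1e-12)

    def test_zero_input_bias_free_gives_zero_maps(self):
        mod = MultiScaleBranches(2, rng_(), norm_act=False).eval()
        for b in (mod.b1, mod.b3, mod.b5):
            b.bias.data[...] = 0.0
        outs = km.multi_scale_branches(FeatureMap(np.zeros((2, 5, 5))), mod)
        for o in outs:
            np.testing.assert_allclose(o.values, 0.0, atol=1e-12)

    def test_shapes_preserved_and_channel_mismatch_raises(self):
        mod = MultiScaleBranches(3, rng_())
        outs = km.multi_scale_branches(FeatureMap(np.ones((3, 8, 10))), mod)
        assert all(o.values.shape == (3, 8, 10) for o in outs)
        with pytest.raises(ValueError, match="channels"):
            mod(Tensor(np.ones((1, 4, 8, 10))))

    def test_3x3_branch_matches_nested_loop_oracle(self):
        # brute-force zero-padded sliding-window sum on a 1x4x4 input
        r = rng_()
        x = r.normal(size=(1, 4, 4))
        k = r.normal(size=(3, 3))
        mod = MultiScaleBranches(1, rng_(), norm_act=False).eval()
        mod.b3.weight.data[0, 0] = k
        mod.b3.bias.data[...] = 0.0
        out = km.multi_scale_branches(FeatureMap(x), mod)[1].values[0]
        xp = np.pad(x[0], 1)
        expect = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                for di in range(3):
                    for dj in range(3):
                        expect[i, j] += xp[i + di, j + dj] * k[di, dj]
        np.testing.assert_allclose(out, expect, atol=1e-5)


class TestPyramidPool:
    def test_constant_input_stays_spatially_constant(self):
        mod = PyramidPool(4, (1, 2, 3), rng_()).eval()
        f = FeatureMap(np.full((4, 6, 6), 3.25))
        out = km.pyramid_pool(f, mod)
        flat = out.values.reshape(4, -1)
        np.testing.assert_allclose(flat - flat[:, :1], 0.0, atol=1e-6)

    def test_channel_count_restored_regardless_of_levels(self):
        for levels in [(1,), (1, 2), (1, 2, 3, 6)]:
            mod = PyramidPool(8, levels, rng_()).eval()
            out = km.pyramid_pool(FeatureMap(rng_().normal(size=(8, 12, 12))), mod)
            assert out.values.shape == (8, 12, 12)

    def test_oversized_level_raises_in_strict_mode(self):
        mod = PyramidPool(2, (1, 9), rng_())
        with pytest.raises(ValueError, match="level 9"):
            km.pyramid_pool(FeatureMap(np.ones((2, 4, 4))), mod)


class TestSKSelect:
    def test_zero_fc_weights_give_uniform_branch_mean(self):
        mod = SKSelect(3, rng_()).eval()
        for lin in (mod.fc_reduce, mod.fc_expand):
            lin.weight.data[...] = 0.0
            lin.bias.data[...] = 0.0
        r = rng_()
        maps = [FeatureMap(r.normal(size=(3, 4, 4))) for _ in range(3)]
        out, state = km.sk_select(*maps, mod)
        np.testing.assert_allclose(state.attention_weights, 1.0 / 3.0, atol=1e-12)
        mean = (maps[0].values + maps[1].values + maps[2].values) / 3.0
        np.testing.assert_allclose(out.values, mean, atol=1e-10)

    def test_identical_branches_returned_unchanged(self):
        mod = SKSelect(2, rng_()).eval()
        m = FeatureMap(rng_().normal(size=(2, 5, 5)))
        out, _ = km.sk_select(m, FeatureMap(m.values.copy()),
                              FeatureMap(m.values.copy()), mod)
        np.testing.assert_allclose(out.values, m.values, atol=1e-6)

    def test_weights_form_simplex_and_output_is_convex(self):
        r = rng_()
        mod = SKSelect(4, rng_()).eval()
        maps = [FeatureMap(r.normal(size=(4, 6, 6))) for _ in range(3)]
        out, state = km.sk_select(*maps, mod)
        w = state.attention_weights
        np.testing.assert_allclose(w.sum(axis=0), 1.0, atol=1e-6)
        assert np.all(w >= 0) and np.all(w <= 1)
        stack = np.stack([m.values for m in maps])
        assert np.all(out.values >= stack.min(axis=0) - 1e-6)
        assert np.all(out.values <= stack.max(axis=0) + 1e-6)

    def test_stepwise_hand_computation(self):
        # GAP -> FC -> ReLU -> FC -> softmax -> weighted sum, by hand
        r = rng_()
        mod = SKSelect(2, rng_(), reduction=1, min_hidden=2).eval()
        maps = [r.normal(size=(2, 2, 2)) for _ in range(3)]
        out, state = km.sk_select(*[FeatureMap(m) for m in maps], mod)
        fused = maps[0] + maps[1] + maps[2]
        z = fused.mean(axis=(1, 2))
        h = np.maximum(z @ mod.fc_reduce.weight.data + mod.fc_reduce.bias.data, 0)
        logits = (h @ mod.fc_expand.weight.data + mod.fc_expand.bias.data).reshape(3, 2)
        e = np.exp(logits - logits.max(axis=0))
        w = e / e.sum(axis=0)
        expect = sum(w[m][:, None, None] * maps[m] for m in range(3))
        np.testing.assert_allclose(state.channel_descriptor, z, atol=1e-5)
        np.testing.assert_allclose(out.values, expect, atol=1e-5)

    def test_shape_mismatch_raises(self):
        mod = SKSelect(2, rng_())
        with pytest.raises(ValueError, match="shape"):
            mod([Tensor(np.ones((1, 2, 4, 4))), Tensor(np.ones((1, 2, 4, 4))),
                 Tensor(np.ones((1, 2, 5, 5)))])


class TestMPSKBlock:
    def cfg(self):
        return MPSKConfig(stage_channels=(8, 16, 32, 64),
                          blocks_per_stage=(1, 1, 1, 1), pool_levels=(1, 2),
                          branch_width_ratio=1.0, sk_min_hidden=4)

    def test_zero_expand_conv_makes_block_identity(self):
        block = MPSKBlock(8, self.cfg(), 0, rng_()).eval()
        block.expand.conv.weight.data[...] = 0.0
        f = FeatureMap(rng_().normal(size=(8, 8, 8)))
        out = km.mpsk_block(f, block)
        np.testing.assert_allclose(out.values, f.values, atol=1e-6)

    def test_residual_decomposition(self):
        block = MPSKBlock(8, self.cfg(), 0, rng_()).eval()
        f = FeatureMap(rng_().normal(size=(8, 8, 8)))
        out = km.mpsk_block(f, block)
        inner = block.inner(Tensor(f.values[None])).data[0]
        np.testing.assert_allclose(out.values - f.values, inner, atol=1e-6)


class TestMPSKPyramid:
    def test_stage_shapes_and_determinism(self):
        cfg = MPSKConfig(stage_channels=(8, 16, 32, 64),
                         blocks_per_stage=(1, 1, 1, 1), pool_levels=(1, 2),
                         sk_min_hidden=4)
        f = FeatureMap(np.random.default_rng(3).normal(size=(8, 16, 16)), stride=4)
        outs1 = km.mpsk_pyramid(f, MPSKPyramid(cfg, np.random.default_rng(5)).eval())
        outs2 = km.mpsk_pyramid(f, MPSKPyramid(cfg, np.random.default_rng(5)).eval())
        shapes = [o.values.shape for o in outs1]
        assert shapes == [(8, 16, 16), (16, 8, 8), (32, 4, 4), (64, 2, 2)]
        assert [o.stride for o in outs1] == [4, 8, 16, 32]
        for a, b in zip(outs1, outs2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_zero_inner_paths_reduce_to_transition_cascade(self):
        cfg = MPSKConfig(stage_channels=(8, 16, 32, 64),
                         blocks_per_stage=(1, 1, 1, 1), pool_levels=(1, 2),
                         sk_min_hidden=4)
        pyr = MPSKPyramid(cfg, np.random.default_rng(5)).eval()
        for stage in pyr.stages.mods:
            for blk in stage.mods:
                blk.expand.conv.weight.data[...] = 0.0
        f = FeatureMap(np.random.default_rng(3).normal(size=(8, 16, 16)), stride=4)
        outs = km.mpsk_pyramid(f, pyr)
        np.testing.assert_allclose(outs[0].values, f.values, atol=1e-6)
        x = Tensor(f.values[None])
        for s in range(3):
            x = pyr.transitions.mods[s](x)
            np.testing.assert_allclose(outs[s + 1].values, x.data[0], atol=1e-5)

    def test_indivisible_input_raises(self):
        cfg = MPSKConfig(stage_channels=(8, 16, 32, 64),
                         blocks_per_stage=(1, 1, 1, 1), pool_levels=(1,),
                         sk_min_hidden=4)
        pyr = MPSKPyramid(cfg, np.random.default_rng(5))
        with pytest.raises(ValueError, match="divisible"):
            pyr(Tensor(np.ones((1, 8, 12, 12))))
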