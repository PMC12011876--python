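"""Unit and property tests for the adaptive multi-scale MLP block."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amsmlp import autodiff as ad
from amsmlp.am_mlp import (
    AMMLP,
    AMMLPConfig,
    AdaptiveAttention,
    BranchFeedForward,
    MixStage,
    SpatialMixBranch,
    attention_fuse,
    channel_split,
    default_grid_sizes,
    partition,
    spatial_mix,
    unpartition,
)
from amsmlp.autodiff import Tensor

from helpers import check_grads


class TestChannelSplit:
    def test_contiguous_convention(self):
        x = np.zeros((1, 4, 2, 2), dtype=np.float32)
        for c, v in enumerate((10, 20, 30, 40)):
            x[:, c] = v
        a, b = channel_split(Tensor(x))
        assert set(np.unique(a.data)) == {10, 20}
        assert set(np.unique(b.data)) == {30, 40}

    def test_concat_roundtrip(self, rng):
        x = Tensor(rng.random((2, 6, 4, 4)))
        a, b = channel_split(x)
        np.testing.assert_array_equal(ad.concat([a, b], axis=1).data, x.data)

    def test_two_channel_ones(self):
        a, b = channel_split(Tensor(np.ones((1, 2, 3, 3))))
        np.testing.assert_array_equal(a.data, b.data)
        assert a.shape == (1, 1, 3, 3)

    def test_odd_channels_rejected(self):
        with pytest.raises(ValueError, match="3"):
            channel_split(Tensor(np.ones((1, 3, 2, 2))))


class TestBranchFeedForward:
    def test_shape_preserved(self, rng):
        ffn = BranchFeedForward(6, rng)
        x = Tensor(rng.random((2, 6, 5, 7)).astype(np.float32))
        assert ffn(x).shape == (2, 6, 5, 7)

    def test_pointwise_in_space(self, rng):
        """Identical channel vectors at different positions map identically."""
        ffn = BranchFeedForward(4, rng)
        vec = rng.random(4).astype(np.float32)
        x = np.zeros((1, 4, 3, 3), dtype=np.float32)
        x[0, :, 0, 0] = vec
        x[0, :, 2, 1] = vec
        y = ffn(Tensor(x)).data
        np.testing.assert_allclose(y[0, :, 0, 0], y[0, :, 2, 1], atol=1e-6)

    def test_zero_weights_give_zero_output(self, rng):
        ffn = BranchFeedForward(4, rng)
        for lin in (ffn.fc1, ffn.fc2):
            lin.weight.data[...] = 0.0
            lin.bias.data[...] = 0.0
        y = ffn(Tensor(rng.random((1, 4, 2, 2)).astype(np.float32)))
        np.testing.assert_array_equal(y.data, 0.0)


class TestPartition:
    def test_sixteen_by_two(self, rng):
        p = partition(Tensor(rng.random((1, 3, 16, 16))), 2)
        assert p.values.shape == (1, 3, 64, 4)  # 8x8 grid of 2x2 patches

    def test_sixteen_by_eight(self, rng):
        p = partition(Tensor(rng.random((1, 3, 16, 16))), 8)
        assert p.values.shape == (1, 3, 4, 64)  # 2x2 blocking of 8x8 patches

    def test_whole_map_single_patch(self, rng):
        x = Tensor(rng.random((1, 2, 4, 4)))
        p = partition(x, 4)
        assert p.values.shape == (1, 2, 1, 16)
        np.testing.assert_array_equal(unpartition(p).data, x.data)

    def test_row_major_layout(self):
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        p = partition(Tensor(x), 2)
        # patch position 1 is the top-right 2x2 patch, row-major within
        np.testing.assert_array_equal(p.values.data[0, 0, 1], [2, 3, 6, 7])

    def test_non_divisor_rejected(self, rng):
        with pytest.raises(ValueError, match="3.*8x8|8x8.*3"):
            partition(Tensor(np.ones((1, 1, 8, 8))), 3)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.sampled_from([(8, 1), (8, 2), (8, 4), (8, 8),
                            (16, 1), (16, 2), (16, 4), (16, 8), (16, 16)]),
           st.integers(0, 10_000))
    def test_roundtrip_bijection(self, size_p, seed):
        size, p = size_p
        x = np.random.default_rng(seed).random((1, 2, size, size))
        t = Tensor(x)
        np.testing.assert_array_equal(unpartition(partition(t, p)).data, x)

    def test_inverse_pair(self, rng):
        pf = partition(Tensor(rng.random((2, 3, 8, 8))), 4)
        pf2 = partition(unpartition(pf), 4)
        np.testing.assert_array_equal(pf2.values.data, pf.values.data)

    def test_partition_is_differentiable_rearrangement(self, rng):
        w = rng.random((4, 4))
        check_grads(
            lambda x: unpartition(
                spatial_mix(partition(x, 2), "patch_positions", Tensor(w))
            ),
            [rng.random((1, 2, 4, 4))],
        )


class TestSpatialMix:
    def test_identity_weights(self, rng):
        pf = partition(Tensor(rng.random((1, 2, 8, 8))), 4)
        out = spatial_mix(pf, "within_patch", np.eye(16))
        np.testing.assert_allclose(out.values.data, pf.values.data, atol=1e-6)

    def test_uniform_averaging_over_positions(self, rng):
        """All-1/Np weights put the per-offset mean at every position."""
        x = rng.random((1, 2, 8, 8))
        pf = partition(Tensor(x), 2)
        np_ = pf.values.shape[2]
        out = spatial_mix(pf, "patch_positions", np.full((np_, np_), 1.0 / np_))
        expected = np.empty_like(pf.values.data)
        for b in range(1):
            for c in range(2):
                for k in range(4):  # explicit-loop oracle
                    expected[b, c, :, k] = pf.values.data[b, c, :, k].mean()
        np.testing.assert_allclose(out.values.data, expected, atol=1e-6)

    def test_within_patch_mixing_is_block_local(self, rng):
        x = rng.random((1, 1, 8, 8))
        w = rng.random((16, 16))
        xp = x.copy()
        xp[0, 0, 0, 0] += 1.0  # inside block 0 (top-left 4x4)
        out = unpartition(spatial_mix(partition(Tensor(x), 4), "within_patch", w))
        outp = unpartition(spatial_mix(partition(Tensor(xp), 4), "within_patch", w))
        diff = np.abs(out.data - outp.data)[0, 0]
        assert diff[:4, :4].max() > 0
        assert diff[4:, :].max() == 0 and diff[:4, 4:].max() == 0

    def test_weight_side_mismatch_rejected(self, rng):
        pf = partition(Tensor(rng.random((1, 1, 8, 8))), 4)
        with pytest.raises(ValueError, match="does not match"):
            spatial_mix(pf, "within_patch", np.eye(5))


class TestBranches:
    def test_global_branch_shape(self, rng):
        br = SpatialMixBranch(8, 32, [8, 4, 2], "patch_positions", rng)
        x = Tensor(rng.random((1, 8, 32, 32)).astype(np.float32))
        _, out = br(x)
        assert out.shape == (1, 8, 32, 32)

    def test_default_block_pairing(self):
        cfg = AMMLPConfig(channels=8, spatial_size=32)
        assert cfg.grid_sizes == [8, 4, 2]
        assert cfg.block_sizes == [4, 8, 16]
        assert all(g * b == 32 for g, b in zip(cfg.grid_sizes, cfg.block_sizes))

    def test_identity_mixing_collapse(self, rng):
        """Identity mixing weights: each residual stage doubles the signal."""
        br = SpatialMixBranch(2, 8, [2, 2, 2], "patch_positions", rng)
        for st_ in br.stages:
            n = st_.weight.data.shape[0]
            st_.weight.data[...] = np.eye(n)
            st_.bias.data[...] = 0.0
        x = Tensor(rng.random((1, 2, 8, 8)).astype(np.float32))
        fc, out = br(x)
        np.testing.assert_allclose(out.data, 8.0 * fc.data, rtol=1e-5)

    def test_global_mixing_couples_distant_positions(self, rng):
        """Position mixing couples far-apart patches sharing a within-patch
        offset: pixel (31,31) (last patch, offset (7,7)) reaches pixel (7,7)
        (first patch, same offset), 24*sqrt(2) pixels away."""
        stage = MixStage(8, 32, "patch_positions", rng, residual=True)
        stage.weight.data[...] = rng.random(stage.weight.shape).astype(np.float32)
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        xp = x.copy()
        xp[0, 0, 31, 31] += 1.0
        d = np.abs(stage(Tensor(x)).data - stage(Tensor(xp)).data)
        assert d[0, 0, 7, 7] > 0  # distant patch responds
        assert d[0, 0, 0, 0] == 0  # different within-patch offset untouched

    def test_local_mixing_confined_to_block(self, rng):
        stage = MixStage(4, 32, "within_patch", rng, residual=True)
        stage.weight.data[...] = rng.random(stage.weight.shape).astype(np.float32)
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        xp = x.copy()
        xp[0, 0, 1, 2] += 1.0  # inside the (0,0) 4x4 block
        d = np.abs(stage(Tensor(x)).data - stage(Tensor(xp)).data)[0, 0]
        assert d[:4, :4].max() > 0
        d[:4, :4] = 0
        assert d.max() == 0

    def test_grid_rule_matches_reference_setting(self):
        assert default_grid_sizes(32) == [8, 4, 2]
        assert default_grid_sizes(64) == [16, 8, 4]
        assert default_grid_sizes(16) == [4, 2, 2]


class TestAttention:
    def test_alpha_bounds_and_complement(self, rng):
        att = AdaptiveAttention(4, rng)
        att.eval()
        inputs = [rng.standard_normal((2, 4, 8, 8)) for _ in range(98)]
        inputs.append(np.zeros((2, 4, 8, 8)))
        inputs.append(1e4 * np.ones((2, 4, 8, 8)))
        for x in inputs:
            a = att(Tensor(x.astype(np.float32)), Tensor(x.astype(np.float32)))
            assert (a.alpha.data >= 0).all() and (a.alpha.data <= 1).all()
            np.testing.assert_allclose(
                a.alpha.data + a.alpha_complement.data, 1.0, atol=1e-6
            )

    def test_attention_shape_collapses_space(self, rng):
        att = AdaptiveAttention(6, rng)
        a = att(Tensor(rng.random((3, 6, 5, 9))), Tensor(rng.random((3, 6, 5, 9))))
        assert a.alpha.shape == (3, 6, 1, 1)

    def test_shape_mismatch_rejected(self, rng):
        att = AdaptiveAttention(4, rng)
        with pytest.raises(ValueError, match="differ"):
            att(Tensor(np.ones((1, 4, 4, 4))), Tensor(np.ones((1, 4, 8, 8))))


class TestFuse:
    def test_alpha_one_keeps_global_only(self, rng):
        from amsmlp.am_mlp import ChannelAttention

        fg = Tensor(rng.random((1, 4, 8, 8)))
        fl = Tensor(rng.random((1, 4, 8, 8)))
        alpha = Tensor(np.ones((1, 4, 1, 1)))
        out = attention_fuse(fg, fl, ChannelAttention(alpha, 1.0 - alpha))
        np.testing.assert_array_equal(out.data[:, :4], fg.data)
        np.testing.assert_array_equal(out.data[:, 4:], 0.0)

    def test_alpha_half_scales_both(self, rng):
        from amsmlp.am_mlp import ChannelAttention

        fg = Tensor(rng.random((1, 4, 8, 8)))
        fl = Tensor(rng.random((1, 4, 8, 8)))
        alpha = Tensor(np.full((1, 4, 1, 1), 0.5))
        out = attention_fuse(fg, fl, ChannelAttention(alpha, 1.0 - alpha))
        np.testing.assert_allclose(out.data[:, :4], 0.5 * fg.data)
        np.testing.assert_allclose(out.data[:, 4:], 0.5 * fl.data)

    def test_channel_restoration(self, rng):
        from amsmlp.am_mlp import ChannelAttention

        alpha = Tensor(np.full((1, 4, 1, 1), 0.3))
        out = attention_fuse(
            Tensor(rng.random((1, 4, 8, 8))), Tensor(rng.random((1, 4, 8, 8))),
            ChannelAttention(alpha, 1.0 - alpha),
        )
        assert out.shape == (1, 8, 8, 8)


class TestFullBlock:
    def test_shape_contract(self, rng):
        blk = AMMLP(AMMLPConfig(channels=16, spatial_size=32), rng)
        x = Tensor(rng.random((2, 16, 32, 32)).astype(np.float32))
        assert blk(x).shape == (2, 16, 32, 32)

    def test_deterministic_forward(self, rng):
        blk = AMMLP(AMMLPConfig(channels=8, spatial_size=16), rng)
        blk.eval()
        x = Tensor(rng.random((1, 8, 16, 16)).astype(np.float32))
        y1 = blk(x).data
        y2 = blk(x).data
        np.testing.assert_array_equal(y1, y2)

    def test_gradients_reach_every_weight(self, rng):
        """Finite-difference check on a tiny 4x4 instance, all parameters."""
        blk = AMMLP(AMMLPConfig(channels=4, spatial_size=4,
                                grid_sizes=[2, 2, 2]), rng)
        for p in blk.parameters():  # float64 for tight finite differences
            p.data = p.data.astype(np.float64)
        x = np.random.default_rng(7).random((2, 4, 4, 4))

        out = blk(Tensor(x))
        out.sum().backward()
        params = list(blk.parameters())
        assert all(p.grad is not None and np.isfinite(p.grad).all()
                   for p in params)
        assert all(np.abs(p.grad).max() > 0 for p in params)

        from helpers import numeric_grad

        r = np.random.default_rng(3)
        for p in params[:6]:  # spot-check a subset numerically
            saved = [q.data.copy() for q in params]

            def fn(arr, p=p, saved=saved):
                for q, s in zip(params, saved):
                    q.data = s.copy()
                p.data = arr
                return blk(Tensor(x)).data

            num, idxs = numeric_grad(fn, [p.data.copy()], 0, max_entries=5, rng=r)
            for q, s in zip(params, saved):
                q.data = s
            np.testing.assert_allclose(
                p.grad.reshape(-1)[idxs], num, rtol=1e-3, atol=1e-6
            )

    def test_config_mismatch_rejected(self, rng):
        blk = AMMLP(AMMLPConfig(channels=8, spatial_size=16), rng)
        with pytest.raises(ValueError, match="channels"):
            blk(Tensor(np.ones((1, 6, 16, 16))))
        with pytest.raises(ValueError, match="spatial"):
            blk(Tensor(np.ones((1, 8, 8, 8))))

    def test_odd_channel_config_rejected(self):
        with pytest.raises(ValueError, match="even"):
            AMMLPConfig(channels=5, spatial_size=16)
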