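"""Adaptive multi-scale MLP (AM-MLP) skip-connection block.

The block splits a feature map channelwise into a *global* branch (GMS-MLP)
and a *local* branch (LMS-MLP). Each branch applies a channelwise feed-forward
projection, then a cascade of three spatial-mixing MLP stages: the map is cut
into non-overlapping p x p patches, and a dense layer mixes either across
patch *positions* (global branch — couples distant locations that share a
within-patch offset) or across pixels *within* one patch (local branch —
strictly block-local coupling). A squeeze-style channel attention computes a
weight vector alpha in [0,1] per channel; the branches are gated by alpha and
1 - alpha and concatenated back to the original channel count.

Grid sizes g_i and block sizes b_i are complementary: g_i * b_i = S, so as the
global branch's patches shrink the local branch's blocks grow. For spatial
size 32 the defaults are grids [8, 4, 2] and blocks [4, 8, 16].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import (
    BatchNorm,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    Parameter,
    trunc_normal,
)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class PartitionedFeatures:
    """Patch-partitioned view of a feature map.

    ``values`` has axes [batch, channel, patch_positions, within_patch]:
    axis 2 indexes the (H/p) x (W/p) patch grid in row-major order, axis 3 the
    p*p pixels inside one patch, also row-major. Partitioning is a pure
    rearrangement; :func:`unpartition` inverts it exactly.
    """

    values: Tensor
    patch_side: int
    source_extent: tuple  # (H, W)


@dataclass
class ChannelAttention:
    """Complementary per-channel gates: ``alpha_complement = 1 - alpha``."""

    alpha: Tensor        # [B, C/2, 1, 1], entries in [0, 1]
    alpha_complement: Tensor


def default_grid_sizes(spatial_size):
    """Grid triple for a given spatial extent: [S/4, S/8, S/16], min 2.

    Reproduces the reference setting [8, 4, 2] at S = 32.
    """
    return [max(2, spatial_size // d) for d in (4, 8, 16)]


@dataclass
class AMMLPConfig:
    channels: int
    spatial_size: int
    grid_sizes: list = None
    block_sizes: list = None
    hidden_expansion: float = 1.0
    use_stage_residual: bool = True
    attention_applies_to: str = "mlp"  # "mlp" (post-cascade) or "fc" (literal)

    def __post_init__(self):
        if self.channels % 2 != 0:
            raise ValueError(
                f"AM-MLP requires an even channel count, got {self.channels}"
            )
        if self.grid_sizes is None:
            self.grid_sizes = default_grid_sizes(self.spatial_size)
        if self.block_sizes is None:
            self.block_sizes = [self.spatial_size // g for g in self.grid_sizes]
        for p in list(self.grid_sizes) + list(self.block_sizes):
            if self.spatial_size % p:
                raise ValueError(
                    f"patch side {p} does not divide spatial size {self.spatial_size}"
                )
        if self.attention_applies_to not in ("mlp", "fc"):
            raise ValueError(f"attention_applies_to: {self.attention_applies_to!r}")


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def channel_split(x):
    """Split [B, C, H, W] into two contiguous channel halves."""
    c = x.shape[1]
    if c % 2 != 0:
        raise ValueError(f"channel_split requires an even channel count, got {c}")
    return x[:, : c // 2], x[:, c // 2 :]


def partition(x, p):
    """Cut [B, C, H, W] into non-overlapping p x p patches.

    Returns :class:`PartitionedFeatures` with values [B, C, Np, p*p],
    Np = (H/p) * (W/p). Pure index rearrangement, no arithmetic.
    """
    b, c, h, w = x.shape
    if h % p or w % p:
        raise ValueError(f"patch side {p} does not divide spatial extent {h}x{w}")
    v = x.reshape(b, c, h // p, p, w // p, p)
    v = v.transpose((0, 1, 2, 4, 3, 5))
    v = v.reshape(b, c, (h // p) * (w // p), p * p)
    return PartitionedFeatures(v, p, (h, w))


def unpartition(pf):
    """Exact inverse of :func:`partition`."""
    h, w = pf.source_extent
    p = pf.patch_side
    b, c, np_, pp = pf.values.shape
    if np_ != (h // p) * (w // p) or pp != p * p:
        raise ValueError(
            f"inconsistent partition metadata: values {pf.values.shape}, "
            f"p={p}, extent={h}x{w}"
        )
    v = pf.values.reshape(b, c, h // p, w // p, p, p)
    v = v.transpose((0, 1, 2, 4, 3, 5))
    return v.reshape(b, c, h, w)


_AXIS = {"patch_positions": 2, "within_patch": 3}


def spatial_mix(pf, axis, weight, bias=None):
    """Dense mixing along one partition axis; other axes untouched.

    ``axis`` is ``"patch_positions"`` (global mixing) or ``"within_patch"``
    (local mixing). ``weight`` must be square with side equal to that axis.
    """
    ax = _AXIS[axis]
    n = pf.values.shape[ax]
    wd = weight.data if isinstance(weight, Tensor) else np.asarray(weight)
    if wd.shape != (n, n):
        raise ValueError(
            f"mixing weight side {wd.shape} does not match axis length {n}"
        )
    w = weight if isinstance(weight, Tensor) else Tensor(weight)
    b = None
    if bias is not None:
        b = bias if isinstance(bias, Tensor) else Tensor(bias)
    out = ad.linear(pf.values, w, b, axis=ax)
    return PartitionedFeatures(out, pf.patch_side, pf.source_extent)


# ---------------------------------------------------------------------------
# learned blocks
# ---------------------------------------------------------------------------

class BranchFeedForward(Module):
    """Channelwise projection FC -> LN -> FC -> GELU; pointwise in space."""

    def __init__(self, channels, rng, expansion=1.0):
        super().__init__()
        hidden = max(1, int(round(channels * expansion)))
        self.fc1 = Linear(channels, hidden, rng, axis=1)
        self.ln = LayerNorm(hidden, axis=1)
        self.fc2 = Linear(hidden, channels, rng, axis=1)

    def __call__(self, x):
        return self.fc2(self.ln(self.fc1(x))).gelu()


class MixStage(Module):
    """One partition -> dense mix -> unpartition stage of the cascade."""

    def __init__(self, patch_side, spatial_size, axis, rng, residual=True):
        super().__init__()
        self.patch_side = patch_side
        self.axis = axis
        self.residual = residual
        n_pos = (spatial_size // patch_side) ** 2
        n = n_pos if axis == "patch_positions" else patch_side * patch_side
        self.weight = Parameter(trunc_normal(rng, (n, n)))
        self.bias = Parameter(np.zeros(n))

    def __call__(self, x):
        pf = partition(x, self.patch_side)
        mixed = unpartition(spatial_mix(pf, self.axis, self.weight, self.bias))
        return x + mixed if self.residual else mixed


class SpatialMixBranch(Module):
    """Feed-forward + three cascaded mixing stages on one chosen axis."""

    def __init__(self, channels, spatial_size, patch_sides, axis, rng,
                 expansion=1.0, residual=True):
        super().__init__()
        self.ffn = BranchFeedForward(channels, rng, expansion)
        self.stages = ModuleList(
            MixStage(p, spatial_size, axis, rng, residual) for p in patch_sides
        )

    def __call__(self, x):
        h = self.ffn(x)
        fc = h
        for stage in self.stages:
            h = stage(h)
        return fc, h


class AdaptiveAttention(Module):
    """Squeeze-style channel attention over the summed branch outputs.

    Global average pooling compresses space, then FC -> batch norm -> sigmoid
    and a second FC -> sigmoid produce alpha in [0,1] per channel. The
    complement 1 - alpha gates the other branch, so the two gates always sum
    to one (a two-way softmax over (logit, 0)).
    """

    def __init__(self, channels, rng):
        super().__init__()
        # no bias before batch norm: BN would cancel it exactly
        self.fc1 = Linear(channels, channels, rng, bias=False)
        self.bn = BatchNorm(channels, axes=(0,))
        self.fc2 = Linear(channels, channels, rng)

    def __call__(self, f_g, f_l):
        if f_g.shape != f_l.shape:
            raise ValueError(
                f"attention branch shapes differ: {f_g.shape} vs {f_l.shape}"
            )
        pooled = (f_g + f_l).mean(axis=(2, 3))          # GAP -> [B, C/2]
        hidden = self.bn(self.fc1(pooled)).sigmoid()
        alpha = self.fc2(hidden).sigmoid()
        b, c = alpha.shape
        alpha = alpha.reshape(b, c, 1, 1)
        return ChannelAttention(alpha, 1.0 - alpha)


def attention_fuse(f_g, f_l, att):
    """Gate the branches by (alpha, 1-alpha) and concatenate channelwise."""
    if f_g.shape != f_l.shape:
        raise ValueError(f"branch shapes differ: {f_g.shape} vs {f_l.shape}")
    return ad.concat([att.alpha * f_g, att.alpha_complement * f_l], axis=1)


class AMMLP(Module):
    """The full adaptive multi-scale MLP block; preserves [B, C, H, W]."""

    def __init__(self, cfg: AMMLPConfig, rng):
        super().__init__()
        self.cfg = cfg
        half = cfg.channels // 2
        self.global_branch = SpatialMixBranch(
            half, cfg.spatial_size, cfg.grid_sizes, "patch_positions", rng,
            cfg.hidden_expansion, cfg.use_stage_residual,
        )
        self.local_branch = SpatialMixBranch(
            half, cfg.spatial_size, cfg.block_sizes, "within_patch", rng,
            cfg.hidden_expansion, cfg.use_stage_residual,
        )
        self.attention = AdaptiveAttention(half, rng)

    def __call__(self, x):
        b, c, h, w = x.shape
        if c != self.cfg.channels:
            raise ValueError(
                f"input has {c} channels, block configured for {self.cfg.channels}"
            )
        if h != self.cfg.spatial_size or w != self.cfg.spatial_size:
            raise ValueError(
                f"input extent {h}x{w} does not match configured spatial size "
                f"{self.cfg.spatial_size}"
            )
        f_g, f_l = channel_split(x)
        fc_g, mlp_g = self.global_branch(f_g)
        fc_l, mlp_l = self.local_branch(f_l)
        att = self.attention(mlp_g, mlp_l)
        if self.cfg.attention_applies_to == "mlp":
            return attention_fuse(mlp_g, mlp_l, att)
        return attention_fuse(fc_g, fc_l, att)
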