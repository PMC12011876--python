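"""Mask-guided decoder blocks: MCRD and MPAM.

MCRD (multi-scale context relation decoder) sharpens a decoder junction by
splitting the skip feature into a foreground path, gated by a soft mask, and
a background path gated by its complement; each path runs through a 3x3
conv block and the two are concatenated and merged. The mask is predicted
from the deeper feature map (2x bilinear upsample, 1x1 conv to one channel,
sigmoid), except at the deepest junction, which can consume the MPAM mask.

MPAM (multi-path aggregation mask module) fuses all five encoder scales into
a single-channel foreground probability mask: levels 2-5 are reduced to the
level-1 width by 1x1 convolutions, upsampled to level-1 resolution by
repeated 2x bilinear steps, summed with the level-1 features, combined with a
sigmoid-gated copy of the shallowest path, and collapsed to one channel. The
result is average-pooled by 16 so it aligns with the level-5 feature map that
the deepest decoder stage consumes.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, ConvBNReLU, Module, ModuleList


class MCRDMaskHead(Module):
    """Predict a one-channel soft mask from the deeper feature map.

    Default order is conv-then-sigmoid so the mask lands in (0, 1); the
    literal sigmoid-then-conv variant (unbounded output) is kept behind a
    flag for comparison.
    """

    def __init__(self, in_ch, rng, literal_order=False):
        super().__init__()
        self.conv = Conv2d(in_ch, 1, 1, rng)
        self.literal_order = literal_order

    def __call__(self, f_deep):
        up = ad.upsample2x_bilinear(f_deep)
        if self.literal_order:
            return self.conv(up.sigmoid())
        return self.conv(up).sigmoid()


class MCRD(Module):
    """Mask-gated foreground/background refinement of a skip feature."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.fg_conv = ConvBNReLU(in_ch, out_ch, rng)
        self.bg_conv = ConvBNReLU(in_ch, out_ch, rng)
        self.merge = ConvBNReLU(2 * out_ch, out_ch, rng)

    def __call__(self, f_i, mask):
        if f_i.shape[2:] != mask.shape[2:]:
            raise ValueError(
                f"mask extent {mask.shape} does not match features {f_i.shape}"
            )
        fg = self.fg_conv(f_i * mask)
        bg = self.bg_conv(f_i * (1.0 - mask))
        return self.merge(ad.concat([fg, bg], axis=1))


class MPAM(Module):
    """Aggregate the five-level encoder pyramid into a level-5 mask."""

    def __init__(self, base_width, num_levels=5, rng=None):
        super().__init__()
        self.base_width = base_width
        self.num_levels = num_levels
        # 1x1 reductions for levels 2..5 down to the level-1 width
        self.reduce = ModuleList(
            Conv2d(base_width * 2 ** i, base_width, 1, rng)
            for i in range(1, num_levels)
        )
        self.fuse = ConvBNReLU(3 * base_width, base_width, rng)
        self.head = Conv2d(base_width, 1, 1, rng)

    def __call__(self, pyramid):
        if len(pyramid) != self.num_levels:
            raise ValueError(
                f"expected a {self.num_levels}-level pyramid, got {len(pyramid)}"
            )
        f1 = pyramid[0]
        c1 = f1.shape[1]
        if c1 != self.base_width:
            raise ValueError(
                f"level-1 width {c1} does not match configured {self.base_width}"
            )
        aligned = []
        for i, (f, red) in enumerate(zip(pyramid[1:], self.reduce), start=1):
            a = red(f)
            for _ in range(i):  # repeated x2 bilinear steps to level-1 extent
                a = ad.upsample2x_bilinear(a)
            if a.shape != f1.shape:
                raise ValueError(
                    f"pyramid level {i + 1} upsampled to {a.shape}, "
                    f"expected {f1.shape}"
                )
            aligned.append(a)
        f_cat = f1
        for a in aligned:
            f_cat = f_cat + a                       # multi-scale fusion (sum)
        f1_out = ad.concat([aligned[0].sigmoid(), f1], axis=1)  # gate from level 2
        f1_en = ad.concat([f_cat, f1_out], axis=1)  # [B, 3*C1, H, W]
        h = self.fuse(f1_en)
        prob = self.head(h).sigmoid()
        pool = 2 ** (self.num_levels - 1)
        return ad.avgpool(prob, pool)               # level-5 resolution mask
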