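"""Configurable encoder-decoder (U-Net) with optional skip convolutions.

Two consumers:

* kernel pretraining - a 5-level U-Net whose skip paths each pass through a
  single convolution of fixed spatial size (5x5 / 7x7 / 11x11, weights
  shared across positions); those weights are later harvested as the frozen
  multi-scale kernels of the preprocessing filter bank.
* the toy segmenter used to exercise joint training - a 3-level plain
  U-Net emitting core / penumbra / background logits.

Downsampling is a stride-2 convolution; upsampling is nearest-neighbour
followed by a 3x3 convolution. All parameters come from a seeded RNG.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, concat

__all__ = ["UNet"]


class _EncBlock(nn.Module):
    def __init__(self, cin, cout, rng):
        self.conv = nn.Conv2d(cin, cout, 3, stride=1, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.down = nn.Conv2d(cout, cout, 3, stride=2, padding=1, rng=rng)
        self.training = True

    def forward(self, x):
        feat = self.bn(self.conv(x)).relu()
        return feat, self.down(feat).relu()


class _DecBlock(nn.Module):
    def __init__(self, cin, cskip, cout, rng):
        self.conv = nn.Conv2d(cin + cskip, cout, 3, stride=1, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.training = True

    def forward(self, x, skip):
        x = x.upsample_nearest2d(2)
        x = concat([x, skip], axis=1)
        return self.bn(self.conv(x)).relu()


class UNet(nn.Module):
    """Symmetric U-Net.

    ``skip_kernel_sizes`` maps encoder levels (shallowest first) to the
    spatial size of a convolution inserted into that level's skip path;
    levels beyond the list use a plain identity skip.
    """

    def __init__(self, in_ch: int = 3, out_ch: int = 3, depth: int = 3,
                 base_width: int = 8, skip_kernel_sizes: tuple[int, ...] = (),
                 seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be at least 2")
        for ks in skip_kernel_sizes:
            if ks % 2 == 0:
                raise ValueError(f"skip kernel size must be odd, got {ks}")
        if len(skip_kernel_sizes) > depth:
            raise ValueError("more skip kernels than encoder levels")
        rng = np.random.default_rng(seed)
        widths = [base_width * 2 ** i for i in range(depth)]
        self.depth = depth
        self.skip_kernel_sizes = tuple(skip_kernel_sizes)
        self.enc = [_EncBlock(in_ch if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(depth)]
        self.mid = nn.Conv2d(widths[-1], widths[-1], 3, padding=1, rng=rng)
        # one conv per skip path with a prescribed kernel size (shared weights
        # across spatial positions; these become the extractable kernels)
        self.skip_convs = []
        for lvl in range(depth):
            if lvl < len(skip_kernel_sizes):
                ks = skip_kernel_sizes[lvl]
                self.skip_convs.append(
                    nn.Conv2d(widths[lvl], widths[lvl], ks,
                              padding=ks // 2, pad_mode="reflect",
                              bias=False, rng=rng))
            else:
                self.skip_convs.append(None)
        self.dec = [
            _DecBlock(widths[i + 1] if i + 1 < depth else widths[i],
                      widths[i], widths[i], rng)
            for i in reversed(range(depth))
        ]
        self.head = nn.Conv2d(widths[0], out_ch, 1, rng=rng)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        cur = x
        for lvl, block in enumerate(self.enc):
            feat, cur = block(cur)
            if self.skip_convs[lvl] is not None:
                feat = self.skip_convs[lvl](feat)
            skips.append(feat)
        cur = self.mid(cur).relu()
        for i, block in enumerate(self.dec):
            cur = block(cur, skips[self.depth - 1 - i])
        return self.head(cur)
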