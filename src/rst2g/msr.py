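"""Residual-guided multi-scale refinement (MSR).

At each encoder stage the three modality feature maps (pre-contrast,
post-contrast, residual) are transformed by modality-specific 3x3
convolutions, concatenated, fused by a channel-wise MLP (two 1x1
convolutions with a ReLU between, shared across spatial positions), and
recalibrated by a spatial attention map: Fout = Ffused * sigmoid(conv1x1(Ffused)).
Because the gate is a sigmoid, |Fout| <= |Ffused| element-wise.

The structural ablation replaces the whole block with plain channel
concatenation followed by a single 1x1 projection.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .encoder import ConvBlock

__all__ = ["FusionAttention", "MSRBlock", "ConcatFusion", "make_fusion"]


class FusionAttention(nn.Module):
    """Channel-wise MLP fusion of a 3C concat, gated by spatial attention.

    fuse: 1x1 conv (3C -> C), ReLU, 1x1 conv (C -> C); gate: 1x1 conv
    (C -> 1) + sigmoid, broadcast over channels.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.mlp1 = nn.Conv2d(3 * channels, channels, 1, rng)
        self.mlp2 = nn.Conv2d(channels, channels, 1, rng)
        self.attn = nn.Conv2d(channels, 1, 1, rng)

    def fuse(self, cat: nn.Tensor) -> nn.Tensor:
        return self.mlp2(self.mlp1(cat).relu())

    def gate(self, fused: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        a = self.attn(fused).sigmoid()
        return fused * a, a

    def forward(self, f_pre: nn.Tensor, f_post: nn.Tensor, f_res: nn.Tensor
                ) -> nn.Tensor:
        _check_shapes(f_pre, f_post, f_res)
        fused = self.fuse(nn.concatenate([f_pre, f_post, f_res], axis=1))
        out, _ = self.gate(fused)
        return out


def _check_shapes(*maps: nn.Tensor) -> None:
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"modality maps must share shape, got {shapes}")


class MSRBlock(nn.Module):
    """One refinement unit: modality-specific convs + fusion attention.

    The three transform parameter sets are independent — permuting which
    branch is called "pre" versus "res" changes the output.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.fconv_pre = ConvBlock(channels, channels, rng)
        self.fconv_post = ConvBlock(channels, channels, rng)
        self.fconv_res = ConvBlock(channels, channels, rng)
        self.fusion = FusionAttention(channels, rng)

    def forward(self, f_pre: nn.Tensor, f_post: nn.Tensor, f_res: nn.Tensor
                ) -> nn.Tensor:
        _check_shapes(f_pre, f_post, f_res)
        return self.fusion(self.fconv_pre(f_pre),
                           self.fconv_post(f_post),
                           self.fconv_res(f_res))


class ConcatFusion(nn.Module):
    """Ablation stand-in: channel concatenation + 1x1 projection."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(3 * channels, channels, 1, rng)

    def forward(self, f_pre: nn.Tensor, f_post: nn.Tensor, f_res: nn.Tensor
                ) -> nn.Tensor:
        _check_shapes(f_pre, f_post, f_res)
        return self.proj(nn.concatenate([f_pre, f_post, f_res], axis=1))


def make_fusion(channels: int, rng: np.random.Generator,
                msr_enabled: bool) -> nn.Module:
    return MSRBlock(channels, rng) if msr_enabled else ConcatFusion(channels, rng)
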