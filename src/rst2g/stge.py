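"""Spatiotemporal graph enhancement: inter-slice and inter-temporal attention.

Inter-slice attention (ISA) treats each spatial position of a bottleneck
feature map as a node of a fully connected graph and applies one graph
attention layer per modality: attention coefficients

    alpha_ij = softmax_j( LeakyReLU( a^T [W h_i || W h_j] ) )

aggregate node features as h_i_out = sigma( sum_j alpha_ij W h_j ) with an
ELU output nonlinearity. A batch-slice recalibration then exploits the batch
axis as a proxy for adjacent slices: the tensor is reshaped so batch and
height aggregate into one axis, a 1x1 convolution + sigmoid produces
per-position weights in (0,1), and the weights multiply the features before
the layout is restored.

Inter-temporal attention (ITA) fuses the three recalibrated modality maps:
channel-wise concatenation, an MLP down to C channels, and a sigmoid spatial
gate — the same fusion-attention form used by the refinement module.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .encoder import ConvBlock, patchify, unpatchify
from .msr import FusionAttention, _check_shapes

__all__ = [
    "GATParams", "gat_attention", "gat_layer", "GraphAttention",
    "batch_slice_attention", "BatchSliceAttention", "ISAModule", "STGE",
]


class GATParams(nn.Module):
    """Learnable pieces of one graph-attention layer: node transform W
    (C -> C') and attention vector a of length 2*C', split as (a_src, a_dst)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        super().__init__()
        self.negative_slope = negative_slope
        scale = 1.0 / np.sqrt(in_dim)
        self.W = nn.Parameter(
            rng.normal(0.0, scale, size=(in_dim, out_dim)).astype(np.float32))
        self.a_src = nn.Parameter(
            rng.normal(0.0, scale, size=(out_dim,)).astype(np.float32))
        self.a_dst = nn.Parameter(
            rng.normal(0.0, scale, size=(out_dim,)).astype(np.float32))


def gat_attention(nodes: nn.Tensor, p: GATParams) -> nn.Tensor:
    """Dense graph-attention coefficients, shape (B, N, N); rows sum to 1.

    With a = [a_src || a_dst], the pairwise logit a^T [W h_i || W h_j]
    decomposes as (W h_i) . a_src + (W h_j) . a_dst, so the full matrix is an
    outer sum of two length-N vectors — no N^2 x 2C' concatenation needed.
    """
    h = nodes @ p.W                                   # (B, N, C')
    B, N, _ = h.shape
    src = (h * p.a_src).sum(axis=-1)                  # (B, N)
    dst = (h * p.a_dst).sum(axis=-1)                  # (B, N)
    logits = src.reshape(B, N, 1) + dst.reshape(B, 1, N)
    return nn.softmax(logits.leaky_relu(p.negative_slope), axis=-1)


def gat_layer(nodes: nn.Tensor, p: GATParams) -> nn.Tensor:
    """Aggregate: h_i_out = ELU( sum_j alpha_ij W h_j )."""
    alpha = gat_attention(nodes, p)
    h = nodes @ p.W
    return (alpha @ h).elu()


class GraphAttention(nn.Module):
    def __init__(self, dim: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        super().__init__()
        self.params = GATParams(dim, dim, rng, negative_slope)

    def forward(self, nodes: nn.Tensor) -> nn.Tensor:
        return gat_layer(nodes, self.params)


def batch_slice_attention(x: nn.Tensor, conv: nn.Conv2d) -> nn.Tensor:
    """Recalibrate features across the batch-as-slices axis.

    Layout: (B, C, H, W) -> rows of (B*H, C, 1, W) so batch and height
    aggregate into one axis; a 1x1 conv + sigmoid yields weights in (0, 1)
    that multiply the features; the inverse reshape restores (B, C, H, W).
    The sigmoid bounds |out| <= |in| element-wise.
    """
    B, C, H, W = x.shape
    z = x.transpose(0, 2, 1, 3).reshape(B * H, C, 1, W)
    weights = conv(z).sigmoid()
    out = z * weights
    return out.reshape(B, H, C, W).transpose(0, 2, 1, 3)


class BatchSliceAttention(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return batch_slice_attention(x, self.conv)


class ISAModule(nn.Module):
    """Inter-slice attention for ONE modality.

    conv transform -> flatten to graph nodes -> graph attention -> reshape
    back -> batch-slice recalibration. Shape is preserved throughout.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        super().__init__()
        self.fconv = ConvBlock(channels, channels, rng)
        self.gat = GraphAttention(channels, rng, negative_slope)
        self.recal = BatchSliceAttention(channels, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        B, C, H, W = x.shape
        feat = self.fconv(x)
        nodes = patchify(feat)            # (B, N=H*W, C)
        nodes = self.gat(nodes)
        feat = unpatchify(nodes, H, W)
        return self.recal(feat)


class STGE(nn.Module):
    """Full enhancement: per-modality ISA, then inter-temporal fusion (ITA)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        super().__init__()
        self.isa_pre = ISAModule(channels, rng, negative_slope)
        self.isa_post = ISAModule(channels, rng, negative_slope)
        self.isa_res = ISAModule(channels, rng, negative_slope)
        self.ita = FusionAttention(channels, rng)

    def forward(self, f_pre: nn.Tensor, f_post: nn.Tensor, f_res: nn.Tensor
                ) -> nn.Tensor:
        _check_shapes(f_pre, f_post, f_res)
        return self.ita(self.isa_pre(f_pre),
                        self.isa_post(f_post),
                        self.isa_res(f_res))
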