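"""Weight-sharing hybrid convolution/transformer encoder.

One parameter set encodes all three input branches (pre-contrast,
post-contrast, residual): the same anatomy underlies every phase, so sharing
regularises training and forces the branches into a common feature space,
while the residual branch carries the enhancement signal.

The encoder is a stack of DownBlocks — 2x2 max pooling followed by
convolution + batch norm + ReLU with a projected residual shortcut — that
halve resolution and widen channels, topped by a transformer stage at the
bottleneck where the feature map is flattened into a token sequence and
passed through pre-norm multi-head self-attention blocks. Placing attention
only at the bottleneck keeps the token count small enough for dense
attention.

Two ablation switches mirror the model's structural variants:
``use_local=False`` replaces every 3x3 convolution with a 1x1 channel
projection (pooling is kept so the resolution schedule survives), and
``use_global=False`` removes the transformer blocks entirely.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn

__all__ = [
    "EncoderConfig", "ConvBlock", "DownBlock", "MultiHeadSelfAttention",
    "VitBlock", "CFormerEncoder", "patchify", "unpatchify", "mhsa",
]


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters for the encoder.

    ``n_stages`` halvings of resolution with per-stage ``channels``; the stem
    at full resolution uses ``channels[0] // 2``. ``input_hw`` fixes the
    spatial size so the learned positional embedding has a definite length.
    """

    n_stages: int = 4
    channels: tuple[int, ...] = (32, 64, 128, 256)
    n_vit_layers: int = 6
    n_heads: int = 4
    mlp_ratio: int = 4
    use_local: bool = True
    use_global: bool = True
    use_pos_embedding: bool = True
    in_channels: int = 1
    input_hw: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if len(self.channels) != self.n_stages:
            raise ValueError("channels must list one width per stage")
        if self.use_global and self.channels[-1] % self.n_heads != 0:
            raise ValueError("head count must divide the bottleneck width")
        down = 2 ** self.n_stages
        h, w = self.input_hw
        if h % down or w % down:
            raise ValueError(
                f"input {self.input_hw} not divisible by 2^{self.n_stages}; "
                f"pad the input to a multiple of {down}")

    @property
    def stem_channels(self) -> int:
        return max(self.channels[0] // 2, 4)

    @property
    def bottleneck_hw(self) -> tuple[int, int]:
        down = 2 ** self.n_stages
        return self.input_hw[0] // down, self.input_hw[1] // down


class ConvBlock(nn.Module):
    """Convolution -> batch norm -> ReLU. The basic local-feature unit."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel_size: int = 3):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel_size, rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.bn(self.conv(x)).relu()


class DownBlock(nn.Module):
    """Halve resolution, widen channels, with a residual shortcut.

    Main path: two ConvBlock-style 3x3 convolutions (the second without its
    ReLU); shortcut: 1x1 projection + BN of the pooled input. Output is
    ReLU(main + shortcut). In the local-ablation variant the whole block
    collapses to pool -> 1x1 projection -> BN -> ReLU.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 use_local: bool = True):
        super().__init__()
        self.use_local = use_local
        if use_local:
            self.block1 = ConvBlock(in_ch, out_ch, rng, kernel_size=3)
            self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
            self.bn2 = nn.BatchNorm2d(out_ch)
            self.shortcut = nn.Conv2d(in_ch, out_ch, 1, rng)
            self.bn_sc = nn.BatchNorm2d(out_ch)
        else:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng)
            self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if min(x.shape[2], x.shape[3]) < 2:
            raise ValueError("spatial dims must be >= 2 before pooling")
        pooled = nn.max_pool2d(x)
        if not self.use_local:
            return self.bn(self.proj(pooled)).relu()
        main = self.bn2(self.conv2(self.block1(pooled)))
        short = self.bn_sc(self.shortcut(pooled))
        return (main + short).relu()


def patchify(x: nn.Tensor) -> nn.Tensor:
    """(B, C, H, W) -> (B, N, D) token sequence, N = H*W, D = C.

    Token i corresponds to raster position (i // W, i % W).
    """
    B, C, H, W = x.shape
    return x.reshape(B, C, H * W).transpose(0, 2, 1)


def unpatchify(z: nn.Tensor, h: int, w: int) -> nn.Tensor:
    """Inverse of :func:`patchify`; errors if N != h*w."""
    B, N, D = z.shape
    if N != h * w:
        raise ValueError(f"token count {N} does not factor as {h}x{w}")
    return z.transpose(0, 2, 1).reshape(B, D, h, w)


def mhsa(z: nn.Tensor, wq: nn.Tensor, wk: nn.Tensor, wv: nn.Tensor,
         wo: nn.Tensor, n_heads: int,
         return_attention: bool = False):
    """Multi-head scaled dot-product self-attention.

    The (D, D) projections are applied once and split head-wise, which is
    algebraically identical to per-head (D, dk) projections stacked
    column-wise. Per head: softmax(Q K^T / sqrt(dk)) V; heads concatenate
    back to D and pass through the output projection.
    """
    B, N, D = z.shape
    if D % n_heads:
        raise ValueError(f"{n_heads} heads do not divide embedding dim {D}")
    dk = D // n_heads

    def split(t: nn.Tensor) -> nn.Tensor:
        return t.reshape(B, N, n_heads, dk).transpose(0, 2, 1, 3)

    q, k, v = split(z @ wq), split(z @ wk), split(z @ wv)  # (B, H, N, dk)
    scores = (q @ k.transpose(0, 1, 3, 2)) / float(np.sqrt(dk))
    attn = nn.softmax(scores, axis=-1)                     # (B, H, N, N)
    ctx = attn @ v                                         # (B, H, N, dk)
    out = ctx.transpose(0, 2, 1, 3).reshape(B, N, D) @ wo
    if return_attention:
        return out, attn
    return out


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.n_heads = n_heads
        scale = 1.0 / np.sqrt(dim)
        init = lambda: nn.Parameter(
            rng.normal(0.0, scale, size=(dim, dim)).astype(np.float32))
        self.wq, self.wk, self.wv, self.wo = init(), init(), init(), init()

    def forward(self, z: nn.Tensor, return_attention: bool = False):
        return mhsa(z, self.wq, self.wk, self.wv, self.wo, self.n_heads,
                    return_attention=return_attention)


class VitBlock(nn.Module):
    """Pre-norm transformer block: z + MHSA(LN(z)), then + MLP(LN(.))."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: int,
                 rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, dim * mlp_ratio, rng)
        self.fc2 = nn.Linear(dim * mlp_ratio, dim, rng)

    def forward(self, z: nn.Tensor) -> nn.Tensor:
        z = z + self.attn(self.norm1(z))
        return z + self.fc2(nn.gelu(self.fc1(self.norm2(z))))


class CFormerEncoder(nn.Module):
    """The shared encoder: stem, DownBlock pyramid, bottleneck transformer.

    ``forward`` returns (skips, bottleneck): skips[0] is the full-resolution
    stem output, skips[i] the output of DownBlock i for i < n_stages; the
    bottleneck is the deepest stage after the transformer blocks.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        stem_ch = cfg.stem_channels
        if cfg.use_local:
            self.stem = ConvBlock(cfg.in_channels, stem_ch, rng, kernel_size=3)
        else:
            self.stem = ConvBlock(cfg.in_channels, stem_ch, rng, kernel_size=1)
        widths = (stem_ch,) + tuple(cfg.channels)
        self._downs = []
        for i in range(cfg.n_stages):
            down = DownBlock(widths[i], widths[i + 1], rng, use_local=cfg.use_local)
            setattr(self, f"down{i}", down)
            self._downs.append(down)
        if cfg.use_global:
            dim = cfg.channels[-1]
            hb, wb = cfg.bottleneck_hw
            if cfg.use_pos_embedding:
                self.pos_embedding = nn.Parameter(
                    rng.normal(0.0, 0.02, size=(1, hb * wb, dim)).astype(np.float32))
            self._vits = []
            for i in range(cfg.n_vit_layers):
                vit = VitBlock(dim, cfg.n_heads, cfg.mlp_ratio, rng)
                setattr(self, f"vit{i}", vit)
                self._vits.append(vit)

    def forward(self, x: nn.Tensor) -> tuple[list[nn.Tensor], nn.Tensor]:
        cfg = self.cfg
        if (x.shape[2], x.shape[3]) != cfg.input_hw:
            raise ValueError(
                f"encoder built for {cfg.input_hw} inputs, got "
                f"{(x.shape[2], x.shape[3])}; pad to a multiple of "
                f"{2 ** cfg.n_stages} and rebuild")
        feat = self.stem(x)
        skips = [feat]
        for down in self._downs:
            feat = down(feat)
            skips.append(feat)
        bottleneck = skips.pop()  # deepest stage; remaining list feeds skips
        if cfg.use_global:
            hb, wb = cfg.bottleneck_hw
            z = patchify(bottleneck)
            if cfg.use_pos_embedding:
                z = z + self.pos_embedding
            for vit in self._vits:
                z = vit(z)
            bottleneck = unpatchify(z, hb, wb)
        return skips, bottleneck

    def encode_branches(self, pre: nn.Tensor, post: nn.Tensor, res: nn.Tensor
                        ) -> dict[str, tuple[list[nn.Tensor], nn.Tensor]]:
        """Apply the one shared parameter set to all three branches.

        The branches are stacked along the batch axis and encoded in a single
        pass: with weight sharing this is the identical computation for every
        spatial op (convolution, pooling, per-token attention), and it makes
        the batch-norm statistics joint across modalities, so the running
        estimates used in eval mode match what training normalised with.
        """
        if not (pre.shape == post.shape == res.shape):
            raise ValueError("branch tensors must share shape")
        b = pre.shape[0]
        stacked = nn.concatenate([pre, post, res], axis=0)
        skips, bottleneck = self.forward(stacked)
        out: dict[str, tuple[list[nn.Tensor], nn.Tensor]] = {}
        for i, name in enumerate(("pre", "post", "res")):
            sl = slice(i * b, (i + 1) * b)
            out[name] = ([s[sl] for s in skips], bottleneck[sl])
        return out
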