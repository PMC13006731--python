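"""End-to-end segmentation network and Grad-CAM interpretability.

Forward composition: the three input branches (pre, post, residual) pass
through the shared encoder; at every skip stage and at the bottleneck the
modality features are fused by the refinement module; the bottleneck
additionally receives the spatiotemporal graph enhancement (per-modality
inter-slice attention, then inter-temporal fusion), combined residually with
the refined bottleneck. A U-Net-style decoder of bilinear-upsample +
skip-concat + convolution blocks restores full resolution and a final 1x1
convolution emits one logit channel; sigmoid gives the probability map and
thresholding (>= threshold, ties to foreground) the binary mask.

Structural variants toggle one component each: local convolutions, the
transformer blocks, the refinement module (replaced by concat + 1x1
projection), or the graph enhancement (bypassed entirely).
"""

from __future__ import annotations

import dataclasses
import pickle
from pathlib import Path

import numpy as np

from . import nn
from .encoder import CFormerEncoder, ConvBlock, EncoderConfig
from .msr import make_fusion
from .stge import STGE
from .volumes_io import SliceBatch

__all__ = [
    "RST2GConfig", "SegmentationOutput", "CDecoder", "RST2G",
    "build_variant", "VARIANTS", "grad_cam",
    "save_checkpoint", "load_checkpoint",
]

VARIANTS = ("full", "w/o CFE-L", "w/o CFE-G", "w/o MSR", "w/o STGE")


@dataclasses.dataclass(frozen=True)
class RST2GConfig:
    """Architecture + training hyperparameters, including ablation toggles."""

    encoder: EncoderConfig = EncoderConfig()
    msr_enabled: bool = True
    stge_enabled: bool = True
    lam: float = 0.5
    beta: float = 0.2
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("loss weights lambda/beta must lie in [0, 1]")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("mask threshold must lie in (0, 1)")

    @staticmethod
    def tiny(input_hw: tuple[int, int] = (32, 32), **overrides) -> "RST2GConfig":
        """A CPU-friendly configuration for tests and small cohorts."""
        enc = EncoderConfig(n_stages=2, channels=(16, 32), n_vit_layers=1,
                            n_heads=4, input_hw=input_hw)
        return RST2GConfig(encoder=enc, **overrides)

    def variant(self, name: str) -> "RST2GConfig":
        """Return the config for one of the structural ablation variants."""
        if name == "full":
            return self
        if name == "w/o CFE-L":
            enc = dataclasses.replace(self.encoder, use_local=False)
            return dataclasses.replace(self, encoder=enc)
        if name == "w/o CFE-G":
            enc = dataclasses.replace(self.encoder, use_global=False)
            return dataclasses.replace(self, encoder=enc)
        if name == "w/o MSR":
            return dataclasses.replace(self, msr_enabled=False)
        if name == "w/o STGE":
            return dataclasses.replace(self, stge_enabled=False)
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")


@dataclasses.dataclass(frozen=True)
class SegmentationOutput:
    """Per-slice probability map, thresholded mask, and raw logits."""

    probabilities: np.ndarray   # (B,1,H,W) in (0,1)
    mask: np.ndarray            # (B,1,H,W) binary
    logits: np.ndarray          # (B,1,H,W)

    @classmethod
    def from_logits(cls, logits: nn.Tensor, threshold: float) -> "SegmentationOutput":
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        return cls(probabilities=probs,
                   mask=(probs >= threshold).astype(np.float32),
                   logits=logits.data)


class UpBlock(nn.Module):
    """Bilinear 2x upsample, concat the skip, then two conv blocks."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = ConvBlock(in_ch + skip_ch, out_ch, rng)
        self.conv2 = ConvBlock(out_ch, out_ch, rng)

    def forward(self, x: nn.Tensor, skip: nn.Tensor) -> nn.Tensor:
        up = nn.upsample_bilinear2x(x)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"skip shape {skip.shape} incompatible with upsampled {up.shape}")
        return self.conv2(self.conv1(nn.concatenate([up, skip], axis=1)))


class CDecoder(nn.Module):
    """Mirror-image decoder: one UpBlock per encoder stage, 1x1 logit head."""

    def __init__(self, enc_cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        widths = (enc_cfg.stem_channels,) + tuple(enc_cfg.channels)
        self._ups = []
        for i in reversed(range(enc_cfg.n_stages)):
            up = UpBlock(widths[i + 1], widths[i], widths[i], rng)
            setattr(self, f"up{i}", up)
            self._ups.append(up)
        self.head = nn.Conv2d(widths[0], 1, 1, rng)

    def forward(self, bottleneck: nn.Tensor, skips: list[nn.Tensor]) -> nn.Tensor:
        """skips ordered shallow -> deep, as the encoder emits them."""
        x = bottleneck
        for up, skip in zip(self._ups, reversed(skips)):
            x = up(x, skip)
        return self.head(x)


class RST2G(nn.Module):
    """The full residual-guided spatiotemporal graph segmentation model."""

    def __init__(self, cfg: RST2GConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        enc_cfg = cfg.encoder
        self.encoder = CFormerEncoder(enc_cfg, rng)
        widths = (enc_cfg.stem_channels,) + tuple(enc_cfg.channels)
        self._fusions = []
        for i in range(enc_cfg.n_stages):      # skip stages 0..n-1
            fusion = make_fusion(widths[i], rng, cfg.msr_enabled)
            setattr(self, f"fusion{i}", fusion)
            self._fusions.append(fusion)
        self.fusion_bottleneck = make_fusion(widths[-1], rng, cfg.msr_enabled)
        if cfg.stge_enabled:
            self.stge = STGE(widths[-1], rng)
        self.decoder = CDecoder(enc_cfg, rng)

    # -- forward ------------------------------------------------------------

    def forward_logits(self, pre: nn.Tensor, post: nn.Tensor, res: nn.Tensor,
                       capture: dict | None = None) -> nn.Tensor:
        pyramids = self.encoder.encode_branches(pre, post, res)
        skips_pre, bott_pre = pyramids["pre"]
        skips_post, bott_post = pyramids["post"]
        skips_res, bott_res = pyramids["res"]
        if capture is not None:
            capture["bottleneck_res"] = bott_res
            capture["bottleneck_pre"] = bott_pre
            capture["bottleneck_post"] = bott_post
            for i, s in enumerate(skips_res):
                capture[f"skip{i}_res"] = s

        skips = [fusion(sp, so, sr) for fusion, sp, so, sr in
                 zip(self._fusions, skips_pre, skips_post, skips_res)]
        refined = self.fusion_bottleneck(bott_pre, bott_post, bott_res)
        if self.cfg.stge_enabled:
            bottleneck = refined + self.stge(bott_pre, bott_post, bott_res)
        else:
            bottleneck = refined
        if capture is not None:
            capture["bottleneck_fused"] = bottleneck
        return self.decoder(bottleneck, skips)

    def forward(self, batch: SliceBatch | tuple, capture: dict | None = None
                ) -> SegmentationOutput:
        if isinstance(batch, SliceBatch):
            pre, post, res = batch.pre, batch.post, batch.res
        else:
            pre, post, res = batch
        logits = self.forward_logits(nn.Tensor(pre), nn.Tensor(post),
                                     nn.Tensor(res), capture=capture)
        return SegmentationOutput.from_logits(logits, self.cfg.threshold)

    def training_logits(self, batch: SliceBatch) -> nn.Tensor:
        return self.forward_logits(nn.Tensor(batch.pre), nn.Tensor(batch.post),
                                   nn.Tensor(batch.res))


def build_variant(cfg: RST2GConfig, name: str = "full") -> RST2G:
    """Instantiate one of the documented structural variants."""
    return RST2G(cfg.variant(name))


# ---------------------------------------------------------------------------
# Grad-CAM

_TARGETS = ("bottleneck_res", "bottleneck_pre", "bottleneck_post",
            "bottleneck_fused")


def grad_cam(model: RST2G, batch: SliceBatch,
             target_layer: str = "bottleneck_res") -> np.ndarray:
    """Gradient-weighted class activation map, (B,1,H,W) in [0, 1].

    The scalar target is the sum of logits inside the predicted mask (or of
    all logits when the mask is empty). Channel weights are the spatially
    averaged gradients at the target activation; the weighted activation sum
    is ReLU-rectified, bilinearly upsampled to input size, and min-max
    normalised per batch item (all-zero maps stay zero).
    """
    valid = _TARGETS + tuple(
        f"skip{i}_res" for i in range(model.cfg.encoder.n_stages))
    if target_layer not in valid:
        raise ValueError(f"unknown target layer {target_layer!r}; "
                         f"choose from {sorted(valid)}")
    model.eval()
    capture: dict[str, nn.Tensor] = {}
    logits = model.forward_logits(nn.Tensor(batch.pre), nn.Tensor(batch.post),
                                  nn.Tensor(batch.res), capture=capture)
    probs = 1.0 / (1.0 + np.exp(-logits.data))
    mask = (probs >= model.cfg.threshold).astype(np.float32)
    if mask.sum() == 0:
        mask = np.ones_like(mask)
    target = (logits * nn.Tensor(mask)).sum()
    model.zero_grad()
    target.backward()

    act = capture[target_layer]
    if act.grad is None:
        return np.zeros((batch.pre.shape[0], 1, *batch.pre.shape[2:]),
                        dtype=np.float32)
    weights = act.grad.mean(axis=(2, 3), keepdims=True)       # (B,C,1,1)
    cam = np.maximum((weights * act.data).sum(axis=1, keepdims=True), 0.0)

    t = nn.Tensor(cam.astype(np.float32))
    while t.shape[2:] != batch.pre.shape[2:]:
        with nn.no_grad():
            t = nn.upsample_bilinear2x(t)
        if t.shape[2] > batch.pre.shape[2]:
            raise ValueError("target layer resolution does not divide input size")
    cam = t.data
    flat = cam.reshape(cam.shape[0], -1)
    lo = flat.min(axis=1, keepdims=True)
    hi = flat.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    cam = ((flat - lo) / span).reshape(cam.shape)
    return cam.astype(np.float32)


# ---------------------------------------------------------------------------
# Checkpoints: single file holding weights + config snapshot


def save_checkpoint(model: RST2G, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config": dataclasses.asdict(model.cfg),
               "state": model.state_dict()}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)
    return path


def load_checkpoint(path: str | Path) -> RST2G:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg_dict = dict(payload["config"])
    enc = EncoderConfig(**{**cfg_dict.pop("encoder")})
    enc = dataclasses.replace(enc, channels=tuple(enc.channels),
                              input_hw=tuple(enc.input_hw))
    cfg = RST2GConfig(encoder=enc, **cfg_dict)
    model = RST2G(cfg)
    model.load_state_dict(payload["state"])
    return model
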