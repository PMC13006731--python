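"""Training objective and evaluation metrics.

The hybrid loss is

    L = L_Dice + lambda * L_BCE + beta * L_Boundary

with soft Dice over the probability map, clamped binary cross-entropy, and a
boundary term comparing Sobel gradients of prediction and target under an L1
penalty summed over both directions (the horizontal and vertical 3x3 kernels
are applied with replicate padding so shape is preserved). The balance
weights default to lambda = 0.5 and beta = 0.2.

Evaluation metrics on binary masks: Dice similarity coefficient
DSC = 2|P∩G| / (|P|+|G|), Jaccard index JI = |P∩G| / |P∪G|, and relative
volume difference RVD = (|P|-|G|) / |G|. For the degenerate empty-vs-empty
pair DSC and JI are defined as 1 (perfect agreement); RVD requires a
nonempty ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn

__all__ = [
    "LossWeights", "SOBEL_X", "SOBEL_Y",
    "dice_loss", "bce_loss", "sobel_gradients", "boundary_loss", "total_loss",
    "dsc", "ji", "rvd",
]

# Directional derivative kernels; the vertical one is the transpose of the
# horizontal one, and each sums to zero so constants have zero gradient.
SOBEL_X = np.array([[-1, 0, 1],
                    [-2, 0, 2],
                    [-1, 0, 1]], dtype=np.float32)
SOBEL_Y = SOBEL_X.T.copy()


@dataclasses.dataclass(frozen=True)
class LossWeights:
    lam: float = 0.5     # BCE weight
    beta: float = 0.2    # boundary weight
    eps: float = 1e-6    # Dice stabiliser
    clip: float = 1e-7   # probability clamp for the BCE logs

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("lambda and beta must lie in [0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if not 0.0 < self.clip < 0.5:
            raise ValueError("clip must lie in (0, 0.5)")


def _lift(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=np.float32))


def _check_coshaped(p: nn.Tensor, g: nn.Tensor) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {g.shape}")


def dice_loss(p, g, eps: float = 1e-6) -> nn.Tensor:
    """Soft Dice loss: 1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps).

    Zero exactly when p equals a binary g (including the all-empty pair,
    where the stabiliser makes the ratio eps/eps = 1).
    """
    p, g = _lift(p), _lift(g)
    _check_coshaped(p, g)
    inter = (p * g).sum()
    denom = p.sum() + g.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def bce_loss(p, g, clip: float = 1e-7) -> nn.Tensor:
    """Mean binary cross-entropy with probabilities clamped to [clip, 1-clip]."""
    p, g = _lift(p), _lift(g)
    _check_coshaped(p, g)
    pc = p.clamp(clip, 1.0 - clip)
    ll = g * pc.log() + (1.0 - g) * (1.0 - pc).log()
    return -ll.mean()


def _replicate_pad1(x: nn.Tensor) -> nn.Tensor:
    """Edge-replicate pad by 1 on both spatial axes of an NCHW tensor."""
    H, W = x.shape[2], x.shape[3]
    ri = np.clip(np.arange(-1, H + 1), 0, H - 1)
    ci = np.clip(np.arange(-1, W + 1), 0, W - 1)
    return x[:, :, ri, :][:, :, :, ci]


_SOBEL_WX = nn.Tensor(SOBEL_X.reshape(1, 1, 3, 3))
_SOBEL_WY = nn.Tensor(SOBEL_Y.reshape(1, 1, 3, 3))


def _sobel_pair(x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
    """Differentiable Sobel responses of an (B,1,H,W) map, replicate-padded."""
    xp = _replicate_pad1(x)
    gx = nn.conv2d(xp, _SOBEL_WX)[:, :, 1:-1, 1:-1]
    gy = nn.conv2d(xp, _SOBEL_WY)[:, :, 1:-1, 1:-1]
    return gx, gy


def sobel_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical Sobel responses of a 2D image.

    Correlation with the two kernels on a replicate-padded image, so the
    output has the input's shape. Requires H, W >= 3.
    """
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("sobel_gradients needs a 2D image with H, W >= 3")
    t = nn.Tensor(img.reshape(1, 1, *img.shape))
    gx, gy = _sobel_pair(t)
    return gx.data[0, 0], gy.data[0, 0]


def boundary_loss(p, g) -> nn.Tensor:
    """Mean L1 distance between Sobel responses of prediction and target,
    summed over the two directions; applied per slice of an (B,1,H,W) pair.

    Invariant to adding the same constant to both inputs, and exactly zero
    when the inputs are equal or both constant.
    """
    p, g = _lift(p), _lift(g)
    _check_coshaped(p, g)
    if p.ndim == 2:
        p = p.reshape(1, 1, *p.shape)
        g = g.reshape(1, 1, *g.shape)
    if p.ndim != 4:
        raise ValueError("boundary_loss expects (B,1,H,W) or (H,W) inputs")
    px, py = _sobel_pair(p)
    gx, gy = _sobel_pair(g)
    n = float(np.prod(p.shape))
    return ((px - gx).abs().sum() + (py - gy).abs().sum()) / n


def total_loss(p, g, weights: LossWeights = LossWeights()
               ) -> tuple[nn.Tensor, dict[str, float]]:
    """Hybrid objective L = L_Dice + lambda*L_BCE + beta*L_Boundary.

    Returns the differentiable total and a float breakdown of components.
    """
    l_dice = dice_loss(p, g, weights.eps)
    l_bce = bce_loss(p, g, weights.clip)
    l_bnd = boundary_loss(p, g)
    total = l_dice + weights.lam * l_bce + weights.beta * l_bnd
    parts = {"dice": l_dice.item(), "bce": l_bce.item(),
             "boundary": l_bnd.item(), "total": total.item()}
    return total, parts


# ---------------------------------------------------------------------------
# Binary-mask metrics


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(getattr(mask, "voxels", mask))
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError(f"metric inputs must be binary, found {values[:10]}")
    return arr.astype(bool)


def _counts(pred, truth) -> tuple[int, int, int]:
    p, g = _as_binary(pred), _as_binary(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return int((p & g).sum()), int(p.sum()), int(g.sum())


def dsc(pred, truth) -> float:
    """Dice similarity coefficient in [0, 1]; empty vs empty -> 1."""
    inter, np_, ng = _counts(pred, truth)
    if np_ + ng == 0:
        return 1.0
    return 2.0 * inter / (np_ + ng)


def ji(pred, truth) -> float:
    """Jaccard index in [0, 1]; empty vs empty -> 1."""
    inter, np_, ng = _counts(pred, truth)
    union = np_ + ng - inter
    if union == 0:
        return 1.0
    return inter / union


def rvd(pred, truth) -> float:
    """Relative volume difference (|P| - |G|) / |G|; needs nonempty truth."""
    _, np_, ng = _counts(pred, truth)
    if ng == 0:
        raise ValueError("RVD is undefined for an empty ground-truth mask")
    return (np_ - ng) / ng
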