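"""Independent straight-line numpy implementations used as test oracles.

Everything here is deliberately naive — explicit loops, no shared code with
the package's compute path — so agreement between the two is meaningful.
"""

import numpy as np


def conv2d_ref(x, w, b):
    """Loop-based stride-1 same-padding correlation. x:(B,C,H,W), w:(O,C,k,k)."""
    B, C, H, W = x.shape
    O, _, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, O, H, W))
    for bb in range(B):
        for o in range(O):
            for i in range(H):
                for j in range(W):
                    out[bb, o, i, j] = np.sum(
                        xp[bb, :, i:i + k, j:j + k] * w[o]) + (b[o] if b is not None else 0.0)
    return out


def bn_eval_ref(x, gamma, beta, rm, rv, eps=1e-5):
    """(B,C,H,W) batch norm with stored statistics."""
    return ((x - rm[None, :, None, None]) / np.sqrt(rv[None, :, None, None] + eps)
            * gamma[None, :, None, None] + beta[None, :, None, None])


def convblock_eval_ref(x, block):
    """conv -> BN(eval stats) -> ReLU, reading the block's arrays directly."""
    bias = None if block.conv.bias is None else block.conv.bias.data
    y = conv2d_ref(x, block.conv.weight.data, bias)
    y = bn_eval_ref(y, block.bn.gamma.data, block.bn.beta.data,
                    block.bn.running_mean, block.bn.running_var, block.bn.eps)
    return np.maximum(y, 0.0)


def softmax_ref(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def mhsa_ref(z, wq, wk, wv, wo, n_heads):
    """Per-head loops over queries: softmax(QK^T/sqrt(dk))V, concat, project."""
    B, N, D = z.shape
    dk = D // n_heads
    out = np.zeros_like(z)
    for bb in range(B):
        heads = []
        for h in range(n_heads):
            cols = slice(h * dk, (h + 1) * dk)
            q = z[bb] @ wq[:, cols]
            k = z[bb] @ wk[:, cols]
            v = z[bb] @ wv[:, cols]
            ctx = np.zeros((N, dk))
            for i in range(N):
                scores = np.array([q[i] @ k[j] for j in range(N)]) / np.sqrt(dk)
                alpha = softmax_ref(scores)
                ctx[i] = sum(alpha[j] * v[j] for j in range(N))
            heads.append(ctx)
        out[bb] = np.concatenate(heads, axis=1) @ wo
    return out


def leaky_relu_ref(v, slope=0.2):
    return np.where(v > 0, v, slope * v)


def gat_attention_ref(nodes, W, a_src, a_dst, slope=0.2):
    """Explicit Eq.-style loops: alpha_ij = softmax_j LeakyReLU(a^T[Wh_i||Wh_j])."""
    B, N, _ = nodes.shape
    a = np.concatenate([a_src, a_dst])
    alpha = np.zeros((B, N, N))
    for bb in range(B):
        h = nodes[bb] @ W
        for i in range(N):
            logits = np.array([
                leaky_relu_ref(a @ np.concatenate([h[i], h[j]]), slope)
                for j in range(N)])
            alpha[bb, i] = softmax_ref(logits)
    return alpha


def elu_ref(v):
    return np.where(v > 0, v, np.exp(v) - 1.0)


def gat_layer_ref(nodes, W, a_src, a_dst, slope=0.2):
    alpha = gat_attention_ref(nodes, W, a_src, a_dst, slope)
    B, N, _ = nodes.shape
    out = np.zeros((B, N, W.shape[1]))
    for bb in range(B):
        h = nodes[bb] @ W
        for i in range(N):
            out[bb, i] = elu_ref(sum(alpha[bb, i, j] * h[j] for j in range(N)))
    return out


def conv1x1_ref(x, w, b):
    """1x1 convolution as a per-pixel matrix product. x:(B,C,H,W), w:(O,C,1,1)."""
    B, C, H, W = x.shape
    O = w.shape[0]
    out = np.zeros((B, O, H, W))
    for i in range(H):
        for j in range(W):
            out[:, :, i, j] = x[:, :, i, j] @ w[:, :, 0, 0].T + b
    return out


def sigmoid_ref(v):
    return 1.0 / (1.0 + np.exp(-v))


def fusion_attention_ref(cat, fa):
    """Channel-MLP fusion + sigmoid spatial gate, reading module arrays."""
    h = conv1x1_ref(cat, fa.mlp1.weight.data, fa.mlp1.bias.data)
    h = np.maximum(h, 0.0)
    fused = conv1x1_ref(h, fa.mlp2.weight.data, fa.mlp2.bias.data)
    gate = sigmoid_ref(conv1x1_ref(fused, fa.attn.weight.data, fa.attn.bias.data))
    return fused * gate


def msr_ref(f_pre, f_post, f_res, block):
    """Straight-line evaluation of the refinement unit in eval mode."""
    tp = convblock_eval_ref(f_pre, block.fconv_pre)
    to = convblock_eval_ref(f_post, block.fconv_post)
    tr = convblock_eval_ref(f_res, block.fconv_res)
    return fusion_attention_ref(np.concatenate([tp, to, tr], axis=1), block.fusion)


def batch_slice_attention_ref(x, conv):
    """Row-layout recalibration: (B,C,H,W) -> (B*H,C,1,W) -> gate -> restore."""
    B, C, H, W = x.shape
    out = np.zeros_like(x)
    w = conv.weight.data[:, :, 0, 0]
    bias = conv.bias.data
    for bb in range(B):
        for hh in range(H):
            row = x[bb, :, hh, :]                 # (C, W)
            logits = w @ row + bias[:, None]
            out[bb, :, hh, :] = row * sigmoid_ref(logits)
    return out


def isa_ref(x, isa):
    """Chained oracle: fconv -> nodes -> GAT -> reshape -> recalibration."""
    B, C, H, W = x.shape
    feat = convblock_eval_ref(x, isa.fconv)
    nodes = feat.reshape(B, C, H * W).transpose(0, 2, 1)
    p = isa.gat.params
    nodes = gat_layer_ref(nodes, p.W.data, p.a_src.data, p.a_dst.data,
                          p.negative_slope)
    feat = nodes.transpose(0, 2, 1).reshape(B, C, H, W)
    return batch_slice_attention_ref(feat, isa.recal.conv)


def stge_ref(f_pre, f_post, f_res, stge):
    cat = np.concatenate([isa_ref(f_pre, stge.isa_pre),
                          isa_ref(f_post, stge.isa_post),
                          isa_ref(f_res, stge.isa_res)], axis=1)
    return fusion_attention_ref(cat, stge.ita)


def randomize_module(module, rng, bn_stats=True):
    """Overwrite every parameter (and BN running stats) with random values."""
    for _, p in module.named_parameters():
        p.data = rng.normal(0.0, 0.5, size=p.data.shape).astype(np.float32)
    if bn_stats:
        for mod in module.modules():
            if hasattr(mod, "running_mean"):
                mod._set_buffer("running_mean",
                                rng.normal(0, 0.3, mod.running_mean.shape).astype(np.float32))
                mod._set_buffer("running_var",
                                rng.uniform(0.5, 1.5, mod.running_var.shape).astype(np.float32))
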