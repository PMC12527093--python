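"""Nested-loop reference implementations used as independent oracles.

These are deliberately slow and literal (quadruple loops, explicit padding)
so they cannot share bugs with the vectorised implementations they check.
"""

import numpy as np


def conv2d(x, w, stride=1, padding=0, dilation=1, bias=None):
    """x [N,C,H,W], w [O,C,kh,kw] -> [N,O,Ho,Wo]; cross-correlation."""
    n, c, h, width = x.shape
    o, _, kh, kw = w.shape
    ho = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    wo = (width + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    xp = np.zeros((n, c, h + 2 * padding, width + 2 * padding), dtype=np.float64)
    xp[:, :, padding:padding + h, padding:padding + width] = x
    out = np.zeros((n, o, ho, wo))
    for ni in range(n):
        for oi in range(o):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ci in range(c):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += (xp[ni, ci, i * stride + ki * dilation,
                                           j * stride + kj * dilation]
                                        * w[oi, ci, ki, kj])
                    out[ni, oi, i, j] = acc
            if bias is not None:
                out[ni, oi] += bias[oi]
    return out


def depthwise_conv2d(x, w, stride=1, padding=1):
    """x [N,C,H,W], w [C,kh,kw] -> per-channel filtering, no mixing."""
    n, c, h, width = x.shape
    _, kh, kw = w.shape
    ho = (h + 2 * padding - (kh - 1) - 1) // stride + 1
    wo = (width + 2 * padding - (kw - 1) - 1) // stride + 1
    xp = np.zeros((n, c, h + 2 * padding, width + 2 * padding), dtype=np.float64)
    xp[:, :, padding:padding + h, padding:padding + width] = x
    out = np.zeros((n, c, ho, wo))
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ki in range(kh):
                        for kj in range(kw):
                            acc += xp[ni, ci, i * stride + ki, j * stride + kj] * w[ci, ki, kj]
                    out[ni, ci, i, j] = acc
    return out


def maxpool2d(x, k=3, stride=2, padding=1):
    n, c, h, width = x.shape
    ho = (h + 2 * padding - k) // stride + 1
    wo = (width + 2 * padding - k) // stride + 1
    xp = np.full((n, c, h + 2 * padding, width + 2 * padding), -np.inf)
    xp[:, :, padding:padding + h, padding:padding + width] = x
    out = np.zeros((n, c, ho, wo))
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    out[ni, ci, i, j] = xp[ni, ci,
                                           i * stride:i * stride + k,
                                           j * stride:j * stride + k].max()
    return out


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


def channel_attention(x, w1, w2):
    """Direct evaluation: sigmoid(MLP(avg) + MLP(max)) channel gates."""
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    for ni in range(n):
        avg = x[ni].reshape(c, -1).mean(axis=1)
        mx = x[ni].reshape(c, -1).max(axis=1)
        s = np.zeros(c)
        for v in (avg, mx):
            hid = np.maximum(w1 @ v, 0.0)
            s += w2 @ hid
        gate = _sigmoid(s)
        for ci in range(c):
            out[ni, ci] = x[ni, ci] * gate[ci]
    return out


def spatial_attention(x, conv_w, conv_b):
    """Direct evaluation: sigmoid(conv([mean_c; max_c])) spatial gates."""
    n, c, h, w = x.shape
    k = conv_w.shape[-1]
    pad = (k - 1) // 2
    out = np.zeros_like(x, dtype=np.float64)
    for ni in range(n):
        maps = np.stack([x[ni].mean(axis=0), x[ni].max(axis=0)])[None]
        s = conv2d(maps, conv_w, stride=1, padding=pad, bias=conv_b)[0, 0]
        gate = _sigmoid(s)
        for ci in range(c):
            out[ni, ci] = x[ni, ci] * gate
    return out


def confusion_counts(y_true, y_pred, n_classes=5):
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[t][p] += 1
    return counts


def median_sorted(values):
    """Median as the central order statistic(s) of a sorted copy."""
    s = sorted(values)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])
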