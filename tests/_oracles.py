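"""Independent brute-force oracles used by several test modules. These stay
deliberately naive (nested loops, pair counting) so they cannot share code
paths with the implementation they check."""

import numpy as np


def direct_conv(x, w, stride=1, pad=0):
    """Nested-loop convolution (cross-correlation, as in CNNs)."""
    n, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (wd + 2 * pad - kw) // stride + 1
    out = np.zeros((n, cout, oh, ow))
    for b in range(n):
        for o in range(cout):
            for i in range(oh):
                for j in range(ow):
                    patch = x[b, :, i * stride : i * stride + kh, j * stride : j * stride + kw]
                    out[b, o, i, j] = np.sum(patch * w[o])
    return out


def dense_layer_oracle(x, layer):
    """Direct-arithmetic forward of a dense layer in inference mode: explicit
    batch norm, ReLU and loop-based convolutions, then concatenation."""

    def bn(v, bnl):
        inv = 1.0 / np.sqrt(bnl.running_var + bnl.eps)
        return (v - bnl.running_mean[None, :, None, None]) * inv[None, :, None, None] \
            * bnl.params["gamma"][None, :, None, None] + bnl.params["beta"][None, :, None, None]

    h = np.maximum(bn(x, layer.bottleneck.bn), 0)
    h = direct_conv(h, layer.bottleneck.conv.params["W"], pad=0)
    h = np.maximum(bn(h, layer.grow.bn), 0)
    h = direct_conv(h, layer.grow.conv.params["W"], pad=1)
    return np.concatenate([x, h], axis=1)


def pair_counting_auc(scores, labels):
    """Mann-Whitney oracle: fraction of (positive, negative) pairs ranked
    correctly, ties counted half."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))
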