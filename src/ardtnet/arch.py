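"""The attention-residual densely connected network.

Building blocks:

* pre-activation convolutions (batch norm -> ReLU -> convolution);
* dense layers: a 1x1 bottleneck to 4k channels followed by a padded 3x3
  convolution producing k new channels, concatenated onto the input;
* transition blocks: pre-activated 1x1 convolution back to the block's input
  channel count, then 2x2 average pooling;
* the attention-residual combine: with F the dense+transition output and G a
  2x2 average pooling of the block input,

      mask = per-channel spatial softmax of F
      W    = mask * G            (element-wise)
      out  = F + G + b * W

  which adds no trainable parameters when the trade-off scalar b is fixed.

The final dense block has no transition (its spatial size is already the
classifier's working resolution), so no shape-compatible shortcut exists and
the attention-residual module is bypassed there.
"""

from __future__ import annotations

import io
import json

import numpy as np

from .layers import (DTYPE, AvgPool2d, BatchNorm2d, Conv2d, GlobalAvgPool,
                     Layer, Linear, ReLU, ShapeError)
from .params import ArchConfig, ModelSpec, assemble_model


# ---------------------------------------------------------------------------
# attention primitives (pure functions, usable outside the network)

def spatial_softmax_mask(f: np.ndarray) -> np.ndarray:
    """Per-channel spatial softmax: mask[..., c, i, j] sums to 1 over (i, j).

    Accepts CHW or NCHW input; exponents are stabilized by subtracting the
    per-channel spatial maximum.
    """
    f = np.asarray(f)
    if not np.all(np.isfinite(f)):
        raise ValueError("spatial softmax requires finite input")
    if f.ndim not in (3, 4):
        raise ShapeError(f"expected CHW or NCHW input, got shape {f.shape}")
    m = f.max(axis=(-2, -1), keepdims=True)
    e = np.exp(f - m)
    return e / e.sum(axis=(-2, -1), keepdims=True)


def attention_residual_combine(f: np.ndarray, g: np.ndarray, b: float) -> np.ndarray:
    """Combine dense-path output ``f`` with shortcut ``g``:
    ``f + g + b * (spatial_softmax_mask(f) * g)``."""
    f = np.asarray(f)
    g = np.asarray(g)
    if f.shape != g.shape:
        raise ShapeError(f"attention combine shape mismatch: {f.shape} vs {g.shape}")
    return f + g + b * spatial_softmax_mask(f) * g


class AttentionResidual(Layer):
    """Stateful version of the combine, with the backward pass.

    When ``learnable`` is true the trade-off scalar b is a trainable
    parameter (one per block); otherwise the module is parameter-free.
    """

    def __init__(self, b: float = 0.001, learnable: bool = False):
        super().__init__()
        if learnable:
            self.params["b"] = np.array([b], dtype=DTYPE)
        else:
            self.b_fixed = float(b)

    @property
    def b(self) -> float:
        return float(self.params["b"][0]) if "b" in self.params else self.b_fixed

    def forward2(self, f: np.ndarray, g: np.ndarray, train: bool = False) -> np.ndarray:
        if f.shape != g.shape:
            raise ShapeError(f"attention combine shape mismatch: {f.shape} vs {g.shape}")
        mask = spatial_softmax_mask(f)
        if train:
            self._cache = (mask, g)
        return f + g + self.b * mask * g

    def backward2(self, grad: np.ndarray):
        """Return (dL/dF, dL/dG)."""
        mask, g = self._cache
        b = self.b
        dg = grad * (1.0 + b * mask)
        dmask = b * grad * g
        # softmax Jacobian applied per channel over spatial positions
        df = grad + mask * (dmask - (dmask * mask).sum(axis=(-2, -1), keepdims=True))
        if "b" in self.params:
            self.grads["b"] = np.array([(grad * mask * g).sum()], dtype=DTYPE)
        return df.astype(DTYPE), dg.astype(DTYPE)


# ---------------------------------------------------------------------------
# composite blocks

class PreActConv:
    """batch norm -> ReLU -> convolution, the ordering used throughout."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng=None, name: str = "preact"):
        self.bn = BatchNorm2d(in_ch)
        self.relu = ReLU()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, pad=pad,
                           bias=False, rng=rng, name=name)

    def forward(self, x, train=False):
        return self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train)

    def backward(self, grad):
        return self.bn.backward(self.relu.backward(self.conv.backward(grad)))

    @property
    def layers(self):
        return [self.bn, self.relu, self.conv]


def preact_conv(x: np.ndarray, module: PreActConv) -> np.ndarray:
    """Functional form of the pre-activated convolution (inference mode)."""
    return module.forward(x, train=False)


class DenseLayer:
    """1x1 bottleneck to 4k channels, 3x3 convolution to k new channels,
    output concatenated with the input along channels."""

    def __init__(self, in_ch: int, growth_rate: int, rng=None, name: str = "dense"):
        self.in_ch = in_ch
        self.bottleneck = PreActConv(in_ch, 4 * growth_rate, 1, rng=rng,
                                     name=f"{name}.bottleneck")
        self.grow = PreActConv(4 * growth_rate, growth_rate, 3, pad=1, rng=rng,
                               name=f"{name}.grow")

    def forward(self, x, train=False):
        new = self.grow.forward(self.bottleneck.forward(x, train), train)
        return np.concatenate([x, new], axis=1)

    def backward(self, grad):
        dx, dnew = grad[:, : self.in_ch], grad[:, self.in_ch:]
        return dx + self.bottleneck.backward(self.grow.backward(dnew))

    @property
    def layers(self):
        return self.bottleneck.layers + self.grow.layers


class DenseBlock:
    def __init__(self, in_ch: int, n_layers: int, growth_rate: int, rng=None,
                 name: str = "block"):
        self.dense_layers = [
            DenseLayer(in_ch + i * growth_rate, growth_rate, rng=rng,
                       name=f"{name}.dense{i + 1}")
            for i in range(n_layers)
        ]
        self.out_ch = in_ch + n_layers * growth_rate

    def forward(self, x, train=False):
        for dl in self.dense_layers:
            x = dl.forward(x, train)
        return x

    def backward(self, grad):
        for dl in reversed(self.dense_layers):
            grad = dl.backward(grad)
        return grad

    @property
    def layers(self):
        return [l for dl in self.dense_layers for l in dl.layers]


class Transition:
    """Pre-activated 1x1 convolution to ``target_channels`` then 2x2 average
    pooling; halves the spatial side."""

    def __init__(self, in_ch: int, target_channels: int, rng=None, name: str = "transition"):
        self.conv = PreActConv(in_ch, target_channels, 1, rng=rng, name=name)
        self.pool = AvgPool2d(2)

    def forward(self, x, train=False):
        return self.pool.forward(self.conv.forward(x, train), train)

    def backward(self, grad):
        return self.conv.backward(self.pool.backward(grad))

    @property
    def layers(self):
        return self.conv.layers + [self.pool]


class ARDTBlock:
    """Dense block + transition on the main path, 2x2 average pooling on the
    shortcut, joined by the attention-residual combine. The final block of the
    network is dense-only (``has_transition=False``)."""

    def __init__(self, in_ch: int, cfg: ArchConfig, has_transition: bool,
                 rng=None, name: str = "ardt"):
        self.in_ch = in_ch
        self.has_transition = has_transition
        self.dense = DenseBlock(in_ch, cfg.layers_per_block, cfg.growth_rate,
                                rng=rng, name=name)
        if has_transition:
            self.transition = Transition(self.dense.out_ch, in_ch, rng=rng,
                                         name=f"{name}.transition")
            self.shortcut_pool = AvgPool2d(2)
            self.attention = AttentionResidual(cfg.attention_weight_b, cfg.b_learnable)
            self.out_ch = in_ch
        else:
            self.out_ch = self.dense.out_ch

    def forward(self, x, train=False):
        if not self.has_transition:
            return self.dense.forward(x, train)
        f = self.transition.forward(self.dense.forward(x, train), train)
        g = self.shortcut_pool.forward(x, train)
        return self.attention.forward2(f, g, train)

    def backward(self, grad):
        if not self.has_transition:
            return self.dense.backward(grad)
        df, dg = self.attention.backward2(grad)
        dx_main = self.dense.backward(self.transition.backward(df))
        dx_short = self.shortcut_pool.backward(dg)
        return dx_main + dx_short

    @property
    def layers(self):
        ls = self.dense.layers
        if self.has_transition:
            ls += self.transition.layers + [self.shortcut_pool, self.attention]
        return ls


class ARDTDenseNet:
    """The full network: 3x3 stride-2 convolution to 4k channels, 2x2 average
    pool, the ARDT blocks, final batch norm + ReLU, global average pooling and
    a softmax classification head."""

    def __init__(self, cfg: ArchConfig | None = None, seed: int = 0):
        self.cfg = cfg or ArchConfig()
        self.cfg.validate()
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = self.cfg

        self.conv1 = Conv2d(3, c.initial_channels, 3, stride=c.conv1_stride,
                            pad=1, bias=False, rng=rng, name="conv1")
        self.pool1 = AvgPool2d(2)
        self.blocks: list[ARDTBlock] = []
        ch = c.initial_channels
        for b in range(c.num_blocks):
            block = ARDTBlock(ch, c, has_transition=(b < c.num_blocks - 1),
                              rng=rng, name=f"block{b + 1}")
            self.blocks.append(block)
            ch = block.out_ch
        self.final_bn = BatchNorm2d(ch)
        self.final_relu = ReLU()
        self.gap = GlobalAvgPool()
        self.head = Linear(ch, c.num_classes, bias=True, rng=rng)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (N, num_classes) for NCHW input."""
        h = self.pool1.forward(self.conv1.forward(x, train), train)
        for block in self.blocks:
            h = block.forward(h, train)
        h = self.final_relu.forward(self.final_bn.forward(h, train), train)
        return self.head.forward(self.gap.forward(h, train), train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.gap.backward(self.head.backward(dlogits))
        g = self.final_bn.backward(self.final_relu.backward(g))
        for block in reversed(self.blocks):
            g = block.backward(g)
        return self.conv1.backward(self.pool1.backward(g))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities via a numerically stable softmax."""
        z = self.forward(x, train=False)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- parameter plumbing -------------------------------------------------
    @property
    def layers_flat(self) -> list[Layer]:
        ls: list[Layer] = [self.conv1, self.pool1]
        for block in self.blocks:
            ls += block.layers
        ls += [self.final_bn, self.final_relu, self.gap, self.head]
        return ls

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers_flat)

    def spec(self) -> ModelSpec:
        return assemble_model(self.cfg)

    # -- checkpointing -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers_flat):
            for k, v in layer.params.items():
                arrays[f"layer{i}.{k}"] = v
            if isinstance(layer, BatchNorm2d):
                arrays[f"layer{i}.running_mean"] = layer.running_mean
                arrays[f"layer{i}.running_var"] = layer.running_var
        return arrays

    def save(self, path) -> None:
        """Single-file checkpoint: the configuration plus every parameter and
        running-statistics array. Round-trips bit-exactly."""
        arrays = self.state_arrays()
        arrays["_config"] = np.frombuffer(
            json.dumps({**self.cfg.__dict__, "seed": self.seed}).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "ARDTDenseNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_config"]).decode())
            seed = meta.pop("seed", 0)
            model = cls(ArchConfig(**meta), seed=seed)
            for i, layer in enumerate(model.layers_flat):
                for k in layer.params:
                    layer.params[k][...] = data[f"layer{i}.{k}"]
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean[...] = data[f"layer{i}.running_mean"]
                    layer.running_var[...] = data[f"layer{i}.running_var"]
        return model
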