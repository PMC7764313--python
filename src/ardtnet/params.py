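"""Declarative layer specs and closed-form parameter arithmetic.

The numeric network in :mod:`ardtnet.arch` and the ``LayerSpec`` list built
here are generated from the same configuration, so the closed-form count can
be cross-checked against the actual parameter arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


class ConfigError(ValueError):
    """Raised when an architecture configuration is internally inconsistent."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a network, described only as far as parameter counting
    and shape bookkeeping need."""

    kind: str  # convolution | fully_connected | batch_norm | pooling | activation
    name: str = ""
    kernel_h: int = 0
    kernel_w: int = 0
    stride: int = 1
    in_channels: int = 0
    out_channels: int = 0
    has_bias: bool = False

    def param_count(self) -> int:
        if self.kind == "convolution":
            n = self.kernel_h * self.kernel_w * self.in_channels * self.out_channels
            return n + (self.out_channels if self.has_bias else 0)
        if self.kind == "fully_connected":
            n = self.in_channels * self.out_channels
            return n + (self.out_channels if self.has_bias else 0)
        if self.kind == "batch_norm":
            return 2 * self.in_channels  # scale + shift; running stats are not parameters
        if self.kind in ("pooling", "activation"):
            return 0
        raise ValueError(f"unknown layer kind: {self.kind}")


@dataclass(frozen=True)
class ArchConfig:
    """Hyperparameters of the attention-residual densely connected network.

    Defaults give the 224-input, four-block configuration: growth rate k=12,
    12 bottleneck layers per dense block, initial 3x3 stride-2 convolution to
    4k channels, transitions that restore each block's input channel count,
    and a parameter-free spatial-softmax attention-residual module per block.
    """

    growth_rate: int = 12
    layers_per_block: int = 12
    num_blocks: int = 4
    initial_channels: int = 48  # 4 * growth_rate
    conv1_stride: int = 2
    attention_weight_b: float = 0.001
    b_learnable: bool = False
    num_classes: int = 2
    input_side: int = 224

    def validate(self) -> None:
        bad = []
        if self.growth_rate < 1:
            bad.append("growth_rate")
        if self.num_blocks < 1:
            bad.append("num_blocks")
        if self.layers_per_block < 0:
            bad.append("layers_per_block")
        if self.num_classes < 1:
            bad.append("num_classes")
        # conv1 (stride 2) + initial pool + one transition per non-final block
        downs = 2 ** (self.num_blocks + 1) if self.conv1_stride == 2 else 2 ** self.num_blocks
        if self.input_side % downs:
            bad.append("input_side")
        if bad:
            raise ConfigError(f"invalid architecture configuration fields: {', '.join(bad)}")

    @property
    def block_output_channels(self) -> int:
        return self.initial_channels + self.layers_per_block * self.growth_rate


@dataclass
class ModelSpec:
    """Ordered layer list plus the spatial-side trace of the block graph."""

    config: ArchConfig
    layers: list[LayerSpec] = field(default_factory=list)
    spatial_trace: list[int] = field(default_factory=list)

    def total_params(self) -> int:
        return count_parameters(self.layers)


def count_parameters(spec: ModelSpec | Iterable[LayerSpec]) -> int:
    """Exact trainable-parameter total of a layer list or ModelSpec."""
    if isinstance(spec, ModelSpec):
        spec = spec.layers
    return sum(l.param_count() for l in spec)


def _preact_conv_specs(name: str, in_ch: int, out_ch: int, k: int) -> list[LayerSpec]:
    return [
        LayerSpec("batch_norm", f"{name}.bn", in_channels=in_ch),
        LayerSpec("activation", f"{name}.relu"),
        LayerSpec("convolution", f"{name}.conv", kernel_h=k, kernel_w=k,
                  in_channels=in_ch, out_channels=out_ch, has_bias=False),
    ]


def assemble_model(cfg: ArchConfig, include_attention: bool = True) -> ModelSpec:
    """Build the declarative model: initial convolution and pool, the dense /
    transition / attention-residual blocks, final normalization, global average
    pooling and the softmax classification head.

    ``include_attention`` exists so the parameter-free property of the
    attention module can be asserted by comparing totals with it on and off.
    """
    cfg.validate()
    layers: list[LayerSpec] = []
    trace = [cfg.input_side]
    side = cfg.input_side

    layers.append(LayerSpec("convolution", "conv1", kernel_h=3, kernel_w=3,
                            stride=cfg.conv1_stride, in_channels=3,
                            out_channels=cfg.initial_channels, has_bias=False))
    side //= cfg.conv1_stride
    trace.append(side)
    layers.append(LayerSpec("pooling", "pool1", kernel_h=2, kernel_w=2, stride=2))
    side //= 2
    trace.append(side)

    ch = cfg.initial_channels
    for b in range(cfg.num_blocks):
        block_in = ch
        for l in range(cfg.layers_per_block):
            layers += _preact_conv_specs(f"block{b + 1}.dense{l + 1}.bottleneck",
                                         ch, 4 * cfg.growth_rate, 1)
            layers += _preact_conv_specs(f"block{b + 1}.dense{l + 1}.grow",
                                         4 * cfg.growth_rate, cfg.growth_rate, 3)
            ch += cfg.growth_rate
        final_block = b == cfg.num_blocks - 1
        if not final_block:
            layers += _preact_conv_specs(f"block{b + 1}.transition", ch, block_in, 1)
            layers.append(LayerSpec("pooling", f"block{b + 1}.transition.pool",
                                    kernel_h=2, kernel_w=2, stride=2))
            ch = block_in
            if include_attention:
                layers.append(LayerSpec("pooling", f"block{b + 1}.shortcut.pool",
                                        kernel_h=2, kernel_w=2, stride=2))
                layers.append(LayerSpec("activation", f"block{b + 1}.attention"))
                if cfg.b_learnable:
                    # one trainable trade-off scalar per block, modelled as a
                    # 1x1 "fully connected" scalar
                    layers.append(LayerSpec("fully_connected", f"block{b + 1}.attention.b",
                                            in_channels=1, out_channels=1, has_bias=False))
            side //= 2
            trace.append(side)

    layers.append(LayerSpec("batch_norm", "final.bn", in_channels=ch))
    layers.append(LayerSpec("activation", "final.relu"))
    layers.append(LayerSpec("pooling", "gap", kernel_h=side, kernel_w=side))
    trace.append(1)
    layers.append(LayerSpec("fully_connected", "head", in_channels=ch,
                            out_channels=cfg.num_classes, has_bias=True))
    layers.append(LayerSpec("activation", "softmax"))
    return ModelSpec(config=cfg, layers=layers, spatial_trace=trace)


_VGG16_CHANNELS: Sequence[int] = (64, 64, 128, 128, 256, 256, 256,
                                  512, 512, 512, 512, 512, 512)
_VGG16_POOL_AFTER = {2, 4, 7, 10, 13}


def vgg16_reference_spec() -> list[LayerSpec]:
    """The standard 16-weight-layer VGG configuration (13 conv + 3 FC),
    224x224x3 input, biases on every weight layer, no batch norm.

    Used purely for closed-form parameter arithmetic as a size reference."""
    layers: list[LayerSpec] = []
    in_ch = 3
    side = 224
    for i, out_ch in enumerate(_VGG16_CHANNELS, start=1):
        layers.append(LayerSpec("convolution", f"conv{i}", kernel_h=3, kernel_w=3,
                                in_channels=in_ch, out_channels=out_ch, has_bias=True))
        layers.append(LayerSpec("activation", f"relu{i}"))
        in_ch = out_ch
        if i in _VGG16_POOL_AFTER:
            layers.append(LayerSpec("pooling", f"maxpool{i}", kernel_h=2, kernel_w=2, stride=2))
            side //= 2
    flat = in_ch * side * side  # 512 * 7 * 7
    for j, width in enumerate((4096, 4096, 1000), start=1):
        layers.append(LayerSpec("fully_connected", f"fc{j}", in_channels=flat,
                                out_channels=width, has_bias=True))
        flat = width
    return layers


def summary_rows(spec: ModelSpec | Iterable[LayerSpec]) -> list[dict]:
    """Machine-readable per-layer summary (for the ``params`` command)."""
    if isinstance(spec, ModelSpec):
        spec = spec.layers
    rows = []
    for l in spec:
        rows.append({
            "name": l.name, "kind": l.kind,
            "kernel": f"{l.kernel_h}x{l.kernel_w}" if l.kernel_h else "",
            "in_channels": l.in_channels, "out_channels": l.out_channels,
            "params": l.param_count(),
        })
    return rows
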