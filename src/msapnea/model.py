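"""Multi-scale 1-D residual network for 60 s derived-signal segments.

The classifier follows the 18-layer residual layout: a stride-3 stem
convolution (kernel 7, 64 filters), a stride-2 max pool, four residual
stages whose convolutional layers each run four parallel same-padded
convolutions with kernels 3/5/7/9 and concatenate them along channels
(branch widths 16/32/64/128, so stage widths 64/128/256/512), global
average pooling, dropout 0.5 and a 2-way softmax head. Shortcuts are
identities except where channel count or length changes, where a 1×1
projection (with normalization) is used. Stride 2 sits in the first layer
of the first block of stages 3–5; stage 2 keeps stride 1 because the pool
has already halved the length. Every convolution is followed by batch
normalization, with rectification before the residual addition in the
classic ordering (conv–norm–relu, conv–norm, add, relu).

For one 2×300 input the feature-map lengths are 100 (stem), then
50/50/25/13/7 across pool and stages — ceil-division under stride with
same-style padding. ``count_operations`` reports the analytic forward-pass
cost as 2 × multiply–accumulates over all branch convolutions, projection
shortcuts and the fully connected layer (pooling, normalization and
activations excluded); the default configuration comes to ≈0.143 × 10⁹.

Setting ``multi_scale=False`` collapses each layer to a single kernel-3
convolution with matched output channels — the plain residual baseline the
multi-scale design is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import nnet
from .nnet import (Adam, BatchNorm1d, Conv1d, Dropout, GlobalAvgPool1d,
                   Linear, MaxPool1d, Parameter, ReLU, conv_output_length,
                   softmax)

__all__ = ["ModelConfig", "LayerShape", "MultiScaleResNet", "build_model",
           "layer_shapes", "count_operations", "desk_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture parameterization (defaults = the published layout)."""

    input_channels: int = 2
    input_length: int = 300
    conv1_kernel: int = 7
    conv1_filters: int = 64
    conv1_stride: int = 3
    pool_kernel: int = 3
    pool_stride: int = 2
    stage_branch_widths: tuple[int, ...] = (16, 32, 64, 128)
    branch_kernels: tuple[int, ...] = (3, 5, 7, 9)
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    layers_per_block: int = 2
    stage_strides: tuple[int, ...] = (1, 2, 2, 2)
    dropout: float = 0.5
    n_classes: int = 2
    multi_scale: bool = True

    def __post_init__(self) -> None:
        if not (len(self.stage_branch_widths) == len(self.blocks_per_stage)
                == len(self.stage_strides)):
            raise ValueError("per-stage field lengths disagree")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.layers_per_block < 1 or self.n_classes < 2:
            raise ValueError("invalid layers_per_block or n_classes")
        for name in ("input_channels", "input_length", "conv1_kernel",
                     "conv1_filters", "conv1_stride", "pool_kernel",
                     "pool_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.stage_branch_widths) < 1 or min(self.branch_kernels) < 1 \
                or min(self.blocks_per_stage) < 1 or min(self.stage_strides) < 1:
            raise ValueError("stage parameters must be >= 1")

    @property
    def n_branches(self) -> int:
        return len(self.branch_kernels)

    def stage_channels(self, stage: int) -> int:
        """Output channels of a stage = branch width × number of branches."""
        return self.stage_branch_widths[stage] * self.n_branches

    def layer_branches(self, stage: int) -> list[tuple[int, int]]:
        """(kernel, width) pairs of one convolutional layer in ``stage``."""
        w = self.stage_branch_widths[stage]
        if self.multi_scale:
            return [(k, w) for k in self.branch_kernels]
        return [(self.branch_kernels[0], w * self.n_branches)]

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


def desk_config(**overrides) -> ModelConfig:
    """Reduced-width configuration for CPU-scale training experiments.

    Same topology (multi-scale residual stages, same kernels and strides),
    quarter branch widths and one block per stage; trains in minutes on a
    single core while keeping the architecture under test identical in kind.
    """
    base = dict(conv1_filters=16, stage_branch_widths=(4, 8, 16, 32),
                blocks_per_stage=(1, 1, 1, 1))
    base.update(overrides)
    return ModelConfig(**base)


@dataclass(frozen=True)
class LayerShape:
    name: str
    channels: int
    length: int


def layer_shapes(config: ModelConfig) -> list[LayerShape]:
    """Analytic shape propagation, no weights instantiated."""
    shapes = [LayerShape("conv1", config.conv1_filters,
                         conv_output_length(config.input_length,
                                            config.conv1_stride))]
    length = conv_output_length(shapes[-1].length, config.pool_stride)
    shapes.append(LayerShape("pool", config.conv1_filters, length))
    for i, stride in enumerate(config.stage_strides):
        length = conv_output_length(length, stride)
        shapes.append(LayerShape(f"stage{i + 2}", config.stage_channels(i),
                                 length))
    return shapes


def count_operations(config: ModelConfig) -> int:
    """Forward-pass FLOPs = 2 × MACs over convolutions + the FC head.

    Counts every branch convolution and 1×1 projection shortcut; pooling,
    normalization and activations are excluded from the convention.
    """
    macs = 0
    length = conv_output_length(config.input_length, config.conv1_stride)
    macs += config.conv1_kernel * config.input_channels \
        * config.conv1_filters * length
    length = conv_output_length(length, config.pool_stride)
    in_ch = config.conv1_filters
    for i, (blocks, stride) in enumerate(zip(config.blocks_per_stage,
                                             config.stage_strides)):
        out_ch = config.stage_channels(i)
        branches = config.layer_branches(i)
        for b in range(blocks):
            s = stride if b == 0 else 1
            out_len = conv_output_length(length, s)
            macs += sum(k * in_ch * w for k, w in branches) * out_len
            for _ in range(config.layers_per_block - 1):
                macs += sum(k * out_ch * w for k, w in branches) * out_len
            if in_ch != out_ch or s != 1:
                macs += in_ch * out_ch * out_len  # 1x1 projection shortcut
            in_ch, length = out_ch, out_len
    macs += in_ch * config.n_classes
    return 2 * macs


# ---------------------------------------------------------------------------
# Layer composition
# ---------------------------------------------------------------------------

class _MultiScaleConvLayer:
    """Parallel same-padded convolutions, channel concat, BN, optional ReLU."""

    def __init__(self, in_channels: int, branches: list[tuple[int, int]],
                 stride: int, rng: np.random.Generator, relu: bool,
                 name: str):
        self.convs = [Conv1d(in_channels, w, k, stride, rng,
                             name=f"{name}.k{k}")
                      for k, w in branches]
        self.widths = [w for _, w in branches]
        out_channels = sum(self.widths)
        self.bn = BatchNorm1d(out_channels, name=f"{name}.bn")
        self.relu = ReLU() if relu else None

    def parameters(self) -> list[Parameter]:
        params = [p for c in self.convs for p in c.parameters()]
        return params + self.bn.parameters()

    def batchnorms(self) -> list[BatchNorm1d]:
        return [self.bn]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.concatenate([c.forward(x) for c in self.convs], axis=1)
        y = self.bn.forward(y, training)
        return self.relu.forward(y) if self.relu else y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = self.relu.backward(dy)
        dy = self.bn.backward(dy)
        dx = None
        offset = 0
        for conv, w in zip(self.convs, self.widths):
            d = conv.backward(dy[:, offset:offset + w, :])
            dx = d if dx is None else dx + d
            offset += w
        return dx


class _ResidualBlock:
    """layers_per_block multi-scale layers + shortcut, post-add ReLU."""

    def __init__(self, in_channels: int, branches: list[tuple[int, int]],
                 stride: int, layers_per_block: int,
                 rng: np.random.Generator, name: str):
        out_channels = sum(w for _, w in branches)
        self.layers = []
        ch = in_channels
        for li in range(layers_per_block):
            s = stride if li == 0 else 1
            last = li == layers_per_block - 1
            self.layers.append(_MultiScaleConvLayer(
                ch, branches, s, rng, relu=not last, name=f"{name}.l{li}"))
            ch = out_channels
        if in_channels != out_channels or stride != 1:
            self.proj = Conv1d(in_channels, out_channels, 1, stride, rng,
                               name=f"{name}.proj")
            self.proj_bn = BatchNorm1d(out_channels, name=f"{name}.proj_bn")
        else:
            self.proj = None
        self.out_relu = ReLU()

    def parameters(self) -> list[Parameter]:
        params = [p for l in self.layers for p in l.parameters()]
        if self.proj:
            params += self.proj.parameters() + self.proj_bn.parameters()
        return params

    def batchnorms(self) -> list[BatchNorm1d]:
        bns = [bn for l in self.layers for bn in l.batchnorms()]
        if self.proj:
            bns.append(self.proj_bn)
        return bns

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, training)
        if self.proj:
            s = self.proj_bn.forward(self.proj.forward(x), training)
        else:
            s = x
        return self.out_relu.forward(h + s)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.out_relu.backward(dy)
        dh, ds = dy, dy
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        if self.proj:
            ds = self.proj.backward(self.proj_bn.backward(ds))
        return dh + ds


class MultiScaleResNet:
    """The classifier; forward records per-stage feature-map shapes."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.conv1 = Conv1d(config.input_channels, config.conv1_filters,
                            config.conv1_kernel, config.conv1_stride, rng,
                            name="conv1")
        self.bn1 = BatchNorm1d(config.conv1_filters, name="bn1")
        self.relu1 = ReLU()
        self.pool = MaxPool1d(config.pool_kernel, config.pool_stride)
        self.stages: list[list[_ResidualBlock]] = []
        in_ch = config.conv1_filters
        for i, (blocks, stride) in enumerate(zip(config.blocks_per_stage,
                                                 config.stage_strides)):
            branches = config.layer_branches(i)
            stage = []
            for b in range(blocks):
                stage.append(_ResidualBlock(
                    in_ch, branches, stride if b == 0 else 1,
                    config.layers_per_block, rng, name=f"s{i + 2}.b{b}"))
                in_ch = config.stage_channels(i)
            self.stages.append(stage)
        self.gap = GlobalAvgPool1d()
        self.drop = Dropout(config.dropout)
        self.fc = Linear(in_ch, config.n_classes, rng)
        self.last_shapes: list[LayerShape] = []

    def parameters(self) -> list[Parameter]:
        params = (self.conv1.parameters() + self.bn1.parameters())
        for stage in self.stages:
            for block in stage:
                params += block.parameters()
        return params + self.fc.parameters()

    def batchnorms(self) -> list[BatchNorm1d]:
        bns = [self.bn1]
        for stage in self.stages:
            for block in stage:
                bns += block.batchnorms()
        return bns

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """(n, 2, 300) float segments → (n, n_classes) logits."""
        x = np.asarray(x, dtype=np.float32)
        shapes = []
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x),
                                                training))
        shapes.append(LayerShape("conv1", h.shape[1], h.shape[2]))
        h = self.pool.forward(h)
        shapes.append(LayerShape("pool", h.shape[1], h.shape[2]))
        for i, stage in enumerate(self.stages):
            for block in stage:
                h = block.forward(h, training)
            shapes.append(LayerShape(f"stage{i + 2}", h.shape[1], h.shape[2]))
        h = self.gap.forward(h)
        h = self.drop.forward(h, training, rng)
        self.last_shapes = shapes
        return self.fc.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits)
        d = self.drop.backward(d)
        d = self.gap.backward(d)
        for stage in reversed(self.stages):
            for block in reversed(stage):
                d = block.backward(d)
        d = self.pool.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        self.conv1.backward(d)

    def predict_proba(self, x: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Class probabilities in eval mode (running BN stats, no dropout)."""
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size],
                                            training=False)))
        return np.concatenate(out) if out else np.empty((0,
                                                         self.config.n_classes))

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self.batchnorms()):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        np.savez(path, config=np.array([repr(self.config.to_dict())]),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MultiScaleResNet":
        import ast
        with np.load(path, allow_pickle=False) as z:
            config = ModelConfig.from_dict(ast.literal_eval(str(z["config"][0])))
            net = cls(config, seed=0)
            for i, p in enumerate(net.parameters()):
                p.value[...] = z[f"p{i}"]
            for i, bn in enumerate(net.batchnorms()):
                bn.running_mean[...] = z[f"rm{i}"]
                bn.running_var[...] = z[f"rv{i}"]
        return net


def build_model(config: ModelConfig = ModelConfig(),
                seed: int = 0) -> MultiScaleResNet:
    """Instantiate the classifier with seeded weight initialization."""
    return MultiScaleResNet(config, seed=seed)
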