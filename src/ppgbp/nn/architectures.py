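"""1-D regression architectures.

Every builder returns a backbone ending in global average pooling plus a
two-output linear head, so any input length that survives the stride
stack (>= 64 samples) produces one (SBP, DBP) pair per segment.  A
global ``scale`` knob shrinks channel widths for CPU-scale experiments;
depth is fixed per family.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .layers import (BatchNorm1d, Conv1d, GlobalAvgPool1d, Linear, MaxPool1d,
                     Module, ReLU, Residual, Sequential, SSMLayer)

__all__ = ["ARCHITECTURES", "build_backbone", "RegressionNet"]

MIN_INPUT_LEN = 64


def _w(base: int, scale: float) -> int:
    return max(4, int(round(base * scale)))


class RegressionNet(Module):
    """backbone -> GAP -> linear head with 2 outputs (SBP, DBP)."""

    def __init__(self, backbone: Module, head_in: int, rng: np.random.Generator):
        super().__init__()
        self.backbone = backbone
        self.pool = GlobalAvgPool1d()
        self.head = Linear(head_in, 2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.pool(self.backbone(x)))


def _conv_bn_relu(c_in, c_out, k, stride, rng) -> Sequential:
    return Sequential(Conv1d(c_in, c_out, k, stride=stride, rng=rng),
                      BatchNorm1d(c_out), ReLU())


# ----------------------------------------------------------------------
def lenet1d(scale: float, rng: np.random.Generator) -> tuple[Module, int]:
    c = _w(16, scale)
    body = Sequential(
        _conv_bn_relu(1, c, 9, 1, rng), MaxPool1d(4),
        _conv_bn_relu(c, 2 * c, 9, 1, rng), MaxPool1d(4),
        _conv_bn_relu(2 * c, 4 * c, 9, 1, rng), MaxPool1d(2),
    )
    return body, 4 * c


# ----------------------------------------------------------------------
def _bottleneck(c_in: int, width: int, stride: int, rng) -> Residual:
    c_out = width * 4
    body = Sequential(
        Conv1d(c_in, width, 1, rng=rng), BatchNorm1d(width), ReLU(),
        Conv1d(width, width, 3, stride=stride, rng=rng), BatchNorm1d(width), ReLU(),
        Conv1d(width, c_out, 1, rng=rng), BatchNorm1d(c_out, zero_init=True),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential(Conv1d(c_in, c_out, 1, stride=stride, rng=rng),
                              BatchNorm1d(c_out))
    return Residual(body, shortcut)


def _xresnet1d(blocks: list[int], scale: float, rng) -> tuple[Module, int]:
    s1, s2 = _w(16, scale), _w(32, scale)
    stem = Sequential(
        _conv_bn_relu(1, s1, 5, 2, rng),
        _conv_bn_relu(s1, s1, 5, 1, rng),
        _conv_bn_relu(s1, s2, 5, 1, rng),
        MaxPool1d(2),
    )
    layers: list[Module] = [stem]
    c_in = s2
    for stage, n_blocks in enumerate(blocks):
        width = _w(32 * 2 ** stage, scale)
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(_bottleneck(c_in, width, stride, rng))
            c_in = width * 4
    return Sequential(*layers), c_in


def xresnet1d50(scale, rng):
    return _xresnet1d([3, 4, 6, 3], scale, rng)


def xresnet1d101(scale, rng):
    return _xresnet1d([3, 4, 23, 3], scale, rng)


# ----------------------------------------------------------------------
class InceptionModule(Module):
    """Parallel convolutions with long kernels plus a pooled 1x1 branch."""

    def __init__(self, c_in: int, c_branch: int, rng):
        super().__init__()
        self.bottleneck = Conv1d(c_in, c_branch, 1, bias=False, rng=rng)
        self.convs = [Conv1d(c_branch, c_branch, k, bias=False, rng=rng)
                      for k in (39, 19, 9)]
        self.pool_conv = Conv1d(c_in, c_branch, 1, bias=False, rng=rng)
        self.norm = BatchNorm1d(4 * c_branch)

    def __call__(self, x: Tensor) -> Tensor:
        z = self.bottleneck(x)
        branches = [conv(z) for conv in self.convs]
        # stride-1 max pool approximated by k=3 pooling of a padded copy
        branches.append(self.pool_conv(x))
        return self.norm(concat(branches, axis=1)).relu()


def inception1d(scale: float, rng) -> tuple[Module, int]:
    # six modules with a residual join around every group of three,
    # following the InceptionTime layout
    c = _w(16, scale)
    groups: list[Module] = []
    c_in = 1
    for _ in range(2):
        inner = Sequential(InceptionModule(c_in, c, rng),
                           InceptionModule(4 * c, c, rng),
                           InceptionModule(4 * c, c, rng))
        shortcut = Sequential(Conv1d(c_in, 4 * c, 1, bias=False, rng=rng),
                              BatchNorm1d(4 * c))
        groups.append(Residual(inner, shortcut))
        c_in = 4 * c
    return Sequential(*groups), c_in


# ----------------------------------------------------------------------
def ssm(scale: float, rng) -> tuple[Module, int]:
    c = _w(32, scale)
    layers: list[Module] = [_conv_bn_relu(1, c, 9, 1, rng)]
    for _ in range(4):
        layers.append(SSMLayer(c, n_states=8, kernel_len=256, rng=rng))
    return Sequential(*layers), c


ARCHITECTURES = {
    "lenet1d": lenet1d,
    "xresnet1d50": xresnet1d50,
    "xresnet1d101": xresnet1d101,
    "inception1d": inception1d,
    "ssm": ssm,
}


def build_backbone(architecture: str, scale: float, rng: np.random.Generator) -> RegressionNet:
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}; "
                         f"choose from {sorted(ARCHITECTURES)}")
    body, head_in = ARCHITECTURES[architecture](scale, rng)
    return RegressionNet(body, head_in, rng)
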