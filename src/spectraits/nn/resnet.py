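"""Residual bottleneck encoder for reshaped spectra.

The encoder follows the classic residual recipe: a 7x7 stride-2 stem with
max-pooling, then four stages of bottleneck blocks (1x1 reduce, 3x3, 1x1
expand by x4) with stride-2 transitions and identity shortcuts, ending in
global average pooling.  The "paper"-scale preset expands stage outputs
64 -> 256 -> 512 -> 1024 on 224x224 inputs; the "small" preset is a
desk-scale variant (16 -> 32 -> 64 -> 128 on 32x32) used as the default
for tests and scaled-down experiments.
"""

from __future__ import annotations

import numpy as np

from .core import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Module,
    ReLU,
    Sequential,
)

__all__ = ["Bottleneck", "ResNetEncoder"]


class Bottleneck(Module):
    """1x1 -> 3x3 -> 1x1 residual block with x4 expansion."""

    def __init__(self, cin: int, mid: int, cout: int, stride: int,
                 rng: np.random.Generator) -> None:
        self.conv1 = Conv2d(cin, mid, 1, rng)
        self.bn1 = BatchNorm2d(mid)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid, mid, 3, rng, stride=stride, pad=1)
        self.bn2 = BatchNorm2d(mid)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid, cout, 1, rng)
        self.bn3 = BatchNorm2d(cout)
        if cin != cout or stride != 1:
            self.shortcut: Module | None = Sequential(
                Conv2d(cin, cout, 1, rng, stride=stride), BatchNorm2d(cout)
            )
        else:
            self.shortcut = None
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.relu2(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        sc = x if self.shortcut is None else self.shortcut(x)
        return self.relu_out(out + sc)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        g_main = self.bn3.backward(g)
        g_main = self.conv3.backward(g_main)
        g_main = self.relu2.backward(g_main)
        g_main = self.bn2.backward(g_main)
        g_main = self.conv2.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.bn1.backward(g_main)
        g_main = self.conv1.backward(g_main)
        g_sc = g if self.shortcut is None else self.shortcut.backward(g)
        return g_main + g_sc


class ResNetEncoder(Module):
    """Image batch (B, 3, side, side) -> feature batch (B, feature_dim)."""

    def __init__(self, stage_channels, blocks_per_stage, stem_channels: int,
                 rng: np.random.Generator) -> None:
        from .core import MaxPool2d  # local import keeps __all__ tidy

        self.stem = Sequential(
            Conv2d(3, stem_channels, 7, rng, stride=2, pad=3),
            BatchNorm2d(stem_channels),
            ReLU(),
            MaxPool2d(3, stride=2, pad=1),
        )
        self.stages: list[Module] = []
        cin = stem_channels
        for s, (cout, nblocks) in enumerate(zip(stage_channels, blocks_per_stage)):
            mid = max(cout // 4, 1)
            blocks = []
            for b in range(nblocks):
                stride = 2 if (b == 0 and s > 0) else 1
                blocks.append(Bottleneck(cin, mid, cout, stride, rng))
                cin = cout
            self.stages.append(Sequential(*blocks))
        self.pool = GlobalAvgPool()
        self.feature_dim = int(stage_channels[-1])
        self.stage_channels = tuple(int(c) for c in stage_channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.stem(x)
        for stage in self.stages:
            out = stage(out)
        return self.pool(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.pool.backward(grad)
        for stage in reversed(self.stages):
            g = stage.backward(g)
        return self.stem.backward(g)
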