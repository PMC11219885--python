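"""Composite blocks: sequential container, residual units, parallel branches."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv1d,
    Layer,
    ReLU,
    ShrinkageGate,
)

__all__ = ["Sequential", "ResidualUnit", "ParallelConcat"]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.sublayers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.sublayers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.sublayers):
            dout = layer.backward(dout)
        return dout


class ResidualUnit(Layer):
    """Two conv+batch-norm blocks with an identity or projection shortcut.

    With ``shrinkage=True`` a channel-wise soft-thresholding gate sits after
    the second batch norm, before the residual addition — the deep residual
    shrinkage variant. The shortcut is a 1x1 convolution plus batch norm
    whenever the stride or channel count changes shape.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 9,
        stride: int = 1,
        shrinkage: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.conv1 = Conv1d(in_channels, out_channels, kernel_size, stride, "same", rng)
        self.bn1 = BatchNorm1d(out_channels)
        self.act1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, kernel_size, 1, "same", rng)
        self.bn2 = BatchNorm1d(out_channels)
        self.gate = ShrinkageGate(out_channels, rng=rng) if shrinkage else None
        self.act_out = ReLU()
        if in_channels != out_channels or stride != 1:
            self.shortcut: Sequential | None = Sequential(
                Conv1d(in_channels, out_channels, 1, stride, "same", rng),
                BatchNorm1d(out_channels),
            )
        else:
            self.shortcut = None
        self.sublayers = [
            lyr
            for lyr in (
                self.conv1,
                self.bn1,
                self.act1,
                self.conv2,
                self.bn2,
                self.gate,
                self.act_out,
                self.shortcut,
            )
            if lyr is not None
        ]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        main = self.act1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        main = self.bn2.forward(self.conv2.forward(main, training), training)
        if self.gate is not None:
            main = self.gate.forward(main, training)
        short = self.shortcut.forward(x, training) if self.shortcut is not None else x
        return self.act_out.forward(main + short, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.act_out.backward(dout)
        dmain = dsum
        if self.gate is not None:
            dmain = self.gate.backward(dmain)
        dmain = self.conv2.backward(self.bn2.backward(dmain))
        dmain = self.conv1.backward(self.bn1.backward(self.act1.backward(dmain)))
        dshort = self.shortcut.backward(dsum) if self.shortcut is not None else dsum
        return dmain + dshort


class ParallelConcat(Layer):
    """Run branches on the same input and concatenate along channels."""

    def __init__(self, *branches: Layer) -> None:
        super().__init__()
        self.sublayers = list(branches)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        outs = [b.forward(x, training) for b in self.sublayers]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        chunks = np.split(dout, self._splits, axis=1)
        dx = None
        for branch, chunk in zip(self.sublayers, chunks):
            g = branch.backward(chunk)
            dx = g if dx is None else dx + g
        return dx
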