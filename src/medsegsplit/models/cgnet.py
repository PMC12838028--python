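"""Split context-guided network (CGNet-style lightweight segmenter).

Context-guided blocks pair a local depthwise 3x3 convolution with a dilated
depthwise 3x3 "surround" convolution on a channel-reduced feature map, so
the receptive field grows without adding many parameters.  The network
predicts at 1/8 resolution and restores full resolution with parameter-free
nearest-neighbour upsampling.

The split is deliberately atypical: a shallow 3-conv FE stem, a 13-conv SS
mid-section, and a deep 11-conv BE that holds the majority of the trainable
parameters (mirroring the heavy-BE partition this architecture is known
for in split deployments).  No side tensors cross the boundaries.
"""

from __future__ import annotations

import numpy as np

from ..nn.layers import Conv2d, NearestUpsample, ReLU, Sequential
from .base import (
    ActivationPacket,
    BESubModel,
    FESubModel,
    SSSubModel,
    SplitSegmentationModel,
    SplitSpec,
    register_arch,
)


class ContextGuidedBlock:
    """1x1 reduce -> (depthwise local || depthwise dilated surround) ->
    concat -> ReLU, with a residual connection.  3 conv layers."""

    def __init__(self, channels: int, dilation: int, rng, dtype) -> None:
        half = channels // 2
        self.half = half
        self.layers = {
            "reduce": Conv2d(channels, half, 1, rng, dtype=dtype),
            "loc": Conv2d(half, half, 3, rng, padding=1, groups=half, dtype=dtype),
            "sur": Conv2d(
                half, half, 3, rng, padding=dilation, dilation=dilation, groups=half, dtype=dtype
            ),
        }
        self._relu_r = ReLU()
        self._relu_j = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        r = self._relu_r.forward(self.layers["reduce"].forward(x))
        joint = np.concatenate(
            [self.layers["loc"].forward(r), self.layers["sur"].forward(r)], axis=1
        )
        return self._relu_j.forward(joint) + x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self._relu_j.backward(gy)
        gr = self.layers["loc"].backward(g[:, : self.half]) + self.layers["sur"].backward(
            g[:, self.half :]
        )
        gx = self.layers["reduce"].backward(self._relu_r.backward(gr))
        return gx + gy

    def zero_grad(self) -> None:
        for lay in self.layers.values():
            lay.zero_grad()


class CGNetFE(FESubModel):
    """3-conv stem; the first conv downsamples by 2."""

    def __init__(self, in_channels: int, w: int, rng, dtype) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.stem = self.add(
            "stem",
            Sequential(
                Conv2d(in_channels, w, 3, rng, stride=2, padding=1, dtype=dtype),
                ReLU(),
                Conv2d(w, w, 3, rng, padding=1, dtype=dtype),
                ReLU(),
                Conv2d(w, w, 3, rng, padding=1, dtype=dtype),
                ReLU(),
            ),
        )

    def forward(self, x: np.ndarray) -> ActivationPacket:
        return ActivationPacket(main=self.stem.forward(x))

    def backward(self, gmain, gside):
        return self.stem.backward(gmain)


class CGNetSS(SSSubModel):
    """Downsampling conv + 4 context-guided blocks at 2w (13 conv layers)."""

    def __init__(self, w: int, rng, dtype) -> None:
        super().__init__()
        self.down = self.add(
            "down2", Sequential(Conv2d(w, 2 * w, 3, rng, stride=2, padding=1, dtype=dtype), ReLU())
        )
        self.blocks = [
            self.add(f"cg{i + 1}", ContextGuidedBlock(2 * w, 2, rng, dtype)) for i in range(4)
        ]

    def forward(self, main: np.ndarray) -> np.ndarray:
        h = self.down.forward(main)
        for blk in self.blocks:
            h = blk.forward(h)
        return h

    def backward(self, gmain: np.ndarray) -> np.ndarray:
        g = gmain
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return self.down.backward(g)


class CGNetBE(BESubModel):
    """Downsampling conv + 3 context-guided blocks at 4w + 1x1 head
    (11 conv layers), then x8 nearest upsampling to full resolution."""

    def __init__(self, w: int, num_classes: int, rng, dtype) -> None:
        super().__init__()
        self.down = self.add(
            "down3",
            Sequential(Conv2d(2 * w, 4 * w, 3, rng, stride=2, padding=1, dtype=dtype), ReLU()),
        )
        self.blocks = [
            self.add(f"cg{i + 1}", ContextGuidedBlock(4 * w, 4, rng, dtype)) for i in range(3)
        ]
        self.head = self.add("head", Conv2d(4 * w, num_classes, 1, rng, dtype=dtype))
        self.upsample = self.add("upsample", NearestUpsample(8))

    def forward(self, main: np.ndarray, side: dict[str, np.ndarray]) -> np.ndarray:
        h = self.down.forward(main)
        for blk in self.blocks:
            h = blk.forward(h)
        return self.upsample.forward(self.head.forward(h))

    def backward(self, glogits):
        g = self.head.backward(self.upsample.backward(glogits))
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return self.down.backward(g), {}


@register_arch("cgnet")
def build_cgnet(num_classes, base_width, in_channels, rng, dtype) -> SplitSegmentationModel:
    fe = CGNetFE(in_channels, base_width, rng, dtype)
    ss = CGNetSS(base_width, rng, dtype)
    be = CGNetBE(base_width, num_classes, rng, dtype)
    spec = SplitSpec(arch_name="cgnet", cut_after_fe=3, cut_before_be=17)
    return SplitSegmentationModel(fe, ss, be, spec, num_classes, base_width, pool_factor=8)
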