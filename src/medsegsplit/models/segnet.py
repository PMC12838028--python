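"""Split SegNet: encoder-decoder without skip connections; the decoder
upsamples by *max unpooling* with the argmax indices recorded by the
matching encoder pooling stage.

FE = first encoder conv stage (+ its pooling).  The stage-1 pooling indices
are a client-side side tensor consumed by BE's unpooling; indices produced
by SS pooling stages stay inside SS.  BE = stage-1 unpooling + final conv
stage + classification head.
"""

from __future__ import annotations

import numpy as np

from ..nn.layers import Conv2d, MaxPool2d, MaxUnpool2d, ReLU, Sequential
from .base import (
    ActivationPacket,
    BESubModel,
    FESubModel,
    SSSubModel,
    SplitSegmentationModel,
    SplitSpec,
    register_arch,
)
from .unet import double_conv


class SegNetFE(FESubModel):
    def __init__(self, in_channels: int, w: int, rng, dtype) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.block = self.add("enc1", double_conv(in_channels, w, rng, dtype))
        self.pool = self.add("pool1", MaxPool2d())

    def forward(self, x: np.ndarray) -> ActivationPacket:
        h = self.block.forward(x)
        main = self.pool.forward(h)
        return ActivationPacket(main=main, side={"pool1_idx": self.pool.indices})

    def backward(self, gmain, gside):
        return self.block.backward(self.pool.backward(gmain))


class SegNetSS(SSSubModel):
    def __init__(self, w: int, rng, dtype) -> None:
        super().__init__()
        widths = [w, 2 * w, 4 * w, 8 * w]
        self.enc = [
            self.add(f"enc{i + 2}", double_conv(widths[i], widths[i + 1], rng, dtype))
            for i in range(3)
        ]
        self.pools = [self.add(f"pool{i + 2}", MaxPool2d()) for i in range(3)]
        self.unpools = [self.add(f"unpool{4 - i}", MaxUnpool2d()) for i in range(3)]
        self.dec = [
            self.add(f"dec{4 - i}", double_conv(widths[3 - i], widths[2 - i], rng, dtype))
            for i in range(3)
        ]

    def forward(self, main: np.ndarray) -> np.ndarray:
        h = main
        for blk, pool in zip(self.enc, self.pools):
            h = pool.forward(blk.forward(h))
        for i in range(3):  # deepest decoder stage first
            h = self.dec[i].forward(self.unpools[i].forward(h, self.pools[2 - i].indices))
        return h

    def backward(self, gmain: np.ndarray) -> np.ndarray:
        g = gmain
        for i in reversed(range(3)):
            g = self.unpools[i].backward(self.dec[i].backward(g))
        for i in reversed(range(3)):
            g = self.enc[i].backward(self.pools[i].backward(g))
        return g


class SegNetBE(BESubModel):
    def __init__(self, w: int, num_classes: int, rng, dtype) -> None:
        super().__init__()
        self.unpool = self.add("unpool1", MaxUnpool2d())
        self.block = self.add(
            "dec1",
            Sequential(Conv2d(w, w, 3, rng, padding=1, dtype=dtype), ReLU()),
        )
        self.head = self.add("head", Conv2d(w, num_classes, 3, rng, padding=1, dtype=dtype))

    def forward(self, main: np.ndarray, side: dict[str, np.ndarray]) -> np.ndarray:
        h = self.unpool.forward(main, side["pool1_idx"])
        return self.head.forward(self.block.forward(h))

    def backward(self, glogits):
        g = self.block.backward(self.head.backward(glogits))
        return self.unpool.backward(g), {}


@register_arch("segnet")
def build_segnet(num_classes, base_width, in_channels, rng, dtype) -> SplitSegmentationModel:
    fe = SegNetFE(in_channels, base_width, rng, dtype)
    ss = SegNetSS(base_width, rng, dtype)
    be = SegNetBE(base_width, num_classes, rng, dtype)
    spec = SplitSpec(
        arch_name="segnet",
        cut_after_fe=2,
        cut_before_be=15,
        side_channel_routes=[("FE", "BE", "pool1_idx")],
    )
    return SplitSegmentationModel(fe, ss, be, spec, num_classes, base_width, pool_factor=16)
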