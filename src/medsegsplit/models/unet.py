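"""Split UNet.

Pinned configuration: 4 encoder + 4 decoder stages, channel widths
``(w, 2w, 4w, 8w, 16w)`` with ``w = base_width``, paired 3x3 convolutions,
no normalization layers, transpose-convolution upsampling, 1x1 output head.
At ``base_width=32, num_classes=2`` this totals 7,760,130 trainable
parameters (7.76 M).

Cut points: FE = first paired-conv block (+ the parameter-free pooling);
BE = last transpose-conv + last paired-conv block + output head; SS =
everything in between.  The stage-1 skip feature is produced by FE and
consumed by BE, so it is routed on the client and never reaches the server.
"""

from __future__ import annotations

import numpy as np

from ..nn.layers import Conv2d, ConvTranspose2d, MaxPool2d, ReLU, Sequential
from .base import (
    ActivationPacket,
    BESubModel,
    FESubModel,
    SSSubModel,
    SplitSegmentationModel,
    SplitSpec,
    register_arch,
)


def double_conv(cin: int, cout: int, rng, dtype) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng, padding=1, dtype=dtype),
        ReLU(),
        Conv2d(cout, cout, 3, rng, padding=1, dtype=dtype),
        ReLU(),
    )


class UNetFE(FESubModel):
    def __init__(self, in_channels: int, w: int, rng, dtype) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.block = self.add("enc1", double_conv(in_channels, w, rng, dtype))
        self.pool = self.add("pool1", MaxPool2d())

    def forward(self, x: np.ndarray) -> ActivationPacket:
        skip = self.block.forward(x)
        return ActivationPacket(main=self.pool.forward(skip), side={"skip1": skip})

    def backward(self, gmain, gside):
        g = self.pool.backward(gmain)
        if "skip1" in gside:
            g = g + gside["skip1"]
        return self.block.backward(g)


class UNetSS(SSSubModel):
    """Encoder stages 2-4, bottleneck, decoder stages 4-2 (skips internal)."""

    def __init__(self, w: int, rng, dtype, gate_factory=None) -> None:
        super().__init__()
        widths = [w, 2 * w, 4 * w, 8 * w, 16 * w]
        self.widths = widths
        self.enc = [
            self.add(f"enc{i + 2}", double_conv(widths[i], widths[i + 1], rng, dtype))
            for i in range(3)
        ]
        self.pools = [self.add(f"pool{i + 2}", MaxPool2d()) for i in range(3)]
        self.mid = self.add("bottleneck", double_conv(widths[3], widths[4], rng, dtype))
        # decoder stages, deepest first: up4/dec4, up3/dec3, up2/dec2
        self.ups = [
            self.add(f"up{4 - i}", ConvTranspose2d(widths[4 - i], widths[3 - i], 2, rng, stride=2, dtype=dtype))
            for i in range(3)
        ]
        self.dec = [
            self.add(f"dec{4 - i}", double_conv(2 * widths[3 - i], widths[3 - i], rng, dtype))
            for i in range(3)
        ]
        # optional attention gates on the internal skips (Attention UNet)
        self.gates = None
        if gate_factory is not None:
            self.gates = [
                self.add(f"gate{4 - i}", gate_factory(widths[3 - i], rng, dtype))
                for i in range(3)
            ]

    def forward(self, main: np.ndarray) -> np.ndarray:
        h = main
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            s = blk.forward(h)
            skips.append(s)
            h = pool.forward(s)
        h = self.mid.forward(h)
        for i in range(3):  # i=0 -> deepest decoder stage
            u = self.ups[i].forward(h)
            s = skips[2 - i]
            if self.gates is not None:
                s = self.gates[i].forward(s, u)
            h = self.dec[i].forward(np.concatenate([u, s], axis=1))
        return h

    def backward(self, gmain: np.ndarray) -> np.ndarray:
        gskips = [None, None, None]
        g = gmain
        for i in reversed(range(3)):
            cu = self.ups[i].cout
            gcat = self.dec[i].backward(g)
            gu, gs = gcat[:, :cu], gcat[:, cu:]
            if self.gates is not None:
                gs, gg = self.gates[i].backward(gs)
                gu = gu + gg
            gskips[2 - i] = gs
            g = self.ups[i].backward(gu)
        g = self.mid.backward(g)
        for i in reversed(range(3)):
            g = self.pools[i].backward(g)
            g = g + gskips[i]
            g = self.enc[i].backward(g)
        return g


class UNetBE(BESubModel):
    def __init__(self, w: int, num_classes: int, rng, dtype, gate_factory=None) -> None:
        super().__init__()
        self.w = w
        self.up = self.add("up1", ConvTranspose2d(2 * w, w, 2, rng, stride=2, dtype=dtype))
        self.gate = self.add("gate1", gate_factory(w, rng, dtype)) if gate_factory else None
        self.block = self.add("dec1", double_conv(2 * w, w, rng, dtype))
        self.head = self.add("head", Conv2d(w, num_classes, 1, rng, dtype=dtype))

    def forward(self, main: np.ndarray, side: dict[str, np.ndarray]) -> np.ndarray:
        u = self.up.forward(main)
        s = side["skip1"]
        if self.gate is not None:
            s = self.gate.forward(s, u)
        h = self.block.forward(np.concatenate([u, s], axis=1))
        return self.head.forward(h)

    def backward(self, glogits):
        g = self.head.backward(glogits)
        gcat = self.block.backward(g)
        gu, gs = gcat[:, : self.w], gcat[:, self.w :]
        if self.gate is not None:
            gs, gg = self.gate.backward(gs)
            gu = gu + gg
        return self.up.backward(gu), {"skip1": gs}


@register_arch("unet")
def build_unet(num_classes, base_width, in_channels, rng, dtype) -> SplitSegmentationModel:
    fe = UNetFE(in_channels, base_width, rng, dtype)
    ss = UNetSS(base_width, rng, dtype)
    be = UNetBE(base_width, num_classes, rng, dtype)
    spec = SplitSpec(
        arch_name="unet",
        cut_after_fe=2,
        cut_before_be=20,
        side_channel_routes=[("FE", "BE", "skip1")],
    )
    return SplitSegmentationModel(fe, ss, be, spec, num_classes, base_width, pool_factor=16)
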