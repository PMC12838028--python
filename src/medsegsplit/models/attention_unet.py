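"""Split Attention UNet: the UNet backbone with additive attention gates on
the decoder skip connections.

Each gate weights a skip feature map by a spatial attention coefficient
``alpha = sigmoid(psi(relu(Wx x + Wg g)))`` where ``x`` is the skip and
``g`` the (upsampled) gating signal from the decoder.  Gates on the internal
skips live in SS; the stage-1 gate lives in BE, with its skip input routed
client-side from FE.
"""

from __future__ import annotations

import numpy as np

from ..nn.layers import Conv2d, ReLU, Sigmoid
from .base import SplitSegmentationModel, SplitSpec, register_arch
from .unet import UNetBE, UNetFE, UNetSS


class AttentionGate:
    """Additive channel-spatial attention gate (layer container)."""

    def __init__(self, channels: int, rng, dtype) -> None:
        f_int = max(channels // 2, 1)
        self.layers = {
            "wx": Conv2d(channels, f_int, 1, rng, dtype=dtype),
            "wg": Conv2d(channels, f_int, 1, rng, dtype=dtype),
            "psi": Conv2d(f_int, 1, 1, rng, dtype=dtype),
        }
        self._relu = ReLU()
        self._sig = Sigmoid()

    def forward(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        a = self._relu.forward(self.layers["wx"].forward(x) + self.layers["wg"].forward(g))
        self._alpha = self._sig.forward(self.layers["psi"].forward(a))
        self._x = x
        return x * self._alpha

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (grad wrt skip x, grad wrt gating signal g)."""
        gx_direct = gy * self._alpha
        galpha = (gy * self._x).sum(axis=1, keepdims=True)
        ga = self.layers["psi"].backward(self._sig.backward(galpha))
        gpre = self._relu.backward(ga)
        gx = gx_direct + self.layers["wx"].backward(gpre)
        gg = self.layers["wg"].backward(gpre)
        return gx, gg

    def zero_grad(self) -> None:
        for lay in self.layers.values():
            lay.zero_grad()


@register_arch("attention_unet")
def build_attention_unet(num_classes, base_width, in_channels, rng, dtype) -> SplitSegmentationModel:
    gate = lambda ch, r, dt: AttentionGate(ch, r, dt)  # noqa: E731
    fe = UNetFE(in_channels, base_width, rng, dtype)
    ss = UNetSS(base_width, rng, dtype, gate_factory=gate)
    be = UNetBE(base_width, num_classes, rng, dtype, gate_factory=gate)
    spec = SplitSpec(
        arch_name="attention_unet",
        cut_after_fe=2,
        cut_before_be=20,
        side_channel_routes=[("FE", "BE", "skip1")],
    )
    return SplitSegmentationModel(fe, ss, be, spec, num_classes, base_width, pool_factor=16)
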