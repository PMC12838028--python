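"""Convolutional layers with explicit forward/backward passes.

Implementation notes:

* Convolutions loop over the (small) kernel footprint and dispatch each tap
  to a BLAS ``tensordot``; this avoids materialising an im2col buffer and is
  fast enough for the desk-scale networks trained here.
* Each layer caches what its own backward pass needs on the instance, so a
  backward call must follow the matching forward call (the training loops
  guarantee this).
* Gradients accumulate into ``layer.grads`` so a split network can run its
  three stages separately and still end up with a complete gradient set.
"""

from __future__ import annotations

import numpy as np


class MacRecorder:
    """Collects multiply-accumulate counts while a probe forward pass runs."""

    def __init__(self) -> None:
        self.active = False
        self.records: list[tuple[str, int]] = []

    def start(self) -> None:
        self.active = True
        self.records = []

    def stop(self) -> int:
        self.active = False
        return self.total

    @property
    def total(self) -> int:
        return int(sum(m for _, m in self.records))

    def add(self, name: str, macs: int) -> None:
        self.records.append((name, int(macs)))


#: Global recorder used by :mod:`medsegsplit.complexity`.
mac_recorder = MacRecorder()


class Layer:
    """Base class: owns parameters and their gradients as ndarray dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    lim = float(np.sqrt(1.0 / fan_in))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class Conv2d(Layer):
    """2-D convolution with stride, zero padding, dilation and groups."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.params["w"] = _uniform_fan_in(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in, dtype
        )
        if bias:
            self.params["b"] = _uniform_fan_in(rng, (out_channels,), fan_in, dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x_padded: np.ndarray | None = None

    def _out_hw(self, H: int, W: int) -> tuple[int, int]:
        span = self.dilation * (self.k - 1) + 1
        Ho = (H + 2 * self.padding - span) // self.stride + 1
        Wo = (W + 2 * self.padding - span) // self.stride + 1
        return Ho, Wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, s, d, g, k = self.padding, self.stride, self.dilation, self.groups, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        N = x.shape[0]
        Ho, Wo = self._out_hw(x.shape[2], x.shape[3])
        if Ho <= 0 or Wo <= 0:
            raise ValueError("input too small for kernel/dilation")
        w = self.params["w"]
        y = np.zeros((N, self.cout, Ho, Wo), dtype=w.dtype)
        for a in range(k):
            for b in range(k):
                x_sl = xp[:, :, a * d : a * d + s * Ho : s, b * d : b * d + s * Wo : s]
                w_ab = w[:, :, a, b]
                if g == 1:
                    y += np.tensordot(x_sl, w_ab, axes=([1], [1])).transpose(0, 3, 1, 2)
                elif g == self.cin and self.cout == self.cin:
                    y += w_ab[:, 0][None, :, None, None] * x_sl
                else:
                    cig, cog = self.cin // g, self.cout // g
                    for gi in range(g):
                        y[:, gi * cog : (gi + 1) * cog] += np.tensordot(
                            x_sl[:, gi * cig : (gi + 1) * cig],
                            w_ab[gi * cog : (gi + 1) * cog],
                            axes=([1], [1]),
                        ).transpose(0, 3, 1, 2)
        if "b" in self.params:
            y += self.params["b"][None, :, None, None]
        if mac_recorder.active:
            mac_recorder.add(
                f"conv{k}x{k}_{self.cin}to{self.cout}",
                k * k * (self.cin // g) * self.cout * Ho * Wo,
            )
        self._x_padded = xp
        self._in_shape = x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._x_padded is None:
            raise RuntimeError("backward called before forward")
        p, s, d, g, k = self.padding, self.stride, self.dilation, self.groups, self.k
        xp, w = self._x_padded, self.params["w"]
        Ho, Wo = gy.shape[2], gy.shape[3]
        dxp = np.zeros_like(xp)
        dw = self.grads["w"]
        for a in range(k):
            for b in range(k):
                hs = slice(a * d, a * d + s * Ho, s)
                ws = slice(b * d, b * d + s * Wo, s)
                x_sl = xp[:, :, hs, ws]
                w_ab = w[:, :, a, b]
                if g == 1:
                    dw[:, :, a, b] += np.tensordot(gy, x_sl, axes=([0, 2, 3], [0, 2, 3]))
                    dxp[:, :, hs, ws] += np.tensordot(
                        gy, w_ab, axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
                elif g == self.cin and self.cout == self.cin:
                    dw[:, 0, a, b] += (gy * x_sl).sum(axis=(0, 2, 3))
                    dxp[:, :, hs, ws] += w_ab[:, 0][None, :, None, None] * gy
                else:
                    cig, cog = self.cin // g, self.cout // g
                    for gi in range(g):
                        gys = gy[:, gi * cog : (gi + 1) * cog]
                        xs = x_sl[:, gi * cig : (gi + 1) * cig]
                        dw[gi * cog : (gi + 1) * cog, :, a, b] += np.tensordot(
                            gys, xs, axes=([0, 2, 3], [0, 2, 3])
                        )
                        dxp[:, gi * cig : (gi + 1) * cig, hs, ws] += np.tensordot(
                            gys, w_ab[gi * cog : (gi + 1) * cog], axes=([1], [0])
                        ).transpose(0, 3, 1, 2)
        if "b" in self.params:
            self.grads["b"] += gy.sum(axis=(0, 2, 3))
        self._x_padded = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2d(Layer):
    """Transpose (fractionally strided) convolution, zero output padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        bias: bool = True,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.stride = in_channels, out_channels, kernel_size, stride
        fan_in = in_channels * kernel_size * kernel_size
        self.params["w"] = _uniform_fan_in(
            rng, (in_channels, out_channels, kernel_size, kernel_size), fan_in, dtype
        )
        if bias:
            self.params["b"] = _uniform_fan_in(rng, (out_channels,), fan_in, dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, w = self.k, self.stride, self.params["w"]
        N, _, H, W = x.shape
        Ho, Wo = (H - 1) * s + k, (W - 1) * s + k
        y = np.zeros((N, self.cout, Ho, Wo), dtype=w.dtype)
        for a in range(k):
            for b in range(k):
                y[:, :, a : a + s * H : s, b : b + s * W : s] += np.tensordot(
                    x, w[:, :, a, b], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        if "b" in self.params:
            y += self.params["b"][None, :, None, None]
        if mac_recorder.active:
            mac_recorder.add(
                f"convT{k}x{k}_{self.cin}to{self.cout}",
                k * k * self.cin * self.cout * H * W,
            )
        self._x = x
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before forward")
        k, s, x, w = self.k, self.stride, self._x, self.params["w"]
        H, W = x.shape[2], x.shape[3]
        dx = np.zeros_like(x)
        for a in range(k):
            for b in range(k):
                gy_sl = gy[:, :, a : a + s * H : s, b : b + s * W : s]
                dx += np.tensordot(gy_sl, w[:, :, a, b], axes=([1], [1])).transpose(0, 3, 1, 2)
                self.grads["w"][:, :, a, b] += np.tensordot(
                    x, gy_sl, axes=([0, 2, 3], [0, 2, 3])
                )
        if "b" in self.params:
            self.grads["b"] += gy.sum(axis=(0, 2, 3))
        self._x = None
        return dx


def _pool_view(x: np.ndarray) -> np.ndarray:
    N, C, H, W = x.shape
    return x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, H // 2, W // 2, 4
    )


def max_pool2x2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2/stride-2 max pooling. Returns (pooled, argmax in {0..3})."""
    if x.shape[2] % 2 or x.shape[3] % 2:
        raise ValueError("spatial size must be even for 2x2 pooling")
    v = _pool_view(x)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    return out, idx.astype(np.int8)

def max_unpool2d(y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Place each pooled value back at its recorded argmax; zeros elsewhere."""
    N, C, Hh, Wh = y.shape
    v = np.zeros((N, C, Hh, Wh, 4), dtype=y.dtype)
    np.put_along_axis(v, idx[..., None].astype(np.intp), y[..., None], axis=-1)
    return v.reshape(N, C, Hh, Wh, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, 2 * Hh, 2 * Wh
    )


def unpool_backward(gy_full: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Gradient of max_unpool2d w.r.t. its pooled input (a gather)."""
    v = _pool_view(gy_full)
    return np.take_along_axis(v, idx[..., None].astype(np.intp), axis=-1)[..., 0]


class MaxPool2d(Layer):
    """2x2 max pooling that remembers argmax indices for unpooling."""

    def __init__(self) -> None:
        super().__init__()
        self.indices: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, self.indices = max_pool2x2(x)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.indices is None:
            raise RuntimeError("backward called before forward")
        return max_unpool2d(gy, self.indices)


class MaxUnpool2d(Layer):
    """Unpooling driven by externally supplied argmax indices."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None

    def forward(self, x: np.ndarray, idx: np.ndarray) -> np.ndarray:  # type: ignore[override]
        self._idx = idx
        return max_unpool2d(x, idx)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._idx is None:
            raise RuntimeError("backward called before forward")
        return unpool_backward(gy, self._idx)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._y * (1.0 - self._y)


class NearestUpsample(Layer):
    """Parameter-free nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        f = self.factor
        N, C, H, W = gy.shape
        return gy.reshape(N, C, H // f, f, W // f, f).sum(axis=(3, 5))


class Sequential(Layer):
    """Chain of layers; parameters are exposed under positional names."""

    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for lay in self.layers:
            lay.zero_grad()
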