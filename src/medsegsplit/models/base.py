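"""Split segmentation models: FE / SS / BE sub-models and their contracts.

A split segmentation network is partitioned into three sub-models:

* **FE** (front end, client side) — the only part that sees raw images.
  Its output packet carries the boundary feature map (sent to the server)
  plus *side tensors* (skip features, pooling indices) that are retained on
  the client and handed directly to BE.
* **SS** (server side) — the bulk of the network.  It consumes the FE
  boundary feature map only; side tensors never transit the server.
* **BE** (back end, client side) — the only part that sees ground-truth
  labels.  It produces logits, starts backpropagation, and relays the
  boundary gradient back through SS to FE.

The monolithic "assembled" view composes the same three sub-models (shared
parameter storage) into a plain forward/backward pair; it backs the
centralized training mode and the split-equivalence tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterator

import numpy as np

from ..nn.layers import Layer


class SubModelRole(str, Enum):
    FE = "FE"
    SS = "SS"
    BE = "BE"


@dataclass
class SplitSpec:
    """Where a network is cut and how side tensors are routed.

    ``side_channel_routes`` lists ``(producer_role, consumer_role, name)``
    triples.  Any tensor produced by FE and consumed by BE is routed on the
    client, never through the server.
    """

    arch_name: str
    cut_after_fe: int
    cut_before_be: int
    side_channel_routes: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cut_after_fe < self.cut_before_be:
            raise ValueError("FE/SS cut must precede SS/BE cut")
        for producer, consumer, _name in self.side_channel_routes:
            if producer == "FE" and consumer == "SS":
                raise ValueError("FE side tensors must not be consumed by SS")


@dataclass
class ActivationPacket:
    """Data crossing a split boundary: main feature map + named side tensors."""

    main: np.ndarray
    side: dict[str, np.ndarray] = field(default_factory=dict)

    def meta(self) -> dict[str, tuple[tuple[int, ...], str]]:
        out = {"main": (tuple(self.main.shape), str(self.main.dtype))}
        for k, v in self.side.items():
            out[k] = (tuple(v.shape), str(v.dtype))
        return out


def _flatten(prefix: str, layer) -> Iterator[tuple[str, Layer]]:
    """Yield (name, leaf layer) pairs, descending into containers."""
    sub = getattr(layer, "layers", None)
    if sub is None:
        yield prefix, layer
    else:
        it = sub.items() if isinstance(sub, dict) else enumerate(sub)
        for key, child in it:
            yield from _flatten(f"{prefix}.{key}", child)


class SubModel:
    """One of the three roles: a named registry of layers with a flat
    parameter namespace, so federated averaging can treat a sub-model as a
    plain ``{name: array}`` collection."""

    role: str = "?"

    def __init__(self) -> None:
        self._registry: dict[str, object] = {}

    def add(self, name: str, layer):
        self._registry[name] = layer
        return layer

    def _leaves(self) -> Iterator[tuple[str, Layer]]:
        for name, layer in self._registry.items():
            yield from _flatten(name, layer)

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": arr
            for name, leaf in self._leaves()
            for k, arr in leaf.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": arr
            for name, leaf in self._leaves()
            for k, arr in leaf.grads.items()
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(params) != set(state):
            raise ValueError(f"{self.role} parameter structure mismatch")
        for k, v in state.items():
            params[k][...] = v

    def zero_grad(self) -> None:
        for _, leaf in self._leaves():
            leaf.zero_grad()

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters().values()))


class FESubModel(SubModel):
    role = "FE"

    def forward(self, x: np.ndarray) -> ActivationPacket:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gmain: np.ndarray, gside: dict[str, np.ndarray]) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover


class SSSubModel(SubModel):
    role = "SS"

    def forward(self, main: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gmain: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BESubModel(SubModel):
    role = "BE"

    def forward(self, main: np.ndarray, side: dict[str, np.ndarray]) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover

    def backward(self, glogits: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        raise NotImplementedError  # pragma: no cover


class SplitSegmentationModel:
    """A segmentation network realized as composable FE/SS/BE sub-models."""

    def __init__(
        self,
        fe: FESubModel,
        ss: SSSubModel,
        be: BESubModel,
        spec: SplitSpec,
        num_classes: int,
        base_width: int,
        pool_factor: int,
    ) -> None:
        self.fe, self.ss, self.be = fe, ss, be
        self.spec = spec
        self.num_classes = num_classes
        self.base_width = base_width
        self.pool_factor = pool_factor
        self._forward_cached = False
        self.last_packets: tuple[ActivationPacket, ActivationPacket] | None = None
        self.last_grad_packets: tuple[ActivationPacket, ActivationPacket] | None = None

    # -- role-wise parameter access -------------------------------------
    def role_parameters(self) -> dict[str, dict[str, np.ndarray]]:
        return {
            "FE": self.fe.parameters(),
            "SS": self.ss.parameters(),
            "BE": self.be.parameters(),
        }

    def all_parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{role}/{k}": v
            for role, params in self.role_parameters().items()
            for k, v in params.items()
        }

    def all_gradients(self) -> dict[str, np.ndarray]:
        grads = {"FE": self.fe.gradients(), "SS": self.ss.gradients(), "BE": self.be.gradients()}
        return {f"{role}/{k}": v for role, g in grads.items() for k, v in g.items()}

    def state_dict(self) -> dict[str, dict[str, np.ndarray]]:
        return {
            "FE": self.fe.state_dict(),
            "SS": self.ss.state_dict(),
            "BE": self.be.state_dict(),
        }

    def load_state_dict(self, state: dict[str, dict[str, np.ndarray]]) -> None:
        self.fe.load_state_dict(state["FE"])
        self.ss.load_state_dict(state["SS"])
        self.be.load_state_dict(state["BE"])

    def zero_grad(self) -> None:
        for sub in (self.fe, self.ss, self.be):
            sub.zero_grad()

    # -- split execution --------------------------------------------------
    def validate_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != getattr(self.fe, "in_channels", x.shape[1]):
            raise ValueError("expected an image batch of shape (N, C, H, W)")
        if x.shape[2] % self.pool_factor or x.shape[3] % self.pool_factor:
            raise ValueError(
                f"{self.spec.arch_name}: spatial size {x.shape[2]}x{x.shape[3]} is not "
                f"divisible by the pooling factor {self.pool_factor}"
            )

    def forward_split(
        self, x: np.ndarray
    ) -> tuple[np.ndarray, tuple[ActivationPacket, ActivationPacket]]:
        self.validate_input(x)
        fe_pkt = self.fe.forward(x)
        ss_out = self.ss.forward(fe_pkt.main)
        ss_pkt = ActivationPacket(main=ss_out)
        logits = self.be.forward(ss_pkt.main, fe_pkt.side)
        self.last_packets = (fe_pkt, ss_pkt)
        self._forward_cached = True
        return logits, (fe_pkt, ss_pkt)

    def backward_relay(self, glogits: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Three-stage gradient relay: BE, then SS, then FE (with client-side
        side-tensor gradients).  Returns fresh per-role gradient dicts."""
        if not self._forward_cached:
            raise RuntimeError("backward_relay called without a cached forward_split")
        self.zero_grad()
        gmain_ss, gside = self.be.backward(glogits)
        gmain_fe = self.ss.backward(gmain_ss)
        self.fe.backward(gmain_fe, gside)
        self.last_grad_packets = (
            ActivationPacket(main=gmain_fe, side=gside),
            ActivationPacket(main=gmain_ss),
        )
        self._forward_cached = False
        return {
            "FE": self.fe.gradients(),
            "SS": self.ss.gradients(),
            "BE": self.be.gradients(),
        }


class AssembledModel:
    """Monolithic view of a split model; shares its parameter storage."""

    def __init__(self, model: SplitSegmentationModel) -> None:
        self.model = model
        self._cached = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        m = self.model
        m.validate_input(x)
        fe_pkt = m.fe.forward(x)
        ss_out = m.ss.forward(fe_pkt.main)
        logits = m.be.forward(ss_out, fe_pkt.side)
        self._cached = True
        return logits

    __call__ = forward

    def backward(self, glogits: np.ndarray) -> dict[str, np.ndarray]:
        if not self._cached:
            raise RuntimeError("backward called before forward")
        m = self.model
        m.zero_grad()
        gmain_ss, gside = m.be.backward(glogits)
        gmain_fe = m.ss.backward(gmain_ss)
        m.fe.backward(gmain_fe, gside)
        self._cached = False
        return m.all_gradients()

    def parameters(self) -> dict[str, np.ndarray]:
        return self.model.all_parameters()


def assemble(model: SplitSegmentationModel) -> AssembledModel:
    return AssembledModel(model)


#: registry filled by the architecture modules
ARCH_BUILDERS: dict[str, Callable[..., SplitSegmentationModel]] = {}


def register_arch(name: str):
    def deco(fn):
        ARCH_BUILDERS[name] = fn
        return fn

    return deco


def build_model(
    arch_name: str,
    num_classes: int,
    base_width: int,
    in_channels: int = 3,
    seed: int = 0,
    dtype=np.float32,
) -> SplitSegmentationModel:
    """Build a split segmentation network with its pinned cut points.

    Parameters are initialised with a seeded uniform fan-in scheme, so two
    calls with the same arguments produce bit-identical models.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if base_width < 1:
        raise ValueError("base_width must be >= 1")
    try:
        builder = ARCH_BUILDERS[arch_name]
    except KeyError:
        raise ValueError(
            f"unknown architecture {arch_name!r}; available: {sorted(ARCH_BUILDERS)}"
        ) from None
    rng = np.random.default_rng(seed)
    return builder(num_classes, base_width, in_channels, rng, dtype)
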