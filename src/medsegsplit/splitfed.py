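"""SplitFed orchestration plus the centralized and local-only baselines.

One process simulates every client and the server.  A global round is:

1. every client loads the current global weights (FE/BE, plus the server's
   per-client SS copy),
2. trains locally for ``local_epochs`` epochs of forward-split -> Soft Dice
   -> backward-relay -> a simultaneous optimizer step on FE, SS copy and BE,
3. the server federated-averages the client FE and BE weight sets (and the
   SS copies, unless ``aggregate_ss`` is off) and broadcasts the result.

Optimizer state is reset at each broadcast by default: aggregated weights
invalidate per-client Adam moments.

Reproducibility: the shuffle for client ``c`` in global epoch ``e`` is
seeded with ``(seed, c, e)``, and the centralized loop uses the same
scheme with ``c = 0``.  With a single client, ``aggregate_ss=True`` and a
matching optimizer-reset policy, SplitFed therefore reproduces centralized
training of the same model bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .metrics import TASK_NUM_CLASSES, average_iou, one_hot, soft_dice_with_logits
from .models import SplitSegmentationModel, assemble
from .nn.optim import make_optimizer
from .synthetic_data import to_arrays


@dataclass
class FederationConfig:
    n_clients: int
    global_rounds: int = 10
    local_epochs: int = 12
    centralized_epochs: int = 120
    batch_size: int = 4
    learning_rate: float = 1e-3
    aggregation_weighting: str = "by_train_size"  # or "uniform"
    aggregate_ss: bool = True
    optimizer: str = "adam"
    reset_optimizer_each_round: bool = True
    smooth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clients < 1 or self.global_rounds < 1 or self.centralized_epochs < 1:
            raise ValueError("client, round and epoch counts must be >= 1")
        if self.local_epochs < 0:
            raise ValueError("local_epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.aggregation_weighting not in ("by_train_size", "uniform"):
            raise ValueError("aggregation_weighting must be by_train_size or uniform")


@dataclass
class RoundResult:
    round_index: int
    client_train_loss: list[float]
    client_val_iou: list[float]
    param_digest: str = ""
    client_digests: list[str] = field(default_factory=list)


def fedavg(
    weight_sets: list[dict[str, np.ndarray]], mix_weights
) -> dict[str, np.ndarray]:
    """Elementwise convex combination of parameter collections.

    Accumulates in float64 and casts back, so averaging identical sets is
    an exact fixed point for float32 parameters.
    """
    if not weight_sets:
        raise ValueError("no weight sets to aggregate")
    mix = np.asarray(mix_weights, dtype=np.float64)
    if len(mix) != len(weight_sets) or np.any(mix < 0):
        raise ValueError("mix_weights must be non-negative, one per weight set")
    total = mix.sum()
    if total <= 0:
        raise ValueError("mix_weights must sum to a positive value")
    alpha = mix / total
    keys = set(weight_sets[0])
    for ws in weight_sets[1:]:
        if set(ws) != keys:
            raise ValueError("weight sets have mismatched structure")
    out: dict[str, np.ndarray] = {}
    for k in weight_sets[0]:
        shapes = {ws[k].shape for ws in weight_sets}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch for parameter {k!r}")
        acc = np.zeros(weight_sets[0][k].shape, dtype=np.float64)
        for a, ws in zip(alpha, weight_sets):
            acc += a * ws[k]
        out[k] = acc.astype(weight_sets[0][k].dtype)
    return out


def _digest(state: dict[str, dict[str, np.ndarray]]) -> str:
    h = hashlib.sha256()
    for role in ("FE", "SS", "BE"):
        for k in sorted(state[role]):
            h.update(state[role][k].tobytes())
    return h.hexdigest()


def _train_one_epoch(
    model: SplitSegmentationModel,
    images: np.ndarray,
    masks_onehot: np.ndarray,
    optimizer,
    config: FederationConfig,
    rng: np.random.Generator,
) -> float:
    n = images.shape[0]
    order = rng.permutation(n)
    losses = []
    for at in range(0, n, config.batch_size):
        idx = order[at : at + config.batch_size]
        logits, _ = model.forward_split(images[idx])
        loss, dz = soft_dice_with_logits(
            logits, masks_onehot[idx].astype(logits.dtype), config.smooth
        )
        model.backward_relay(dz)
        optimizer.step(model.all_gradients())
        losses.append(loss)
    return float(np.mean(losses))


def run_local_round(
    model: SplitSegmentationModel,
    train_samples,
    config: FederationConfig,
    round_index: int = 0,
    client_index: int = 0,
    optimizer=None,
):
    """One client's local training for ``config.local_epochs`` epochs.

    Updates the model in place; returns (model, per-epoch mean losses).
    """
    if not train_samples:
        raise ValueError("client has no training samples")
    images, masks = to_arrays(train_samples)
    onehot = one_hot(masks, model.num_classes)
    if optimizer is None:
        optimizer = make_optimizer(
            config.optimizer, model.all_parameters(), config.learning_rate
        )
    losses = []
    for e in range(config.local_epochs):
        epoch_index = round_index * config.local_epochs + e
        rng = np.random.default_rng([config.seed, client_index, epoch_index])
        losses.append(_train_one_epoch(model, images, onehot, optimizer, config, rng))
    return model, losses


def evaluate_model(
    model: SplitSegmentationModel,
    samples,
    task_kind: str,
    batch_size: int = 8,
    include_background: bool = False,
) -> float:
    """Average IoU of argmax predictions on a sample list."""
    if not samples:
        raise ValueError("no samples to evaluate")
    images, masks = to_arrays(samples)
    mono = assemble(model)
    pairs = []
    for at in range(0, images.shape[0], batch_size):
        logits = mono.forward(images[at : at + batch_size])
        preds = logits.argmax(axis=1)
        pairs.extend(zip(preds, masks[at : at + batch_size]))
    return average_iou(pairs, task_kind, include_background)


def _as_train_val(shard):
    if isinstance(shard, tuple):
        return shard
    return shard, []


def run_splitfed(
    model_factory,
    client_shards,
    config: FederationConfig,
    task_kind: str | None = None,
):
    """Full SplitFed training; returns (global model, per-round history).

    ``client_shards`` is one entry per client: either a list of training
    samples or a ``(train_samples, val_samples)`` tuple.
    """
    shards = [_as_train_val(s) for s in client_shards]
    if len(shards) != config.n_clients:
        raise ValueError("number of shards must equal n_clients")
    if not any(len(tr) for tr, _ in shards):
        raise ValueError("no client has training data")
    global_model = model_factory(config.seed)
    client_models = [model_factory(config.seed) for _ in shards]
    global_state = global_model.state_dict()
    ss_copies = [
        {k: v.copy() for k, v in global_state["SS"].items()} for _ in shards
    ]
    persistent_opts: list = [None] * len(shards)
    history: list[RoundResult] = []
    for r in range(config.global_rounds):
        role_states: dict[str, list] = {"FE": [], "SS": [], "BE": []}
        sizes, losses = [], []
        for ci, (train, _val) in enumerate(shards):
            cm = client_models[ci]
            cm.load_state_dict(
                {"FE": global_state["FE"], "SS": ss_copies[ci], "BE": global_state["BE"]}
            )
            if config.reset_optimizer_each_round:
                optimizer = None
            else:
                # parameter arrays persist across load_state_dict (copied in
                # place), so a long-lived optimizer keeps tracking them
                if persistent_opts[ci] is None:
                    persistent_opts[ci] = make_optimizer(
                        config.optimizer, cm.all_parameters(), config.learning_rate
                    )
                optimizer = persistent_opts[ci]
            _, epoch_losses = run_local_round(
                cm, train, config, round_index=r, client_index=ci, optimizer=optimizer
            )
            state = cm.state_dict()
            for role in role_states:
                role_states[role].append(state[role])
            sizes.append(len(train))
            losses.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        mix = sizes if config.aggregation_weighting == "by_train_size" else [1.0] * len(shards)
        global_state["FE"] = fedavg(role_states["FE"], mix)
        global_state["BE"] = fedavg(role_states["BE"], mix)
        if config.aggregate_ss:
            global_state["SS"] = fedavg(role_states["SS"], mix)
            ss_copies = [
                {k: v.copy() for k, v in global_state["SS"].items()} for _ in shards
            ]
        else:
            ss_copies = [role_states["SS"][ci] for ci in range(len(shards))]
        # broadcast for local validation
        val_ious, client_digests = [], []
        for ci, (_train, val) in enumerate(shards):
            cm = client_models[ci]
            cm.load_state_dict(
                {"FE": global_state["FE"], "SS": ss_copies[ci], "BE": global_state["BE"]}
            )
            client_digests.append(_digest(cm.state_dict()))
            if val and task_kind:
                val_ious.append(evaluate_model(cm, val, task_kind))
            else:
                val_ious.append(float("nan"))
        history.append(
            RoundResult(
                round_index=r,
                client_train_loss=losses,
                client_val_iou=val_ious,
                param_digest=_digest(
                    {"FE": global_state["FE"], "SS": global_state["SS"], "BE": global_state["BE"]}
                ),
                client_digests=client_digests,
            )
        )
    global_model.load_state_dict(global_state)
    return global_model, history


def run_centralized(
    model: SplitSegmentationModel,
    samples,
    config: FederationConfig,
    epochs: int | None = None,
    opt_reset_every: int = 0,
):
    """Standard minibatch training of the assembled monolithic model.

    ``opt_reset_every=k`` re-initializes the optimizer every k epochs,
    matching SplitFed's reset-at-broadcast policy when k = local_epochs.
    Returns (model, per-epoch mean losses).
    """
    if not samples:
        raise ValueError("no training data")
    n_epochs = config.centralized_epochs if epochs is None else epochs
    images, masks = to_arrays(samples)
    onehot = one_hot(masks, model.num_classes)
    optimizer = None
    losses = []
    for e in range(n_epochs):
        if optimizer is None or (opt_reset_every and e % opt_reset_every == 0):
            optimizer = make_optimizer(
                config.optimizer, model.all_parameters(), config.learning_rate
            )
        rng = np.random.default_rng([config.seed, 0, e])
        losses.append(_train_one_epoch(model, images, onehot, optimizer, config, rng))
    return model, losses


def run_local_only(
    model_factory,
    client_shards,
    test_samples,
    config: FederationConfig,
    task_kind: str,
):
    """Independent centralized training per client; reports per-client and
    mean test average IoU.  Returns (models, per-client IoUs, mean IoU)."""
    shards = [_as_train_val(s)[0] for s in client_shards]
    if any(not s for s in shards):
        raise ValueError("every client needs at least one training sample")
    models, ious = [], []
    for _ci, train in enumerate(shards):
        m = model_factory(config.seed)
        run_centralized(m, train, config)
        models.append(m)
        ious.append(evaluate_model(m, test_samples, task_kind))
    return models, ious, float(np.mean(ious))


def num_classes_for(task_kind: str) -> int:
    return TASK_NUM_CLASSES[task_kind]
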