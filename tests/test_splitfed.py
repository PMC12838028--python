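import numpy as np
import pytest

from medsegsplit.models import assemble, build_model
from medsegsplit.metrics import one_hot, soft_dice_with_logits
from medsegsplit.splitfed import (
    FederationConfig,
    evaluate_model,
    fedavg,
    run_centralized,
    run_local_only,
    run_local_round,
    run_splitfed,
)
from medsegsplit.synthetic_data import SyntheticTaskSpec, generate_dataset, to_arrays


def _cfg(**kw):
    base = dict(n_clients=1, global_rounds=2, local_epochs=1, centralized_epochs=2,
                batch_size=4, learning_rate=1e-3, seed=0)
    base.update(kw)
    return FederationConfig(**base)


# ---------------------------------------------------------------- fedavg
def test_fedavg_identical_sets_is_an_exact_fixed_point(rng):
    ws = {"a": rng.normal(size=(3, 3)).astype(np.float32), "b": rng.normal(size=5).astype(np.float32)}
    out = fedavg([ws, {k: v.copy() for k, v in ws.items()}, ws], [0.2, 5.0, 1.3])
    for k in ws:
        np.testing.assert_array_equal(out[k], ws[k])


def test_fedavg_weighted_mean_on_hand_values():
    out = fedavg([{"p": np.array([0.0])}, {"p": np.array([1.0])}], [1, 3])
    np.testing.assert_allclose(out["p"], [0.75])


def test_fedavg_uniform_mix_is_order_invariant_mean(rng):
    sets = [{"p": rng.normal(size=4)} for _ in range(5)]
    out = fedavg(sets, [1] * 5)
    np.testing.assert_allclose(out["p"], np.mean([s["p"] for s in sets], axis=0), rtol=1e-12)
    out_rev = fedavg(sets[::-1], [1] * 5)
    np.testing.assert_allclose(out["p"], out_rev["p"], rtol=1e-12)


def test_fedavg_output_lies_in_the_convex_envelope(rng):
    sets = [{"p": rng.normal(size=(6, 6))} for _ in range(4)]
    mix = rng.uniform(0.1, 2.0, size=4)
    out = fedavg(sets, mix)
    stack = np.stack([s["p"] for s in sets])
    assert np.all(out["p"] >= stack.min(axis=0) - 1e-12)
    assert np.all(out["p"] <= stack.max(axis=0) + 1e-12)


def test_fedavg_rejects_bad_inputs(rng):
    good = {"p": np.zeros(3)}
    with pytest.raises(ValueError, match="structure"):
        fedavg([good, {"q": np.zeros(3)}], [1, 1])
    with pytest.raises(ValueError, match="positive"):
        fedavg([good, good], [0, 0])


# ------------------------------------------------------------ local round
def test_local_round_zero_epochs_leaves_parameters_untouched(multiclass_samples, tiny_unet):
    before = {k: v.copy() for k, v in tiny_unet.all_parameters().items()}
    run_local_round(tiny_unet, multiclass_samples[:4], _cfg(local_epochs=0))
    for k, v in tiny_unet.all_parameters().items():
        np.testing.assert_array_equal(v, before[k])


def test_one_sgd_epoch_equals_manual_gradient_step(multiclass_samples):
    """One epoch, one full batch, plain gradient descent: parameters move by
    exactly -lr * g where g comes from monolithic autodiff on a copy."""
    samples = multiclass_samples[:3]
    lr = 0.05
    model = build_model("unet", num_classes=5, base_width=4, seed=1)
    oracle = build_model("unet", num_classes=5, base_width=4, seed=1)

    images, masks = to_arrays(samples)
    order = np.random.default_rng([0, 0, 0]).permutation(3)  # the engine's epoch shuffle
    mono = assemble(oracle)
    logits = mono.forward(images[order])
    _, dz = soft_dice_with_logits(logits, one_hot(masks[order], 5).astype(logits.dtype))
    grads = mono.backward(dz)
    expected = {
        k: v - np.float32(lr) * grads[k] for k, v in oracle.all_parameters().items()
    }

    cfg = _cfg(local_epochs=1, batch_size=3, learning_rate=lr, optimizer="sgd")
    run_local_round(model, samples, cfg)
    for k, v in model.all_parameters().items():
        np.testing.assert_array_equal(v, expected[k])


def test_local_round_rejects_empty_shard(tiny_unet):
    with pytest.raises(ValueError, match="no training samples"):
        run_local_round(tiny_unet, [], _cfg())


# ------------------------------------------------------------- centralized
def test_centralized_zero_epochs_is_identity(multiclass_samples, tiny_unet):
    before = {k: v.copy() for k, v in tiny_unet.all_parameters().items()}
    run_centralized(tiny_unet, multiclass_samples[:4], _cfg(), epochs=0)
    for k, v in tiny_unet.all_parameters().items():
        np.testing.assert_array_equal(v, before[k])


def test_centralized_is_bit_deterministic(multiclass_samples):
    outs = []
    for _ in range(2):
        m = build_model("unet", num_classes=5, base_width=4, seed=3)
        _, losses = run_centralized(m, multiclass_samples[:4], _cfg(seed=5), epochs=2)
        outs.append((losses, {k: v.copy() for k, v in m.all_parameters().items()}))
    assert outs[0][0] == outs[1][0]
    for k in outs[0][1]:
        np.testing.assert_array_equal(outs[0][1][k], outs[1][1][k])


def test_centralized_training_reduces_loss_on_clean_data():
    samples = generate_dataset(
        SyntheticTaskSpec("multiclass5", n_samples=5, image_size=64, noise_sd=0.0, seed=4)
    )
    m = build_model("unet", num_classes=5, base_width=4, seed=0)
    _, losses = run_centralized(m, samples, _cfg(batch_size=2, learning_rate=1e-3), epochs=50)
    assert np.all(np.isfinite(losses))
    assert losses[-1] < losses[0]


# ---------------------------------------------------------------- splitfed
def test_splitfed_history_shape_and_broadcast_consistency(multiclass_samples):
    factory = lambda seed: build_model("unet", num_classes=5, base_width=4, seed=seed)  # noqa: E731
    shards = [
        (multiclass_samples[:4], multiclass_samples[4:6]),
        (multiclass_samples[6:10], multiclass_samples[10:12]),
    ]
    cfg = _cfg(n_clients=2, global_rounds=3, local_epochs=1)
    _, history = run_splitfed(factory, shards, cfg, task_kind="multiclass5")
    assert len(history) == 3
    for r, res in enumerate(history):
        assert res.round_index == r
        assert len(res.client_train_loss) == 2
        assert len(res.client_val_iou) == 2
        assert np.all(np.isfinite(res.client_train_loss))
        # post-broadcast client states are identical
        assert len(set(res.client_digests)) == 1
        assert res.client_digests[0] == res.param_digest


def test_single_client_splitfed_equals_centralized(multiclass_samples):
    """Aggregation over one client is the identity, so SplitFed must
    reproduce centralized training of the same seed exactly."""
    samples = multiclass_samples[:6]
    factory = lambda seed: build_model("unet", num_classes=5, base_width=4, seed=seed)  # noqa: E731
    cfg = _cfg(global_rounds=2, local_epochs=2, seed=9)
    sf_model, _ = run_splitfed(factory, [samples], cfg)
    central = factory(cfg.seed)
    run_centralized(central, samples, cfg, epochs=4, opt_reset_every=2)
    for k, v in sf_model.all_parameters().items():
        assert np.abs(v - central.all_parameters()[k]).max() <= 1e-6


def test_splitfed_requires_training_data():
    factory = lambda seed: build_model("unet", num_classes=5, base_width=4, seed=seed)  # noqa: E731
    with pytest.raises(ValueError, match="no client has training data"):
        run_splitfed(factory, [[]], _cfg())


# -------------------------------------------------------------- local-only
def test_local_only_mean_and_single_client_consistency(multiclass_samples):
    factory = lambda seed: build_model("unet", num_classes=5, base_width=4, seed=seed)  # noqa: E731
    shards = [multiclass_samples[:4], multiclass_samples[4:8]]
    test = multiclass_samples[8:]
    cfg = _cfg(n_clients=2, centralized_epochs=1)
    models, ious, mean = run_local_only(factory, shards, test, cfg, "multiclass5")
    assert len(models) == len(ious) == 2
    assert mean == pytest.approx(np.mean(ious))
    # one client reduces to plain centralized training
    solo = factory(cfg.seed)
    run_centralized(solo, shards[0], cfg)
    assert evaluate_model(solo, test, "multiclass5") == pytest.approx(ious[0])


def test_local_only_rejects_empty_client(multiclass_samples):
    factory = lambda seed: build_model("unet", num_classes=5, base_width=4, seed=seed)  # noqa: E731
    with pytest.raises(ValueError, match="at least one training sample"):
        run_local_only(factory, [multiclass_samples[:2], []], multiclass_samples[2:4], _cfg(n_clients=2), "multiclass5")
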