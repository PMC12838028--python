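import numpy as np
import pytest

from medsegsplit.models import CORE_ARCHS, assemble, build_model
from medsegsplit.models.base import SplitSpec


def _rand_batch(rng, n=2, hw=32, dtype=np.float32):
    return rng.normal(size=(n, 3, hw, hw)).astype(dtype)


@pytest.mark.parametrize("arch", CORE_ARCHS)
def test_split_forward_matches_monolithic_assembly(arch, rng):
    model = build_model(arch, num_classes=3, base_width=4, seed=1)
    x = _rand_batch(rng)
    logits, _packets = model.forward_split(x)
    assert logits.shape == (2, 3, 32, 32)
    mono = assemble(model)(x)
    assert np.abs(logits - mono).max() <= 1e-5


@pytest.mark.parametrize("arch", CORE_ARCHS)
def test_backward_relay_matches_monolithic_gradients(arch, rng):
    model = build_model(arch, num_classes=2, base_width=4, seed=2)
    x = _rand_batch(rng)
    logits, _ = model.forward_split(x)
    g = rng.normal(size=logits.shape).astype(np.float32)
    relay = model.backward_relay(g)
    mono = assemble(model)
    mono.forward(x)
    reference = mono.backward(g)
    for role, grads in relay.items():
        for name, val in grads.items():
            ref = reference[f"{role}/{name}"]
            assert np.abs(val - ref).max() <= 1e-5 * max(1.0, np.abs(ref).max()), (
                f"{role}/{name}"
            )


@pytest.mark.parametrize("arch", CORE_ARCHS)
def test_relay_gradients_match_finite_differences(arch):
    """End-to-end independent oracle: median relative error of directional
    finite differences (float64).  The median tolerates the occasional
    probe that lands on a ReLU/max-pool kink."""
    model = build_model(arch, num_classes=2, base_width=4, seed=3, dtype=np.float64)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, 3, 32, 32))
    mono = assemble(model)
    c = rng.normal(size=mono.forward(x).shape)
    mono.forward(x)
    grads = mono.backward(c)
    params = model.all_parameters()
    rels = []
    for name in rng.choice(list(params), size=12, replace=False):
        p = params[name]
        idx = np.unravel_index(rng.integers(p.size), p.shape)
        eps = 1e-6
        orig = p[idx]
        p[idx] = orig + eps
        lp = float((assemble(model).forward(x) * c).sum())
        p[idx] = orig - eps
        lm = float((assemble(model).forward(x) * c).sum())
        p[idx] = orig
        num = (lp - lm) / (2 * eps)
        ana = grads[name][idx]
        rels.append(abs(num - ana) / max(1e-9, abs(num) + abs(ana)))
    assert np.median(rels) < 1e-4, sorted(rels)


@pytest.mark.parametrize("arch", CORE_ARCHS)
def test_parameters_partition_into_roles(arch):
    model = build_model(arch, num_classes=2, base_width=4)
    role_counts = {r: sum(p.size for p in d.values()) for r, d in model.role_parameters().items()}
    assert all(c > 0 for c in role_counts.values())
    assert sum(role_counts.values()) == sum(
        p.size for p in assemble(model).parameters().values()
    )
    # names are disjoint across roles by construction of the flat namespace
    names = list(model.all_parameters())
    assert len(names) == len(set(names))


@pytest.mark.parametrize("arch", CORE_ARCHS)
def test_gradient_shapes_match_parameter_shapes(arch, rng):
    model = build_model(arch, num_classes=2, base_width=4, seed=4)
    x = _rand_batch(rng, n=1)
    logits, _ = model.forward_split(x)
    grads = model.backward_relay(np.ones_like(logits))
    for role, params in model.role_parameters().items():
        assert set(grads[role]) == set(params)
        for name in params:
            assert grads[role][name].shape == params[name].shape


@pytest.mark.parametrize("arch", CORE_ARCHS)
def test_zero_loss_gradient_yields_zero_parameter_gradients(arch, rng):
    model = build_model(arch, num_classes=2, base_width=4, seed=5)
    logits, _ = model.forward_split(_rand_batch(rng, n=1))
    grads = model.backward_relay(np.zeros_like(logits))
    for role_grads in grads.values():
        for g in role_grads.values():
            assert np.all(g == 0.0)


@pytest.mark.parametrize("arch", CORE_ARCHS)
def test_boundary_packets_keep_their_shape_in_the_backward_pass(arch, rng):
    model = build_model(arch, num_classes=2, base_width=4, seed=6)
    logits, (fe_pkt, ss_pkt) = model.forward_split(_rand_batch(rng))
    model.backward_relay(np.ones_like(logits))
    fe_grad, ss_grad = model.last_grad_packets
    assert fe_grad.main.shape == fe_pkt.main.shape
    assert ss_grad.main.shape == ss_pkt.main.shape
    for name, g in fe_grad.side.items():
        assert g.shape == fe_pkt.side[name].shape


@pytest.mark.parametrize("arch", CORE_ARCHS)
def test_forward_is_deterministic(arch, rng):
    x = _rand_batch(rng)
    a = build_model(arch, num_classes=2, base_width=4, seed=7)
    b = build_model(arch, num_classes=2, base_width=4, seed=7)
    np.testing.assert_array_equal(a.forward_split(x)[0], b.forward_split(x)[0])


def test_privacy_partition_fe_side_tensors_never_route_to_ss():
    for arch in CORE_ARCHS:
        spec = build_model(arch, num_classes=2, base_width=4).spec
        assert all(
            not (prod == "FE" and cons == "SS") for prod, cons, _ in spec.side_channel_routes
        )
    with pytest.raises(ValueError, match="must not be consumed by SS"):
        SplitSpec("bad", 1, 2, side_channel_routes=[("FE", "SS", "leak")])


def test_ss_output_is_independent_of_client_side_tensors(rng):
    """The server sub-model's computation depends only on the boundary
    feature map, not on the client-retained skip tensor."""
    model = build_model("unet", num_classes=2, base_width=4, seed=8)
    x = _rand_batch(rng, n=1)
    pkt = model.fe.forward(x)
    out1 = model.ss.forward(pkt.main.copy())
    pkt.side["skip1"][...] += 100.0  # corrupt the client-side tensor
    out2 = model.ss.forward(pkt.main.copy())
    np.testing.assert_array_equal(out1, out2)


def test_pinned_unet_parameter_count_is_7760130():
    model = build_model("unet", num_classes=2, base_width=32)
    assert sum(p.size for p in model.all_parameters().values()) == 7_760_130


def test_cgnet_back_end_holds_the_parameter_majority():
    model = build_model("cgnet", num_classes=2, base_width=16)
    counts = {r: sum(p.size for p in d.values()) for r, d in model.role_parameters().items()}
    assert counts["BE"] > counts["FE"] + counts["SS"]


def test_indivisible_input_size_is_rejected_with_stage_info(rng):
    model = build_model("unet", num_classes=2, base_width=4)
    with pytest.raises(ValueError, match="pooling factor 16"):
        model.forward_split(rng.normal(size=(1, 3, 40, 40)).astype(np.float32))


def test_relay_without_forward_is_a_state_error():
    model = build_model("unet", num_classes=2, base_width=4)
    with pytest.raises(RuntimeError, match="without a cached forward"):
        model.backward_relay(np.zeros((1, 2, 32, 32), dtype=np.float32))


def test_unknown_architecture_rejected():
    with pytest.raises(ValueError, match="unknown architecture"):
        build_model("deeplabv3", num_classes=2, base_width=4)


def test_assembled_model_shares_parameter_storage(rng):
    model = build_model("unet", num_classes=2, base_width=4, seed=9)
    x = _rand_batch(rng, n=1)
    mono = assemble(model)
    before = mono(x).copy()
    fe_params = model.fe.parameters()
    next(iter(fe_params.values()))[...] += 0.5
    after = mono(x)
    assert not np.array_equal(before, after)
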