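"""Network construction, shape inference, topology and gradient tests."""

import numpy as np
import pytest

from tinyweednet import network as nn
from tinyweednet.config import (
    ArchConfig,
    all_variants,
    default_config,
    make_ablation_config,
)
from tinyweednet.network import TensorSpec, assemble_network, infer_shapes

TINY = ArchConfig(stem_channels=4, input_side=32, dropout_p=0.0)


def shapes_as_tuples(config, spec=None):
    return [(name, (s.channels, s.height, s.width))
            for name, s in infer_shapes(config, spec)]


class TestShapeInference:
    def test_reference_schedule(self):
        expected = [
            ("stem", (24, 112, 112)),
            ("msc", (36, 112, 112)),
            ("ir1", (48, 56, 56)),
            ("ir2", (72, 28, 28)),
            ("ir3", (96, 14, 14)),
            ("ir4", (120, 7, 7)),
            ("ir5", (120, 7, 7)),
            ("head_conv", (240, 7, 7)),
            ("gap", (240, 1, 1)),
            ("fc", (9, 1, 1)),
        ]
        assert shapes_as_tuples(default_config()) == expected

    def test_ir5_preserves_spatial_size(self):
        shapes = dict(shapes_as_tuples(default_config()))
        assert shapes["ir5"][1:] == shapes["ir4"][1:]

    def test_double_input_doubles_spatial_only(self):
        base = shapes_as_tuples(default_config())
        big = shapes_as_tuples(default_config(), TensorSpec(3, 448, 448))
        for (name, (c, h, w)), (_, (c2, h2, w2)) in zip(base, big):
            assert c2 == c
            if name in ("gap", "fc"):
                assert (h2, w2) == (h, w) == (1, 1)
            else:
                assert (h2, w2) == (2 * h, 2 * w)

    def test_no_final_projection_skips_head_conv(self):
        names = [n for n, _ in infer_shapes(make_ablation_config("no_final_projection"))]
        assert "head_conv" not in names
        shapes = dict(shapes_as_tuples(make_ablation_config("no_final_projection")))
        assert shapes["gap"][0] == 120  # classifier fed by IR#5 width

    @pytest.mark.parametrize(
        "spec",
        [TensorSpec(3, 24, 24), TensorSpec(3, 64, 32), TensorSpec(1, 64, 64)],
    )
    def test_invalid_inputs_rejected(self, spec):
        with pytest.raises(ValueError):
            infer_shapes(default_config(), spec)


class TestAssembly:
    def test_all_31_variants_assemble(self):
        for cfg in all_variants():
            net = assemble_network(cfg, seed=0)
            assert len(net.ir_blocks) == 5

    def test_seed_determinism_bitwise(self):
        a = assemble_network(TINY, seed=9)
        b = assemble_network(TINY, seed=9)
        for (na, pa), (_, pb) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data), na
        c = assemble_network(TINY, seed=10)
        assert any(
            not np.array_equal(pa.data, pc.data)
            for (_, pa), (_, pc) in zip(a.parameters(), c.parameters())
        )

    def test_exactly_one_residual_edge(self):
        net = assemble_network(default_config(), 0)
        adds = [(stage, s) for stage, s in net.layer_specs() if s.kind == "add"]
        assert [stage for stage, _ in adds] == ["ir5"]
        assert net.ir_blocks[4].residual  # stride 1, 120 -> 120
        assert not net.ir_blocks[0].residual  # stride 2, 36 -> 48

    def test_projection_is_linear_bottleneck(self):
        """No activation between each projection BN and the next stage."""
        net = assemble_network(default_config(), 0)
        for ir in net.ir_blocks:
            kinds = [s.kind for s in ir.specs()]
            i = len(kinds) - 1 - kinds[::-1].index("batch_norm")  # projection BN
            assert kinds[i - 1] == "conv"
            assert "relu" not in kinds[i + 1 :]

    def test_ablation_topologies(self):
        no_ca = assemble_network(make_ablation_config("no_attention"), 0)
        assert all(s.kind != "channel_scale" for _, s in no_ca.layer_specs())
        no_msc = assemble_network(make_ablation_config("no_msc"), 0)
        assert all(s.kind != "concat" for _, s in no_msc.layer_specs())
        no_dw = assemble_network(make_ablation_config("no_depthwise"), 0)
        assert all(s.kind != "depthwise_conv" for _, s in no_dw.layer_specs())


class TestForward:
    def test_deterministic_and_finite(self):
        net = assemble_network(TINY, 3)
        x = np.zeros((1, 3, 32, 32), np.float32)
        y1, y2 = net.forward(x), net.forward(x)
        assert np.isfinite(y1).all()
        assert np.array_equal(y1, y2)
        assert y1.shape == (1, TINY.num_classes)

    def test_batch_independence_in_eval(self):
        net = assemble_network(TINY, 3)
        rng = np.random.default_rng(0)
        x = rng.random((2, 3, 32, 32), dtype=np.float32)
        batched = net.forward(x)
        singles = np.vstack([net.forward(x[i : i + 1]) for i in range(2)])
        np.testing.assert_allclose(batched, singles, atol=1e-5)

    def test_output_width_is_num_classes(self):
        net = assemble_network(default_config(input_side=64), 0)
        y = net.forward(np.zeros((1, 3, 64, 64), np.float32))
        assert y.shape == (1, 9)

    def test_wrong_shape_rejected(self):
        net = assemble_network(TINY, 0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 3, 64, 64), np.float32))


class TestChannelAttention:
    def test_zero_parameters_halve_the_input(self):
        rng = np.random.default_rng(0)
        ca = nn.ChannelAttention(8, 4, rng)
        for _, p in ca.params():
            p.data[:] = 0.0
        x = rng.random((2, 8, 5, 5), dtype=np.float32)
        np.testing.assert_allclose(ca.forward(x), 0.5 * x, rtol=1e-6)

    def test_gate_lies_in_unit_interval(self):
        rng = np.random.default_rng(1)
        ca = nn.ChannelAttention(8, 4, rng)
        x = rng.random((3, 8, 6, 6), dtype=np.float32) + 0.1
        ca.forward(x)
        assert np.all(ca._gate > 0.0) and np.all(ca._gate < 1.0)

    def test_spatially_constant_input_equalizes_paths(self):
        """Constant feature maps give q_avg == q_max, so the two shared-MLP
        paths coincide and the gate uses twice one path's output."""
        rng = np.random.default_rng(2)
        ca = nn.ChannelAttention(6, 2, rng)
        x = np.broadcast_to(
            rng.random((1, 6, 1, 1), dtype=np.float32), (1, 6, 4, 4)
        ).copy()
        q_avg = x.mean(axis=(2, 3))
        q_max = x.max(axis=(2, 3))
        np.testing.assert_allclose(q_avg, q_max, rtol=1e-6)
        out = ca.forward(x)
        assert out.shape == x.shape


def _fd_check(layer, x, train=False, n_probes=6, eps=1e-3, tol=2e-2):
    """Finite-difference check of input and parameter gradients."""
    rng = np.random.default_rng(99)
    y = layer.forward(x, train)
    gy = rng.standard_normal(y.shape).astype(np.float32)
    for _, p in layer.params():
        p.grad[:] = 0.0
    gx = layer.backward(gy)

    def loss():
        return float((layer.forward(x, train) * gy).sum())

    for _ in range(n_probes):
        idx = tuple(rng.integers(s) for s in x.shape)
        xo = float(x[idx])
        x[idx] = xo + eps
        lp = loss()
        x[idx] = xo - eps
        lm = loss()
        x[idx] = xo
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - gx[idx]) <= tol * max(1.0, abs(fd) + abs(gx[idx]))
    for _, p in layer.params():
        for _ in range(2):
            idx = tuple(rng.integers(s) for s in p.data.shape)
            po = float(p.data[idx])
            p.data[idx] = po + eps
            lp = loss()
            p.data[idx] = po - eps
            lm = loss()
            p.data[idx] = po
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - p.grad[idx]) <= tol * max(1.0, abs(fd) + abs(p.grad[idx]))


class TestGradients:
    """Finite-difference validation of every layer family's backward pass."""

    @pytest.fixture
    def rng(self):
        return np.random.default_rng(7)

    @pytest.mark.parametrize(
        "make, shape, train",
        [
            (lambda r: nn.Conv2d(3, 5, 3, 2, 1, rng=r), (2, 3, 8, 8), False),
            (lambda r: nn.Conv2d(4, 6, 1, 1, 0, rng=r), (2, 4, 5, 5), False),
            (lambda r: nn.Conv2d(3, 4, 5, 1, 2, rng=r), (2, 3, 7, 7), False),
            (lambda r: nn.DepthwiseConv2d(4, 3, 1, 1, rng=r), (2, 4, 6, 6), False),
            (lambda r: nn.DepthwiseConv2d(4, 3, 2, 1, rng=r), (2, 4, 8, 8), False),
            (lambda r: nn.GlobalAvgPool(), (2, 4, 5, 5), False),
            (lambda r: nn.GlobalMaxPool(), (2, 4, 5, 5), False),
            (lambda r: nn.Linear(6, 4, r), (3, 6), False),
            (lambda r: nn.ChannelAttention(8, 4, r), (2, 8, 5, 5), False),
        ],
        ids=["conv3x3s2", "conv1x1", "conv5x5", "dw_s1", "dw_s2", "gap", "gmp",
             "linear", "channel_attention"],
    )
    def test_layer_gradients(self, make, shape, train, rng):
        layer = make(rng)
        x = rng.random(shape, dtype=np.float32)
        _fd_check(layer, x, train)

    def test_maxpool_gradient_without_ties(self, rng):
        layer = nn.MaxPool2d(3, 1, 1)
        # well-separated values so the argmax is stable under the probe step
        x = (rng.permutation(2 * 3 * 36).reshape(2, 3, 6, 6) / 10.0).astype(np.float32)
        _fd_check(layer, x, eps=1e-2)

    @pytest.mark.parametrize("mode", ["train", "eval"])
    def test_batchnorm_gradients(self, mode, rng):
        layer = nn.BatchNorm2d(4)
        layer.momentum = 0.0  # freeze running stats so the loss is pure
        x = rng.random((3, 4, 5, 5), dtype=np.float32)
        _fd_check(layer, x, train=mode == "train")

    def test_ir_block_gradients_train_mode(self, rng):
        ir = nn.IRBlock(6, 6, 1, TINY, rng, 1)
        for blk in (ir.expand, ir.dw, ir.project):
            for layer in blk.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    layer.momentum = 0.0
        ir.ca.bn.momentum = 0.0
        x = rng.random((2, 6, 6, 6), dtype=np.float32)
        _fd_check(ir, x, train=True)
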