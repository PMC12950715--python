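"""Exchange-format export and embedded-operator compatibility linting.

The exported artifact is a self-describing JSON graph (text file): an
ordered node list in execution order, an initializer table holding the
weights (float32, base64-encoded), and explicit tensor names for every edge
— the same information an ONNX protobuf carries, in a dependency-free
encoding.  Dropout is stripped (inference graph); batch normalization is
preserved with its running statistics.

A small reference interpreter executes the exported graph with plain numpy
ops, deliberately written independently of the layer implementations in
:mod:`tinyweednet.network`, so a round-trip (export, reload, run) checks the
graph against the native forward pass.

The operator whitelist mirrors what microcontroller inference toolchains
support natively: standard/grouped/depthwise convolution, batch
normalization, ReLU, sigmoid, max and global pooling, fully connected
(Gemm), concat, element-wise add/multiply, and reshape/flatten.
"""

from __future__ import annotations

import base64
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .network import (
    BN_EPS,
    BatchNorm2d,
    ChannelAttention,
    Conv2d,
    DepthwiseConv2d,
    GlobalAvgPool,
    GlobalMaxPool,
    Head,
    IRBlock,
    Linear,
    MaxPool2d,
    MSCBlock,
    ReLU,
    Sigmoid,
    StemBlock,
    TinyWeedNet,
    _Sequential,
)

__all__ = [
    "OPERATOR_WHITELIST",
    "CompatReport",
    "export_graph",
    "load_graph",
    "run_graph",
    "check_operator_whitelist",
]

FORMAT_NAME = "twn-exchange"

OPERATOR_WHITELIST = frozenset(
    {
        "Conv",
        "BatchNormalization",
        "Relu",
        "Sigmoid",
        "MaxPool",
        "AveragePool",
        "GlobalAveragePool",
        "GlobalMaxPool",
        "Gemm",
        "MatMul",
        "Concat",
        "Add",
        "Mul",
        "Flatten",
        "Reshape",
    }
)


@dataclass
class CompatReport:
    """Operator inventory and whitelist violations of an exported graph."""

    inventory: dict[str, int]
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


class _GraphBuilder:
    def __init__(self):
        self.nodes = []
        self.initializers = {}
        self._counter = 0

    def tensor(self, hint="t"):
        self._counter += 1
        return f"{hint}_{self._counter}"

    def add_init(self, name, array):
        self.initializers[name] = np.ascontiguousarray(array, dtype=np.float32)
        return name

    def node(self, op, inputs, attrs=None, name=None):
        out = self.tensor(op.lower())
        self.nodes.append(
            {
                "op": op,
                "name": name or out,
                "inputs": list(inputs),
                "output": out,
                "attrs": attrs or {},
            }
        )
        return out


def _emit_layer(b: _GraphBuilder, layer, x: str, prefix: str) -> str:
    if isinstance(layer, Conv2d):
        w = b.add_init(f"{prefix}.W", layer.W.data)
        inputs = [x, w]
        if layer.b is not None:
            inputs.append(b.add_init(f"{prefix}.b", layer.b.data))
        return b.node(
            "Conv",
            inputs,
            {"kernel": layer.k, "stride": layer.stride, "pad": layer.pad, "group": 1},
            name=prefix,
        )
    if isinstance(layer, DepthwiseConv2d):
        w = b.add_init(f"{prefix}.W", layer.W.data[:, None, :, :])
        return b.node(
            "Conv",
            [x, w],
            {
                "kernel": layer.k,
                "stride": layer.stride,
                "pad": layer.pad,
                "group": layer.c,
            },
            name=prefix,
        )
    if isinstance(layer, BatchNorm2d):
        names = [
            b.add_init(f"{prefix}.gamma", layer.gamma.data),
            b.add_init(f"{prefix}.beta", layer.beta.data),
            b.add_init(f"{prefix}.mean", layer.running_mean),
            b.add_init(f"{prefix}.var", layer.running_var),
        ]
        return b.node(
            "BatchNormalization", [x] + names, {"epsilon": BN_EPS}, name=prefix
        )
    if isinstance(layer, ReLU):
        return b.node("Relu", [x])
    if isinstance(layer, Sigmoid):
        return b.node("Sigmoid", [x])
    if isinstance(layer, MaxPool2d):
        return b.node(
            "MaxPool",
            [x],
            {"kernel": layer.k, "stride": layer.stride, "pad": layer.pad},
        )
    if isinstance(layer, Linear):
        w = b.add_init(f"{prefix}.W", layer.W.data)
        bias = b.add_init(f"{prefix}.b", layer.b.data)
        return b.node("Gemm", [x, w, bias], name=prefix)
    raise TypeError(f"layer kind {type(layer).__name__} cannot be exported")


def _emit_sequential(b, seq: _Sequential, x: str, prefix: str) -> str:
    for i, layer in enumerate(seq.layers):
        x = _emit_layer(b, layer, x, f"{prefix}.{i}")
    return x


def _emit_ca(b, ca: ChannelAttention, x: str, prefix: str) -> str:
    w1 = b.add_init(f"{prefix}.fc1.W", ca.fc1.W.data)
    b1 = b.add_init(f"{prefix}.fc1.b", ca.fc1.b.data)
    bn = [
        b.add_init(f"{prefix}.bn.gamma", ca.bn.gamma.data),
        b.add_init(f"{prefix}.bn.beta", ca.bn.beta.data),
        b.add_init(f"{prefix}.bn.mean", ca.bn.running_mean),
        b.add_init(f"{prefix}.bn.var", ca.bn.running_var),
    ]
    w2 = b.add_init(f"{prefix}.fc2.W", ca.fc2.W.data)
    b2 = b.add_init(f"{prefix}.fc2.b", ca.fc2.b.data)

    paths = []
    for pool_op in ("GlobalAveragePool", "GlobalMaxPool"):
        q = b.node(pool_op, [x])
        z = b.node("Conv", [q, w1, b1], {"kernel": 1, "stride": 1, "pad": 0, "group": 1})
        z = b.node("BatchNormalization", [z] + bn, {"epsilon": BN_EPS})
        z = b.node("Relu", [z])
        z = b.node("Conv", [z, w2, b2], {"kernel": 1, "stride": 1, "pad": 0, "group": 1})
        paths.append(z)
    gate = b.node("Sigmoid", [b.node("Add", paths)])
    return b.node("Mul", [x, gate], name=prefix)


def build_graph_dict(network: TinyWeedNet) -> dict:
    """Serialize the network to the exchange-graph dictionary (eval mode)."""
    b = _GraphBuilder()
    x = "input"
    x = _emit_sequential(b, network.stem.seq, x, "stem")

    msc = network.msc
    if msc.single_branch:
        x = _emit_sequential(b, msc.branches[0], x, "msc.branch0")
    else:
        outs = [
            _emit_sequential(b, branch, x, f"msc.branch{i}")
            for i, branch in enumerate(msc.branches)
        ]
        x = b.node("Concat", outs, {"axis": 1}, name="msc.concat")

    for ir in network.ir_blocks:
        inp = x
        x = _emit_sequential(b, ir.expand, x, f"{ir.name}.expand")
        x = _emit_sequential(b, ir.dw, x, f"{ir.name}.dw")
        if ir.ca is not None:
            x = _emit_ca(b, ir.ca, x, f"{ir.name}.ca")
        x = _emit_sequential(b, ir.project, x, f"{ir.name}.project")
        if ir.residual:
            x = b.node("Add", [inp, x], name=f"{ir.name}.residual")

    head: Head = network.head
    if head.project is not None:
        x = _emit_sequential(b, head.project, x, "head.project")
    x = b.node("GlobalAveragePool", [x])
    x = b.node("Flatten", [x])
    x = b.node("Gemm", [
        x,
        b.add_init("head.fc.W", head.fc.W.data),
        b.add_init("head.fc.b", head.fc.b.data),
    ], name="head.fc")

    side = network.config.input_side
    return {
        "format": FORMAT_NAME,
        "version": 1,
        "input": {"name": "input", "shape": [None, 3, side, side]},
        "initializers": {
            name: {
                "dtype": "float32",
                "shape": list(arr.shape),
                "data_b64": base64.b64encode(arr.tobytes()).decode("ascii"),
            }
            for name, arr in b.initializers.items()
        },
        "nodes": b.nodes,
        "output": x,
    }


def export_graph(network: TinyWeedNet, path: str | Path) -> Path:
    """Write the inference graph (dropout stripped) as a JSON text file."""
    path = Path(path)
    path.write_text(json.dumps(build_graph_dict(network)))
    return path


def load_graph(path: str | Path) -> dict:
    path = Path(path)
    try:
        graph = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise IOError(f"cannot read exchange graph {path}: {exc}") from exc
    if graph.get("format") != FORMAT_NAME:
        raise IOError(f"{path} is not a {FORMAT_NAME} file")
    return graph


# ---------------------------------------------------------------------------
# reference interpreter (independent numpy execution of the exported graph)
# ---------------------------------------------------------------------------


def _decode_initializers(graph: dict) -> dict[str, np.ndarray]:
    out = {}
    for name, spec in graph["initializers"].items():
        arr = np.frombuffer(base64.b64decode(spec["data_b64"]), dtype=np.float32)
        out[name] = arr.reshape(spec["shape"])
    return out


def _ref_conv(x, w, bias, stride, pad, group):
    n, cin = x.shape[:2]
    cout, cpg, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    if group == 1:
        out = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
    elif group == cin and cpg == 1:
        out = np.einsum("nchwij,cij->nchw", win, w[:, 0], optimize=True)
    else:  # grouped conv, block-diagonal weights
        out_groups = []
        for g in range(group):
            xs = win[:, g * cpg : (g + 1) * cpg]
            ws = w[g * (cout // group) : (g + 1) * (cout // group)]
            out_groups.append(np.einsum("nchwij,ocij->nohw", xs, ws, optimize=True))
        out = np.concatenate(out_groups, axis=1)
    if bias is not None:
        out = out + bias[None, :, None, None]
    return out.astype(np.float32)


def run_graph(graph: dict, x: np.ndarray) -> np.ndarray:
    """Execute an exchange graph on an input batch; returns the output tensor."""
    tensors: dict[str, np.ndarray] = {"input": np.asarray(x, dtype=np.float32)}
    weights = _decode_initializers(graph)

    def fetch(name):
        return tensors[name] if name in tensors else weights[name]

    for node in graph["nodes"]:
        op = node["op"]
        ins = node["inputs"]
        attrs = node["attrs"]
        if op == "Conv":
            w = fetch(ins[1])
            bias = fetch(ins[2]) if len(ins) > 2 else None
            y = _ref_conv(
                fetch(ins[0]), w, bias, attrs["stride"], attrs["pad"], attrs["group"]
            )
        elif op == "BatchNormalization":
            xin, gamma, beta, mean, var = (fetch(n) for n in ins)
            shape = (1, -1) + (1,) * (xin.ndim - 2)
            y = (xin - mean.reshape(shape)) / np.sqrt(
                var.reshape(shape) + attrs["epsilon"]
            ) * gamma.reshape(shape) + beta.reshape(shape)
        elif op == "Relu":
            y = np.maximum(fetch(ins[0]), 0.0)
        elif op == "Sigmoid":
            y = 1.0 / (1.0 + np.exp(-fetch(ins[0])))
        elif op == "MaxPool":
            xin = fetch(ins[0])
            k, s, p = attrs["kernel"], attrs["stride"], attrs["pad"]
            if p:
                xin = np.pad(
                    xin,
                    ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf,
                )
            win = sliding_window_view(xin, (k, k), axis=(2, 3))[:, :, ::s, ::s]
            y = win.max(axis=(4, 5))
        elif op == "GlobalAveragePool":
            y = fetch(ins[0]).mean(axis=(2, 3), keepdims=True)
        elif op == "GlobalMaxPool":
            y = fetch(ins[0]).max(axis=(2, 3), keepdims=True)
        elif op == "Concat":
            y = np.concatenate([fetch(n) for n in ins], axis=attrs["axis"])
        elif op == "Add":
            y = fetch(ins[0]) + fetch(ins[1])
        elif op == "Mul":
            y = fetch(ins[0]) * fetch(ins[1])
        elif op == "Flatten":
            xin = fetch(ins[0])
            y = xin.reshape(xin.shape[0], -1)
        elif op == "Gemm":
            y = fetch(ins[0]) @ fetch(ins[1]).T + fetch(ins[2])
        else:
            raise NotImplementedError(f"interpreter does not support op {op!r}")
        tensors[node["output"]] = y.astype(np.float32)
    return tensors[graph["output"]]


def check_operator_whitelist(graph: dict | str | Path) -> CompatReport:
    """Lint an exported graph against the embedded-operator whitelist."""
    if not isinstance(graph, dict):
        graph = load_graph(graph)
    inventory = Counter(node["op"] for node in graph["nodes"])
    violations = [
        (node["op"], node["name"])
        for node in graph["nodes"]
        if node["op"] not in OPERATOR_WHITELIST
    ]
    return CompatReport(inventory=dict(inventory), violations=violations)
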