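"""Exact complexity accounting: parameters, MACC and serialized size.

Two independent routes are provided and must agree exactly:

* :func:`count_parameters` *walks the assembled graph* and sums the sizes of
  the actual weight arrays;
* :func:`closed_form_params` evaluates the per-layer formulas directly from a
  configuration — conv ``k^2*Cin*Cout + Cout``, depthwise ``9*C`` (bias-free),
  BN ``2*C``, channel attention ``2*C*Cr + Cr + C + 2*Cr`` (shared bottleneck
  with biases and a BN on the squeeze), FC ``in*out + out``.

Headline MACC counts convolution and FC multiplies only
(``output elements x k^2 x per-group input channels``); normalization,
activation and pooling element-ops are reported in a separate column and are
an unvalidated approximation of what deployment profilers print.

Model size follows the float32 convention: 4 bytes per parameter, with
MB = 2^20 bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ArchConfig, all_variants
from .network import TensorSpec, TinyWeedNet, infer_shapes

__all__ = [
    "ComplexityReport",
    "count_parameters",
    "closed_form_params",
    "count_macc",
    "grid_report",
    "model_size_mb",
]

BYTES_PER_PARAM = 4  # float32


@dataclass
class ComplexityReport:
    """Per-stage and total complexity of one network variant."""

    per_layer: pd.DataFrame
    total_params: int
    total_macc: int
    model_size_bytes: int

    @property
    def model_size_mb(self) -> float:
        return self.model_size_bytes / 2**20


def model_size_mb(total_params: int) -> float:
    return total_params * BYTES_PER_PARAM / 2**20


def count_parameters(network: TinyWeedNet) -> ComplexityReport:
    """Parameter count by walking the assembled graph's weight arrays."""
    per_stage: dict[str, int] = {}
    for name, p in network.parameters():
        stage = name.split(".", 1)[0]
        per_stage[stage] = per_stage.get(stage, 0) + p.size
    rows = [
        {"stage": stage, "params": count} for stage, count in per_stage.items()
    ]
    df = pd.DataFrame(rows)
    total = int(df["params"].sum())
    return ComplexityReport(
        per_layer=df,
        total_params=total,
        total_macc=0,
        model_size_bytes=total * BYTES_PER_PARAM,
    )


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------


def _conv_params(cin, cout, k, bias=True):
    return k * k * cin * cout + (cout if bias else 0)


def _bn_params(c):
    return 2 * c


def _ca_params(channels, reduction_ratio):
    r = max(1, channels // reduction_ratio)
    squeeze = channels * r + r + _bn_params(r)  # conv1x1 + bias + BN
    excite = r * channels + channels  # conv1x1 + bias
    return squeeze + excite


def closed_form_params(config: ArchConfig, per_stage: bool = False):
    """Total trainable parameters from the per-layer formulas alone."""
    sched = config.schedule
    stages: dict[str, int] = {}

    stages["stem"] = _conv_params(3, sched.stem_out, 3) + _bn_params(sched.stem_out)

    if config.ablation == "no_msc":
        stages["msc"] = _conv_params(sched.stem_out, sched.msc_out, 3) + _bn_params(
            sched.msc_out
        )
    else:
        msc = 0
        for w, k in zip(sched.msc_branch_widths, (1, 3, 5, 1)):
            msc += _conv_params(sched.stem_out, w, k) + _bn_params(w)
        stages["msc"] = msc

    cin = sched.msc_out
    for i, cout in enumerate(sched.ir_out, 1):
        e = config.expand_ratio * cin
        total = _conv_params(cin, e, 1) + _bn_params(e)  # expand
        if config.ablation == "no_depthwise":
            total += _conv_params(e, e, 3) + _bn_params(e)
        else:
            total += 9 * e + _bn_params(e)  # depthwise, bias-free
        if config.ablation != "no_attention":
            total += _ca_params(e, config.reduction_ratio)
        total += _conv_params(e, cout, 1) + _bn_params(cout)  # project
        stages[f"ir{i}"] = total
        cin = cout

    head = 0
    if config.ablation != "no_final_projection":
        head += _conv_params(cin, sched.head_out, 1) + _bn_params(sched.head_out)
        fc_in = sched.head_out
    else:
        fc_in = cin
    head += fc_in * config.num_classes + config.num_classes
    stages["head"] = head

    total = sum(stages.values())
    return (total, stages) if per_stage else total


def count_macc(
    network: TinyWeedNet | ArchConfig, input_spec: TensorSpec | None = None
) -> ComplexityReport:
    """Multiply-accumulate counts per stage at a given input size.

    The ``macc`` column counts convolution and FC multiplies; ``element_ops``
    approximates the per-element work of BN, activations and pooling that
    deployment tools fold into their own (unvalidated) figures.
    """
    config = network.config if isinstance(network, TinyWeedNet) else network
    shapes = infer_shapes(config, input_spec)
    shape = {name: spec for name, spec in shapes}
    sched = config.schedule

    rows = []

    def add(stage, macc, elem, spec, attn=0):
        rows.append(
            {
                "stage": stage,
                "macc": int(macc),
                "attn_macc": int(attn),
                "element_ops": int(elem),
                "out_channels": spec.channels,
                "out_side": spec.height,
            }
        )

    def conv_macc(cout_spec, k, cin, groups=1):
        return cout_spec.height * cout_spec.width * cout_spec.channels * k * k * (
            cin // groups
        )

    s = shape["stem"]
    add("stem", conv_macc(s, 3, 3), 3 * s.channels * s.height * s.width, s)

    m = shape["msc"]
    if config.ablation == "no_msc":
        macc = conv_macc(m, 3, sched.stem_out)
        elem = 3 * m.channels * m.height * m.width
    else:
        macc = 0
        for w, k in zip(sched.msc_branch_widths, (1, 3, 5, 1)):
            macc += m.height * m.width * w * k * k * sched.stem_out
        # pool branch max-pool + per-branch BN/ReLU
        elem = (9 + 3) * sched.stem_out * m.height * m.width + 3 * m.channels * (
            m.height * m.width
        )
    add("msc", macc, elem, m)

    cin = sched.msc_out
    prev_spec = m
    for i, cout in enumerate(sched.ir_out, 1):
        spec = shape[f"ir{i}"]
        e = config.expand_ratio * cin
        macc = prev_spec.height * prev_spec.width * e * cin  # expand 1x1
        if config.ablation == "no_depthwise":
            macc += spec.height * spec.width * e * 9 * e
        else:
            macc += spec.height * spec.width * e * 9  # depthwise
        attn = 0
        if config.ablation != "no_attention":
            r = max(1, e // config.reduction_ratio)
            attn = 2 * (e * r + r * e)  # shared MLP on two pooled vectors
        macc += spec.height * spec.width * cout * e  # project 1x1
        elem = 6 * e * (prev_spec.height * prev_spec.width + spec.height * spec.width)
        add(f"ir{i}", macc, elem, spec, attn)
        cin = cout
        prev_spec = spec

    if config.ablation != "no_final_projection":
        h = shape["head_conv"]
        add("head_conv", conv_macc(h, 1, cin), 3 * h.channels * h.height * h.width, h)
        fc_in = sched.head_out
        pool_spec = h
    else:
        fc_in = cin
        pool_spec = prev_spec
    add(
        "fc",
        fc_in * config.num_classes,
        pool_spec.channels * pool_spec.height * pool_spec.width,
        shape["fc"],
    )

    df = pd.DataFrame(rows)
    total_params = closed_form_params(config)
    return ComplexityReport(
        per_layer=df,
        total_params=total_params,
        total_macc=int(df["macc"].sum() + df["attn_macc"].sum()),
        model_size_bytes=total_params * BYTES_PER_PARAM,
    )


def grid_report(configs: list[ArchConfig] | None = None) -> pd.DataFrame:
    """Complexity table (id, params, model size, MACC) for a config list.

    Defaults to the 27-point grid plus the four ablation variants, sorted by
    identifier; ablation rows are tagged in the ``ablation`` column.
    """
    if configs is None:
        configs = all_variants()
    rows = []
    for cfg in configs:
        params = closed_form_params(cfg)
        report = count_macc(cfg)
        ident = cfg.variant_id if cfg.ablation == "none" else f"ablation_{cfg.ablation}"
        rows.append(
            {
                "id": ident,
                "ablation": cfg.ablation,
                "params": params,
                "model_size_mb": round(model_size_mb(params), 3),
                "macc": report.total_macc,
            }
        )
    df = pd.DataFrame(rows).sort_values("id").reset_index(drop=True)
    return df
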