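"""Architecture configuration for the TinyWeedNet family.

A network variant is fully described by three integers — the inverted-residual
expand ratio ``E``, the channel-attention reduction ratio ``R`` and the stem
width ``S`` — plus the channel schedule they induce.  The printed layer
schedule for the reference design (``S = 24``) is::

    stem 24 -> MSC 36 (branches 9+9+9+9) -> IR 48/72/96/120/120 -> head 240

For other stem widths the schedule scales proportionally:
``msc = 1.5*S``, ``ir = [2S, 3S, 4S, 5S, 5S]``, ``head = 10*S``.  All grid
values of ``S`` (8, 16, 24) keep every entry integral, so no divisibility
correction is needed; :func:`make_divisible` is provided for user-defined
widths that fall off the grid.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "GRID_EXPAND_RATIOS",
    "GRID_REDUCTION_RATIOS",
    "GRID_STEM_CHANNELS",
    "ABLATION_KINDS",
    "ChannelSchedule",
    "ArchConfig",
    "make_divisible",
    "derive_channel_schedule",
    "default_config",
    "enumerate_grid",
    "make_ablation_config",
    "save_config",
    "load_config",
]

GRID_EXPAND_RATIOS = (3, 4, 6)
GRID_REDUCTION_RATIOS = (4, 8, 16)
GRID_STEM_CHANNELS = (8, 16, 24)

#: Structural ablations of the reference design.  Each removes or replaces a
#: single module; everything else (schedule, strides, head) is unchanged.
ABLATION_KINDS = ("no_msc", "no_attention", "no_depthwise", "no_final_projection")

IR_STRIDES = (2, 2, 2, 2, 1)


def make_divisible(value: float, divisor: int) -> int:
    """Round ``value`` to the nearest multiple of ``divisor``.

    Follows the MobileNet-family convention: the result never drops below
    ``divisor`` and never falls under 90% of ``value`` (rounding down by more
    than ~10% would change a layer's capacity too much).
    """
    if value <= 0:
        raise ValueError(f"value must be positive, got {value}")
    if divisor < 1:
        raise ValueError(f"divisor must be >= 1, got {divisor}")
    rounded = max(divisor, int(value + divisor / 2) // divisor * divisor)
    if rounded < 0.9 * value:
        rounded += divisor
    return rounded


@dataclass(frozen=True)
class ChannelSchedule:
    """Per-stage channel widths and strides of one network variant."""

    stem_out: int
    msc_out: int
    msc_branch_widths: tuple[int, int, int, int]
    ir_out: tuple[int, int, int, int, int]
    ir_strides: tuple[int, int, int, int, int] = IR_STRIDES
    head_out: int = 240

    def __post_init__(self) -> None:
        if sum(self.msc_branch_widths) != self.msc_out:
            raise ValueError(
                f"MSC branch widths {self.msc_branch_widths} do not sum to "
                f"msc_out={self.msc_out}"
            )
        if tuple(self.ir_strides) != IR_STRIDES:
            raise ValueError(f"IR strides must be {IR_STRIDES}")
        if any(c < 1 for c in (self.stem_out, self.msc_out, self.head_out)):
            raise ValueError("all channel widths must be positive")
        if any(c < 1 for c in self.ir_out):
            raise ValueError("all IR widths must be positive")


def derive_channel_schedule(stem_channels: int) -> ChannelSchedule:
    """Scale the reference channel schedule to an arbitrary stem width.

    The four MSC branches share the total ``1.5*S`` equally; any remainder
    from the integer split is assigned to the pooling branch (a deterministic
    tie-break).
    """
    if stem_channels < 4:
        raise ValueError(f"stem_channels must be >= 4, got {stem_channels}")
    s = stem_channels
    msc = int(1.5 * s)
    q = msc // 4
    branches = (q, q, q, msc - 3 * q)
    return ChannelSchedule(
        stem_out=s,
        msc_out=msc,
        msc_branch_widths=branches,
        ir_out=(2 * s, 3 * s, 4 * s, 5 * s, 5 * s),
        head_out=10 * s,
    )


@dataclass(frozen=True)
class ArchConfig:
    """One point of the (E, R, S) design space, optionally ablated."""

    expand_ratio: int = 4
    reduction_ratio: int = 8
    stem_channels: int = 24
    num_classes: int = 9
    input_side: int = 224
    dropout_p: float = 0.2
    ablation: str = "none"
    schedule: ChannelSchedule = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.expand_ratio < 1 or self.reduction_ratio < 1:
            raise ValueError("expand_ratio and reduction_ratio must be positive")
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ValueError(f"dropout_p must be in [0, 1], got {self.dropout_p}")
        if self.input_side < 1:
            raise ValueError("input_side must be positive")
        if self.ablation not in ("none",) + ABLATION_KINDS:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if self.schedule is None:
            object.__setattr__(
                self, "schedule", derive_channel_schedule(self.stem_channels)
            )
        elif self.schedule.stem_out != self.stem_channels:
            raise ValueError(
                f"schedule stem_out={self.schedule.stem_out} inconsistent with "
                f"stem_channels={self.stem_channels}"
            )

    @property
    def head_channels(self) -> int:
        """Width of the final 1x1 projection (Cf)."""
        return self.schedule.head_out

    @property
    def variant_id(self) -> str:
        return f"E{self.expand_ratio}_R{self.reduction_ratio}_S{self.stem_channels}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = dataclasses.asdict(self.schedule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        d = dict(d)
        sched = d.pop("schedule", None)
        if sched is not None:
            sched = ChannelSchedule(
                stem_out=sched["stem_out"],
                msc_out=sched["msc_out"],
                msc_branch_widths=tuple(sched["msc_branch_widths"]),
                ir_out=tuple(sched["ir_out"]),
                ir_strides=tuple(sched.get("ir_strides", IR_STRIDES)),
                head_out=sched["head_out"],
            )
        return cls(schedule=sched, **d)


def default_config(**overrides) -> ArchConfig:
    """The reference design point: E=4, R=8, S=24."""
    return ArchConfig(**overrides)


def enumerate_grid() -> list[ArchConfig]:
    """All 27 variants of the full-factorial (E, R, S) hyperparameter grid."""
    return [
        ArchConfig(expand_ratio=e, reduction_ratio=r, stem_channels=s)
        for e, r, s in itertools.product(
            GRID_EXPAND_RATIOS, GRID_REDUCTION_RATIOS, GRID_STEM_CHANNELS
        )
    ]


def make_ablation_config(kind: str) -> ArchConfig:
    """The reference design with one structural component removed.

    ``no_msc``
        multi-scale block replaced by a single 3x3 branch of equal width;
    ``no_attention``
        channel-attention gates removed from every IR block;
    ``no_depthwise``
        depthwise convolutions replaced by standard 3x3 convolutions;
    ``no_final_projection``
        head 1x1 projection omitted, pooled features feed the classifier
        directly.
    """
    if kind not in ABLATION_KINDS:
        raise ValueError(f"unknown ablation kind {kind!r}; expected one of {ABLATION_KINDS}")
    return ArchConfig(ablation=kind)


def save_config(config: ArchConfig, path: str | Path) -> None:
    """Serialize a configuration to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> ArchConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ArchConfig.from_dict(d)


def write_variant_configs(out_dir: str | Path) -> list[Path]:
    """Write all 27 grid configs plus the 4 ablations to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for cfg in enumerate_grid():
        p = out_dir / f"{cfg.variant_id}.yaml"
        save_config(cfg, p)
        written.append(p)
    for kind in ABLATION_KINDS:
        cfg = make_ablation_config(kind)
        p = out_dir / f"ablation_{kind}.yaml"
        save_config(cfg, p)
        written.append(p)
    return written


def all_variants() -> list[ArchConfig]:
    """The 27 grid configs plus the 4 ablation variants (31 total)."""
    return enumerate_grid() + [make_ablation_config(k) for k in ABLATION_KINDS]
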