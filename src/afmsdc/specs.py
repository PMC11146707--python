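"""Architecture specifications and the static analyzer for MSDC / residual blocks.

An MSDC (multi-scale dilated convolution) block is a set of parallel dilated
1-D convolution branches merged by channel concatenation; it is a drop-in
replacement for a plain residual block in a deep 1-D CNN for ECG rhythm
classification.  This module holds the declarative description of branches,
blocks and whole networks, plus the static analysis that a practitioner
wants before building anything: tap positions, receptive fields under the
tap-union counting rule, and parameter counts under two conventions.

Dilation convention
-------------------
The dilation factor ``d`` follows the convention in which ``d = 0`` denotes a
plain (contiguous) convolution and any ``d >= 1`` spaces consecutive kernel
taps ``d`` samples apart.  The effective tap stride is therefore
``max(d, 1)``: ``d = 0`` and ``d = 1`` both mean contiguous taps.

Parameter conventions
---------------------
``published``  counts ``k * f`` weights per branch — kernel taps times filters,
           ignoring input channels and biases.  This is the convention under
           which the four canonical blocks weigh 512 / 224 / 128 / 256.
``full``   counts ``in_channels * k * f + f`` per branch — the true trainable
           weight count of a conv layer with bias, used for real model sizing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence


class SpecError(ValueError):
    """An architecture specification violates an invariant."""


@dataclass(frozen=True)
class ConvBranchSpec:
    """One dilated-convolution branch: kernel size, stride, dilation factor, filters."""

    kernel_size: int
    stride: int
    dilation_factor: int
    filters: int

    def __post_init__(self) -> None:
        if not (isinstance(self.kernel_size, int) and self.kernel_size >= 1):
            raise SpecError(f"kernel_size must be a positive integer, got {self.kernel_size!r}")
        if not (isinstance(self.stride, int) and self.stride >= 1):
            raise SpecError(f"stride must be a positive integer, got {self.stride!r}")
        if not (isinstance(self.dilation_factor, int) and self.dilation_factor >= 0):
            raise SpecError(
                f"dilation_factor must be a non-negative integer, got {self.dilation_factor!r}"
            )
        if not (isinstance(self.filters, int) and self.filters >= 1):
            raise SpecError(f"filters must be a positive integer, got {self.filters!r}")

    @property
    def tap_stride(self) -> int:
        """Spacing between consecutive kernel taps; d=0 and d=1 both mean contiguous."""
        return max(self.dilation_factor, 1)

    @property
    def span(self) -> int:
        """Number of input samples covered from first to last tap, inclusive."""
        return (self.kernel_size - 1) * self.tap_stride + 1

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.kernel_size, self.stride, self.dilation_factor, self.filters)


@dataclass(frozen=True)
class BlockSpec:
    """A residual or MSDC block: ordered branches, concat merge, optional shortcut."""

    name: str
    branches: tuple[ConvBranchSpec, ...]
    skip: bool = True

    def __post_init__(self) -> None:
        if not self.branches:
            raise SpecError("a block needs at least one branch")
        object.__setattr__(self, "branches", tuple(self.branches))

    @property
    def out_channels(self) -> int:
        """Channel-concatenation merge: output width is the sum of branch filters."""
        return sum(b.filters for b in self.branches)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "branches": [b.as_tuple() for b in self.branches],
            "skip": self.skip,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockSpec":
        return cls(
            name=d["name"],
            branches=tuple(ConvBranchSpec(*t) for t in d["branches"]),
            skip=d.get("skip", True),
        )


@dataclass(frozen=True)
class NetworkSpec:
    """A full detection network: one block type stacked ``n_blocks`` deep.

    ``downsample_schedule`` lists block indices (0-based) whose branches run
    at stride 2, halving the temporal length.  ``input_length`` is a sample
    count or the string ``"variable"`` for length-agnostic inference (the
    global-average-pooling head accepts any admissible length).
    """

    block: BlockSpec
    n_blocks: int = 15
    n_classes: int = 2
    input_rate: float = 250.0
    input_length: int | str = 2500
    downsample_schedule: tuple[int, ...] = (3, 7, 11)
    stem_kernel: int = 16
    stem_filters: int = 32
    stem_stride: int = 2

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise SpecError("n_blocks must be >= 1")
        if self.n_classes not in (2, 4):
            raise SpecError(f"n_classes must be 2 or 4, got {self.n_classes}")
        object.__setattr__(self, "downsample_schedule", tuple(self.downsample_schedule))
        for i in self.downsample_schedule:
            if not (0 <= i < self.n_blocks):
                raise SpecError(
                    f"downsample_schedule index {i} out of range for n_blocks={self.n_blocks}"
                )

    def as_json(self) -> str:
        d = {
            "block": self.block.as_dict(),
            "n_blocks": self.n_blocks,
            "n_classes": self.n_classes,
            "input_rate": self.input_rate,
            "input_length": self.input_length,
            "downsample_schedule": list(self.downsample_schedule),
            "stem_kernel": self.stem_kernel,
            "stem_filters": self.stem_filters,
            "stem_stride": self.stem_stride,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        return cls(
            block=BlockSpec.from_dict(d["block"]),
            n_blocks=d["n_blocks"],
            n_classes=d["n_classes"],
            input_rate=d["input_rate"],
            input_length=d["input_length"],
            downsample_schedule=tuple(d["downsample_schedule"]),
            stem_kernel=d["stem_kernel"],
            stem_filters=d["stem_filters"],
            stem_stride=d.get("stem_stride", 2),
        )


# Canonical block definitions (branch tuples as published for the four blocks).
RESIDUAL = BlockSpec("residual", (ConvBranchSpec(16, 1, 0, 32),))
MSDC_A = BlockSpec("msdc_a", (ConvBranchSpec(8, 1, 2, 16), ConvBranchSpec(6, 1, 3, 16)))
MSDC_B = BlockSpec(
    "msdc_b",
    (
        ConvBranchSpec(8, 1, 2, 8),
        ConvBranchSpec(6, 1, 3, 8),
        ConvBranchSpec(1, 1, 5, 8),
        ConvBranchSpec(1, 1, 7, 8),
    ),
)
MSDC_C = BlockSpec("msdc_c", (ConvBranchSpec(8, 1, 2, 32),))

CANONICAL_BLOCKS: dict[str, BlockSpec] = {
    "residual": RESIDUAL,
    "msdc_a": MSDC_A,
    "msdc_b": MSDC_B,
    "msdc_c": MSDC_C,
}

# Receptive fields as printed in the original comparison table.  Block B's
# printed value (13) disagrees with the tap-union rule applied to its printed
# branch tuples (11); the analyzer reports both and flags the discrepancy.
PRINTED_RECEPTIVE_FIELDS: dict[str, int] = {
    "residual": 16,
    "msdc_a": 11,
    "msdc_b": 13,
    "msdc_c": 8,
}
PRINTED_PARAM_COUNTS: dict[str, int] = {
    "residual": 512,
    "msdc_a": 224,
    "msdc_b": 128,
    "msdc_c": 256,
}


def tap_positions(branch: ConvBranchSpec) -> tuple[int, ...]:
    """Input offsets touched by one application of the branch kernel.

    Taps sit at ``i * max(d, 1)`` for ``i = 0 .. k-1``, anchored at offset 0.
    """
    t = branch.tap_stride
    return tuple(i * t for i in range(branch.kernel_size))


def block_receptive_field(block: BlockSpec) -> int:
    """Distinct input positions feeding one output unit, union over branches.

    All branches are anchored at position 0; the receptive field is the
    cardinality of the union of their tap-position sets.
    """
    positions: set[int] = set()
    for b in block.branches:
        positions.update(tap_positions(b))
    return len(positions)


def branch_param_count(branch: ConvBranchSpec) -> int:
    """Weight count of one branch under the ``k * f`` convention."""
    return branch.kernel_size * branch.filters


def block_param_count(
    block: BlockSpec, convention: str = "published", in_channels: int | None = None
) -> int:
    """Parameter count of a block under the given convention.

    ``published``: sum of ``k * f`` over branches (input channels and biases
    excluded).  ``full``: sum of ``in_channels * k * f + f`` over branches —
    the trainable weight count of the convolutions themselves (normalization
    and shortcut-projection weights are not part of this sum).
    """
    if convention == "published":
        return sum(branch_param_count(b) for b in block.branches)
    if convention == "full":
        if in_channels is None:
            raise SpecError("convention='full' requires in_channels")
        return sum(
            in_channels * b.kernel_size * b.filters + b.filters for b in block.branches
        )
    raise SpecError(f"unknown parameter convention {convention!r} (use 'published' or 'full')")


def analyze_block(block: BlockSpec) -> dict:
    """One analyzer report row: branch tuples, receptive field, parameter count.

    For canonical blocks the row also carries the printed reference values and
    a ``discrepancy`` note whenever the tap-union rule disagrees with the
    printed receptive field (the case for block B: rule 11 vs printed 13).
    """
    rf = block_receptive_field(block)
    row = {
        "block": block.name,
        "branches": [b.as_tuple() for b in block.branches],
        "receptive_field": rf,
        "params_published": block_param_count(block, "published"),
        "out_channels": block.out_channels,
    }
    printed_rf = PRINTED_RECEPTIVE_FIELDS.get(block.name)
    if printed_rf is not None:
        row["printed_receptive_field"] = printed_rf
        row["printed_params"] = PRINTED_PARAM_COUNTS[block.name]
        if printed_rf != rf:
            row["discrepancy"] = (
                f"tap-union rule gives receptive field {rf}, but the published "
                f"table prints {printed_rf}; the printed branch tuples cannot "
                f"produce {printed_rf} under any tap-spacing reading consistent "
                f"with the printed parameter count"
            )
    return row


def analyze_table(blocks: Sequence[BlockSpec] = None) -> list[dict]:
    """Analyzer rows for a list of blocks (default: the four canonical ones)."""
    if blocks is None:
        blocks = list(CANONICAL_BLOCKS.values())
    return [analyze_block(b) for b in blocks]


def format_table(rows: Sequence[dict]) -> str:
    """Render analyzer rows as an aligned plain-text table with footnotes."""
    header = ("Block", "(k, s, d, f)", "RF", "Params(k*f)")
    lines = []
    notes = []
    body = []
    for row in rows:
        tuples = "".join(str(t) for t in row["branches"])
        rf = str(row["receptive_field"])
        if "printed_receptive_field" in row and row["printed_receptive_field"] != row["receptive_field"]:
            rf += "*"
            notes.append(
                f"* {row['block']}: printed receptive field is "
                f"{row['printed_receptive_field']}; {row['discrepancy']}"
            )
        body.append((row["block"], tuples, rf, str(row["params_published"])))
    widths = [max(len(r[i]) for r in [header, *body]) for i in range(4)]
    for r in [header, *body]:
        lines.append("  ".join(r[i].ljust(widths[i]) for i in range(4)).rstrip())
    lines[1:1] = ["-" * len(lines[0])]
    lines.extend(notes)
    return "\n".join(lines)


def network_spec(
    kind: str,
    n_blocks: int = 15,
    n_classes: int = 2,
    **kwargs,
) -> NetworkSpec:
    """NetworkSpec for a named architecture.

    ``kind`` is one of ``afmsdc_a``, ``afmsdc_b``, ``afmsdc_c``, ``resnet1d``
    (or a bare block name, which maps to the network built from that block).
    """
    aliases = {
        "afmsdc_a": "msdc_a",
        "afmsdc_b": "msdc_b",
        "afmsdc_c": "msdc_c",
        "resnet1d": "residual",
    }
    block_name = aliases.get(kind, kind)
    if block_name not in CANONICAL_BLOCKS:
        raise SpecError(
            f"unknown architecture {kind!r}; expected one of "
            f"{sorted(CANONICAL_BLOCKS) + sorted(aliases)}"
        )
    if "downsample_schedule" not in kwargs:
        # temporal halving every 4th block (indices 3, 7, 11 for the 15-block stack)
        kwargs["downsample_schedule"] = tuple(
            i for i in range(n_blocks) if i % 4 == 3
        )
    return NetworkSpec(
        block=CANONICAL_BLOCKS[block_name],
        n_blocks=n_blocks,
        n_classes=n_classes,
        **kwargs,
    )


def reduced_spec(kind: str, n_classes: int = 2) -> NetworkSpec:
    """Desk-scale 4-block variant: every block halves the temporal length."""
    return replace(
        network_spec(kind, n_blocks=4, n_classes=n_classes),
        downsample_schedule=(0, 1, 2, 3),
    )
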