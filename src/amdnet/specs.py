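"""Declarative layer and block specifications with analytic parameter counting.

A network is described as a tree of :class:`ConvSpec` leaves composed by
:class:`BlockSpec` nodes (sequential chains, parallel branches concatenated on
the channel axis, residual wrappers, and channel-attention scaling).  The
specification is the unit of parameter auditing: every trainable-parameter
total reported by the package is derivable from a spec tree by closed-form
arithmetic, independently of any instantiated weights.

Parameter formulas (biases included when ``bias`` is set):

* standard k_h x k_w convolution with F filters on C channels:
  ``(k_h * k_w * C + 1) * F``
* depthwise convolution: ``k_h * k_w * C + C`` (one filter per input channel)
* pointwise (1x1) convolution: ``(C + 1) * F``
* dense: ``(C + 1) * F``
* batch normalization adds ``2 * C_out`` trainable scalars (scale and shift;
  moving statistics are not trainable)
* max pooling and global average pooling are parameter free
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Union

import yaml

__all__ = [
    "TensorShape",
    "ConvSpec",
    "BlockSpec",
    "InvalidSpecError",
    "param_count",
    "out_channels",
    "propagate_shape",
    "block_param_total",
    "block_to_dict",
    "block_from_dict",
    "save_block_yaml",
    "load_block_yaml",
]

KINDS = ("standard", "depthwise", "pointwise", "maxpool", "dense", "gap")
ACTIVATIONS = ("none", "relu", "gelu", "sigmoid", "softmax")
TOPOLOGIES = ("sequential", "parallel_concat", "residual", "scale")


class InvalidSpecError(ValueError):
    """Raised when a layer or block specification is internally inconsistent."""


@dataclass(frozen=True)
class TensorShape:
    """Spatial height/width in pixels plus channel count."""

    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        for name in ("height", "width", "channels"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise InvalidSpecError(f"TensorShape.{name} must be a positive int, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.height, self.width, self.channels)


@dataclass(frozen=True)
class ConvSpec:
    """One parameterizable (or pooling) layer.

    ``filters`` is the output-channel count for standard/pointwise convolutions
    and the unit count for dense layers; it must be left unset for depthwise
    convolutions and pooling, whose output width is fixed by the input.
    """

    kind: str
    kernel: tuple[int, int] = (1, 1)
    filters: int | None = None
    stride: int = 1
    padding: str = "same"
    bias: bool = True
    activation: str = "none"
    batchnorm: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidSpecError(f"unknown layer kind {self.kind!r}")
        if self.activation not in ACTIVATIONS:
            raise InvalidSpecError(f"unknown activation {self.activation!r}")
        if self.padding not in ("same", "valid"):
            raise InvalidSpecError(f"unknown padding {self.padding!r}")
        kh, kw = self.kernel
        if kh < 1 or kw < 1 or self.stride < 1:
            raise InvalidSpecError("kernel dims and stride must be positive")
        if self.kind == "pointwise" and self.kernel != (1, 1):
            raise InvalidSpecError("pointwise convolution requires a 1x1 kernel")
        if self.kind == "depthwise" and self.filters is not None:
            raise InvalidSpecError(
                "depthwise convolution has no independent filter count "
                "(output channels equal input channels)"
            )
        if self.kind in ("maxpool", "gap") and self.filters is not None:
            raise InvalidSpecError(f"{self.kind} takes no filter count")
        if self.kind in ("standard", "pointwise", "dense") and (
            self.filters is None or self.filters < 1
        ):
            raise InvalidSpecError(f"{self.kind} layer requires a positive filter count")

    def kernel_filter_label(self) -> str:
        """Human-readable 'kernel/filters' string in the audit-table style."""
        kh, kw = self.kernel
        if self.kind == "dense":
            return f"dense/{self.filters}"
        if self.kind == "gap":
            return "gap"
        if self.kind in ("depthwise", "maxpool"):
            return f"{kh} x {kw}"
        return f"{kh} x {kw}/{self.filters}"


Node = Union[ConvSpec, "BlockSpec"]


@dataclass
class BlockSpec:
    """Composite of layers and sub-blocks.

    Topologies:

    * ``sequential`` — nodes applied in order.
    * ``parallel_concat`` — each node consumes the block input; outputs are
      concatenated along the channel axis (branches must agree on spatial
      dims).
    * ``residual`` — the node chain must preserve shape; the block output is
      input + chain(input).
    * ``scale`` — the node chain maps the input to one weight per channel
      (squeeze-and-excitation style); the block output is the input rescaled
      channel-wise, so its shape equals the input shape.
    """

    name: str
    topology: str = "sequential"
    nodes: list[Node] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise InvalidSpecError(f"unknown topology {self.topology!r}")

    def leaves(self) -> Iterator[ConvSpec]:
        """All ConvSpec leaves in depth-first (audit table) order."""
        for node in self.nodes:
            if isinstance(node, BlockSpec):
                yield from node.leaves()
            else:
                yield node


# ---------------------------------------------------------------------------
# analytic parameter accounting


def param_count(spec: ConvSpec, in_channels: int) -> int:
    """Exact trainable-parameter count of one layer given its input channels."""
    if in_channels < 1:
        raise InvalidSpecError(f"in_channels must be >= 1, got {in_channels}")
    kh, kw = spec.kernel
    b = 1 if spec.bias else 0
    if spec.kind == "standard":
        n = (kh * kw * in_channels + b) * spec.filters
    elif spec.kind == "depthwise":
        n = kh * kw * in_channels + b * in_channels
    elif spec.kind in ("pointwise", "dense"):
        n = (in_channels + b) * spec.filters
    elif spec.kind in ("maxpool", "gap"):
        n = 0
    else:  # pragma: no cover - guarded by __post_init__
        raise InvalidSpecError(spec.kind)
    if spec.batchnorm:
        n += 2 * out_channels(spec, in_channels)
    return n


def out_channels(spec: ConvSpec, in_channels: int) -> int:
    if spec.kind in ("depthwise", "maxpool", "gap"):
        return in_channels
    return int(spec.filters)


def _conv_spatial(size: int, k: int, stride: int, padding: str) -> int:
    if padding == "same":
        return math.ceil(size / stride)
    return (size - k) // stride + 1


def propagate_shape(node: Node, in_shape: TensorShape) -> TensorShape:
    """Output shape of a layer or block applied to ``in_shape``.

    Raises :class:`InvalidSpecError` when a topology constraint is violated
    (mismatched parallel branches, non-shape-preserving residual chains).
    """
    if isinstance(node, ConvSpec):
        if node.kind == "dense":
            if in_shape.height != 1 or in_shape.width != 1:
                raise InvalidSpecError(
                    f"dense layer {node.name!r} requires a flat (1,1,C) input, got "
                    f"{in_shape.as_tuple()}"
                )
            return TensorShape(1, 1, node.filters)
        if node.kind == "gap":
            return TensorShape(1, 1, in_shape.channels)
        kh, kw = node.kernel
        h = _conv_spatial(in_shape.height, kh, node.stride, node.padding)
        w = _conv_spatial(in_shape.width, kw, node.stride, node.padding)
        if h < 1 or w < 1:
            raise InvalidSpecError(f"layer {node.name!r} collapses spatial dims to zero")
        return TensorShape(h, w, out_channels(node, in_shape.channels))

    if node.topology == "sequential":
        shape = in_shape
        for child in node.nodes:
            shape = propagate_shape(child, shape)
        return shape
    if node.topology == "parallel_concat":
        outs = [propagate_shape(child, in_shape) for child in node.nodes]
        hw = {(s.height, s.width) for s in outs}
        if len(hw) != 1:
            raise InvalidSpecError(
                f"parallel branches of {node.name!r} disagree on spatial dims: {sorted(hw)}"
            )
        return TensorShape(outs[0].height, outs[0].width, sum(s.channels for s in outs))
    if node.topology == "residual":
        inner = in_shape
        for child in node.nodes:
            inner = propagate_shape(child, inner)
        if inner != in_shape:
            raise InvalidSpecError(
                f"residual block {node.name!r} must preserve shape; "
                f"{in_shape.as_tuple()} -> {inner.as_tuple()}"
            )
        return in_shape
    # scale: chain output is one weight per channel; block output is the input
    inner = in_shape
    for child in node.nodes:
        inner = propagate_shape(child, inner)
    if inner.channels != in_shape.channels or (inner.height, inner.width) != (1, 1):
        raise InvalidSpecError(
            f"scale block {node.name!r} must emit a (1,1,{in_shape.channels}) "
            f"weight vector, got {inner.as_tuple()}"
        )
    return in_shape


def block_param_total(node: Node, in_shape: TensorShape) -> int:
    """Analytic trainable-parameter total of a layer/block tree."""
    if isinstance(node, ConvSpec):
        return param_count(node, in_shape.channels)
    total = 0
    if node.topology == "parallel_concat":
        for child in node.nodes:
            total += block_param_total(child, in_shape)
    else:
        shape = in_shape
        for child in node.nodes:
            total += block_param_total(child, shape)
            shape = propagate_shape(child, shape)
    return total


# ---------------------------------------------------------------------------
# YAML (de)serialization, mirroring the audit-table schema


def _spec_to_dict(spec: ConvSpec) -> dict:
    d = {
        "layer": spec.name,
        "kind": spec.kind,
        "kernel_size/filter": spec.kernel_filter_label(),
        "kernel": list(spec.kernel),
        "stride": spec.stride,
        "padding": spec.padding,
        "bias": spec.bias,
        "activation": spec.activation,
        "batchnorm": spec.batchnorm,
    }
    if spec.filters is not None:
        d["filters"] = spec.filters
    return d


def block_to_dict(node: Node) -> dict:
    if isinstance(node, ConvSpec):
        return _spec_to_dict(node)
    return {
        "block": node.name,
        "topology": node.topology,
        "nodes": [block_to_dict(child) for child in node.nodes],
    }


def block_from_dict(d: dict) -> Node:
    if "block" in d:
        return BlockSpec(
            name=d["block"],
            topology=d["topology"],
            nodes=[block_from_dict(c) for c in d["nodes"]],
        )
    return ConvSpec(
        kind=d["kind"],
        kernel=tuple(d.get("kernel", (1, 1))),
        filters=d.get("filters"),
        stride=d.get("stride", 1),
        padding=d.get("padding", "same"),
        bias=d.get("bias", True),
        activation=d.get("activation", "none"),
        batchnorm=d.get("batchnorm", False),
        name=d.get("layer", ""),
    )


def save_block_yaml(node: Node, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(block_to_dict(node), fh, sort_keys=False)


def load_block_yaml(path) -> Node:
    with open(path) as fh:
        return block_from_dict(yaml.safe_load(fh))


def with_name(spec: ConvSpec, name: str) -> ConvSpec:
    return replace(spec, name=name)
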