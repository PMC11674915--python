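"""Builders for the network's architectural building blocks.

The model under study is a compact OCT B-scan classifier assembled from four
pieces:

* a convolutional **stem** (5x5 conv, depthwise-separable conv, batch norm,
  strided max pooling) that downsamples the 224x224 input once;
* a **modified Inception module (MIM)** — the classic four-branch Inception
  layout with the 3x3 and 5x5 standard convolutions replaced by depthwise +
  pointwise pairs, cutting the branch parameter cost by more than an order of
  magnitude;
* a **depthwise squeeze-and-excitation block (DSEB)** — two depthwise
  separable convolutions followed by channel attention;
* a **ConvMixer stage** — patch embedding followed by ``d`` repetitions of a
  residual depthwise mixer and a pointwise channel mixer, each with GELU and
  batch normalization.

Branch order inside the Inception modules follows the audit-table layout
(spatial convolution before the trailing 1x1 in the 3x3 and 5x5 branches);
the per-row parameter counts force this reading.  All convolutions inside the
stem and the Inception modules use stride 1 with 'same' padding so that the
four parallel branches agree on spatial dims; the stem max pool is the single
downsampling step (stride 2).
"""

from __future__ import annotations

from .specs import BlockSpec, ConvSpec, InvalidSpecError, TensorShape

__all__ = [
    "build_stem",
    "build_inception_standard",
    "build_mim",
    "build_se",
    "build_dseb",
    "build_convmixer",
]


def build_stem(in_shape: TensorShape, filters: int = 32) -> BlockSpec:
    """Stem: Conv 5x5/filters -> DConv 3x3 -> PConv 1x1/filters + BN -> maxpool 3x3 s2."""
    return BlockSpec(
        name="stem",
        topology="sequential",
        nodes=[
            ConvSpec("standard", (5, 5), filters, activation="relu", name="Stem_Conv"),
            ConvSpec("depthwise", (3, 3), activation="relu", name="Stem_DConv"),
            ConvSpec(
                "pointwise", (1, 1), filters, activation="relu", batchnorm=True,
                name="Stem_PConv",
            ),
            ConvSpec("maxpool", (3, 3), stride=2, name="Stem_Max_pooling"),
        ],
    )


def build_inception_standard(in_shape: TensorShape, branch_filters: int = 64) -> BlockSpec:
    """Standard four-branch Inception module (1x1 | 3x3-1x1 | 5x5-1x1 | pool-1x1)."""
    f = branch_filters
    return BlockSpec(
        name="IM",
        topology="parallel_concat",
        nodes=[
            ConvSpec("standard", (1, 1), f, activation="relu", name="Conv1"),
            BlockSpec(
                name="IM_branch3x3",
                nodes=[
                    ConvSpec("standard", (3, 3), f, activation="relu", name="Conv2"),
                    ConvSpec("standard", (1, 1), f, activation="relu", name="Conv3"),
                ],
            ),
            BlockSpec(
                name="IM_branch5x5",
                nodes=[
                    ConvSpec("standard", (5, 5), f, activation="relu", name="Conv4"),
                    ConvSpec("standard", (1, 1), f, activation="relu", name="Conv5"),
                ],
            ),
            BlockSpec(
                name="IM_branchpool",
                nodes=[
                    ConvSpec("maxpool", (3, 3), name="Max_pooling"),
                    ConvSpec("standard", (1, 1), f, activation="relu", name="Conv6"),
                ],
            ),
        ],
    )


def build_mim(in_shape: TensorShape, branch_filters: int = 64) -> BlockSpec:
    """Modified Inception module: depthwise+pointwise pairs in the 3x3/5x5 branches."""
    f = branch_filters
    return BlockSpec(
        name="MIM",
        topology="parallel_concat",
        nodes=[
            ConvSpec("standard", (1, 1), f, activation="relu", name="Conv1"),
            BlockSpec(
                name="MIM_branch3x3",
                nodes=[
                    ConvSpec("depthwise", (3, 3), activation="relu", name="DConv1"),
                    ConvSpec("pointwise", (1, 1), f, activation="relu", name="PConv1"),
                ],
            ),
            BlockSpec(
                name="MIM_branch5x5",
                nodes=[
                    ConvSpec("depthwise", (5, 5), activation="relu", name="DConv2"),
                    ConvSpec("pointwise", (1, 1), f, activation="relu", name="PConv2"),
                ],
            ),
            BlockSpec(
                name="MIM_branchpool",
                nodes=[
                    ConvSpec("maxpool", (3, 3), name="Max_pooling"),
                    ConvSpec("standard", (1, 1), f, activation="relu", name="Conv6"),
                ],
            ),
        ],
    )


def build_se(channels: int, ratio: int = 16) -> BlockSpec:
    """Squeeze-and-excitation: GAP -> dense C/r (ReLU) -> dense C (sigmoid) -> rescale.

    The bottleneck width is ``max(channels // ratio, 1)``.  The sigmoid gate
    keeps every attention weight in (0, 1); the block output preserves the
    input shape because the weights only rescale channels.
    """
    if channels < 1:
        raise InvalidSpecError(f"channels must be >= 1, got {channels}")
    if ratio < 1:
        raise InvalidSpecError(f"ratio must be >= 1, got {ratio}")
    squeeze = max(channels // ratio, 1)
    return BlockSpec(
        name="SE",
        topology="scale",
        nodes=[
            ConvSpec("gap", name="SE_squeeze"),
            ConvSpec("dense", filters=squeeze, activation="relu", name="SE_reduce"),
            ConvSpec("dense", filters=channels, activation="sigmoid", name="SE_expand"),
        ],
    )


def build_dseb(in_shape: TensorShape, filters: int = 64, se_ratio: int = 16) -> BlockSpec:
    """DSEB: DConv 5x5 -> PConv/filters -> DConv 3x3 -> PConv/filters -> SE."""
    return BlockSpec(
        name="DSEB",
        topology="sequential",
        nodes=[
            ConvSpec("depthwise", (5, 5), activation="relu", name="DSEB_DConv1"),
            ConvSpec("pointwise", (1, 1), filters, activation="relu", name="DSEB_PConv1"),
            ConvSpec("depthwise", (3, 3), activation="relu", name="DSEB_DConv2"),
            ConvSpec("pointwise", (1, 1), filters, activation="relu", name="DSEB_PConv2"),
            build_se(filters, se_ratio),
        ],
    )


def build_convmixer(
    in_shape: TensorShape, h: int = 256, d: int = 16, k: int = 5, p: int = 2
) -> BlockSpec:
    """ConvMixer stage: patch embedding plus ``d`` depthwise/pointwise mixer blocks.

    The embedding is a standard convolution with kernel and stride equal to the
    patch size ``p``, mapping an ``n x n x C`` input to ``n/p x n/p x h``; every
    mixer block preserves that shape.
    """
    if in_shape.height % p or in_shape.width % p:
        raise InvalidSpecError(
            f"patch size {p} does not divide spatial dims "
            f"{in_shape.height}x{in_shape.width} at the ConvMixer stage"
        )
    nodes: list = [
        ConvSpec(
            "standard", (p, p), h, stride=p, padding="valid",
            activation="gelu", batchnorm=True, name="CM_patch_embed",
        )
    ]
    for i in range(1, d + 1):
        nodes.append(
            BlockSpec(
                name=f"CM_block{i}",
                topology="sequential",
                nodes=[
                    BlockSpec(
                        name=f"CM_block{i}_residual",
                        topology="residual",
                        nodes=[
                            ConvSpec(
                                "depthwise", (k, k), activation="gelu",
                                batchnorm=True, name=f"CM_block{i}_DConv",
                            )
                        ],
                    ),
                    ConvSpec(
                        "pointwise", (1, 1), h, activation="gelu",
                        batchnorm=True, name=f"CM_block{i}_PConv",
                    ),
                ],
            )
        )
    return BlockSpec(name="CM", topology="sequential", nodes=nodes)
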