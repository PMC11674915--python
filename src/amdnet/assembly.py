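"""Full-model assembly, ablation variants, parameter auditing and
reconciliation of under-determined hyperparameters.

The complete classifier chains stem -> modified Inception module (x1) ->
3x3/128 convolution -> DSEB -> ConvMixer stage (h=256, d=16, k=5, p=2) ->
global average pooling -> fully connected head -> softmax over 3 classes.
Several head/attention hyperparameters of the published design are not pinned
down by its description; :func:`reconcile_config` searches a small documented
space of candidates for a configuration whose trainable-parameter count hits a
target total, and reports the nearest miss when none does.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace

import yaml

from .blocks import build_convmixer, build_dseb, build_mim, build_stem
from .engine import Model, compile_model
from .specs import (
    BlockSpec,
    ConvSpec,
    TensorShape,
    block_param_total,
    param_count,
    propagate_shape,
)

__all__ = [
    "ModelConfig",
    "LayerAudit",
    "AblationId",
    "build_pm_spec",
    "build_pm",
    "build_ablation",
    "count_trainable",
    "audit",
    "audit_block",
    "reconcile_config",
    "ReconcileResult",
    "NearestMiss",
    "DEFAULT_SEARCH_SPACE",
]

BN_VARIANTS = ("stem", "stem_postmim")


@dataclass
class ModelConfig:
    """Every hyperparameter of the full model, stated and reconciled.

    ``se_ratio``, ``head_hidden_units``, ``bias`` and ``bn_variant`` are the
    reconciliation knobs; the remaining fields are fixed by the architecture
    description.
    """

    input_shape: TensorShape = field(default_factory=lambda: TensorShape(224, 224, 3))
    stem_filters: int = 32
    mim_branch_filters: int = 64
    mim_repeats: int = 1
    post_mim_kernel: int = 3
    post_mim_filters: int = 128
    dseb_filters: int = 64
    se_ratio: int = 16
    cm_h: int = 256
    cm_d: int = 16
    cm_k: int = 5
    cm_p: int = 2
    head_hidden_units: list[int] = field(default_factory=list)
    n_classes: int = 3
    bias: bool = True
    bn_variant: str = "stem"

    def __post_init__(self) -> None:
        if isinstance(self.input_shape, (tuple, list)):
            self.input_shape = TensorShape(*self.input_shape)
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.bn_variant not in BN_VARIANTS:
            raise ValueError(f"bn_variant must be one of {BN_VARIANTS}")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["input_shape"] = list(self.input_shape.as_tuple())
        d["head_hidden_units"] = list(self.head_hidden_units)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class AblationId:
    """Component flags of one ablation variant (stem and head always present)."""

    id: int
    uses_mim: bool
    uses_dseb: bool
    uses_cm: bool

    _TABLE = {
        1: (True, False, False),
        2: (False, True, False),
        3: (False, False, True),
        4: (False, True, True),
        5: (True, False, True),
        6: (True, True, False),
        7: (True, True, True),
    }

    @classmethod
    def from_id(cls, i: int) -> "AblationId":
        if i not in cls._TABLE:
            raise ValueError(f"ablation id must be in 1..7, got {i}")
        return cls(i, *cls._TABLE[i])

    def __post_init__(self) -> None:
        expected = self._TABLE.get(self.id)
        if expected is None:
            raise ValueError(f"ablation id must be in 1..7, got {self.id}")
        if (self.uses_mim, self.uses_dseb, self.uses_cm) != expected:
            raise ValueError(f"component flags inconsistent with ablation id {self.id}")


def _set_bias(node, bias: bool):
    if isinstance(node, ConvSpec):
        return replace(node, bias=bias)
    return BlockSpec(
        name=node.name, topology=node.topology,
        nodes=[_set_bias(c, bias) for c in node.nodes],
    )


def _head_nodes(config: ModelConfig) -> list:
    nodes: list = [ConvSpec("gap", name="GAP")]
    for i, units in enumerate(config.head_hidden_units, start=1):
        nodes.append(ConvSpec("dense", filters=units, activation="relu", name=f"FC{i}"))
    nodes.append(
        ConvSpec("dense", filters=config.n_classes, activation="softmax", name="FC_out")
    )
    return nodes


def _component_spec(config: ModelConfig, flags: AblationId, name: str) -> BlockSpec:
    shape = config.input_shape
    nodes: list = [build_stem(shape, config.stem_filters)]
    shape = propagate_shape(nodes[-1], shape)
    if flags.uses_mim:
        for _ in range(config.mim_repeats):
            nodes.append(build_mim(shape, config.mim_branch_filters))
            shape = propagate_shape(nodes[-1], shape)
        k = config.post_mim_kernel
        nodes.append(
            ConvSpec(
                "standard", (k, k), config.post_mim_filters, activation="relu",
                batchnorm=(config.bn_variant == "stem_postmim"), name="Post_MIM_Conv",
            )
        )
        shape = propagate_shape(nodes[-1], shape)
    if flags.uses_dseb:
        nodes.append(build_dseb(shape, config.dseb_filters, config.se_ratio))
        shape = propagate_shape(nodes[-1], shape)
    if flags.uses_cm:
        nodes.append(build_convmixer(shape, config.cm_h, config.cm_d, config.cm_k, config.cm_p))
        shape = propagate_shape(nodes[-1], shape)
    nodes.extend(_head_nodes(config))
    spec = BlockSpec(name=name, topology="sequential", nodes=nodes)
    if not config.bias:
        spec = _set_bias(spec, False)
    return spec


def build_pm_spec(config: ModelConfig | None = None) -> BlockSpec:
    """Declarative spec of the full model for the given configuration."""
    config = config or ModelConfig()
    return _component_spec(config, AblationId.from_id(7), "full_model")


def build_pm(config: ModelConfig | None = None, seed: int = 0, dtype=None) -> Model:
    """Compile the full model into an executable network."""
    import numpy as np

    config = config or ModelConfig()
    spec = build_pm_spec(config)
    return compile_model(spec, config.input_shape, seed=seed,
                         dtype=dtype or np.float32)


def build_ablation(
    abl: AblationId | int, config: ModelConfig | None = None, seed: int = 0, dtype=None
) -> Model:
    """Compile an ablation variant containing exactly the flagged components.

    The stem and the GAP/FC/softmax head are always retained; flagged
    components appear in full-model order, and the post-Inception 3x3
    convolution travels with the Inception module.
    """
    import numpy as np

    config = config or ModelConfig()
    if isinstance(abl, int):
        abl = AblationId.from_id(abl)
    spec = _component_spec(config, abl, f"Model{abl.id}")
    return compile_model(spec, config.input_shape, seed=seed, dtype=dtype or np.float32)


# ---------------------------------------------------------------------------
# auditing


@dataclass
class LayerAudit:
    """Per-layer parameter table: (layer, input, kernel/filter, params) rows."""

    rows: list[tuple[str, str, str, int]]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(r[3] for r in self.rows):
            raise ValueError("audit total does not equal the sum of row params")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["layer", "input", "kernel_filter", "params"])

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.loc[len(df)] = ["Total", "", "", self.total]
        df.to_csv(path, index=False)

    def param_column(self) -> list[int]:
        return [r[3] for r in self.rows]


def count_trainable(model: Model | None) -> int:
    """Exact count of trainable scalars in a compiled model (0 for empty)."""
    if model is None:
        return 0
    return model.n_trainable()


def audit(model: Model) -> LayerAudit:
    """Audit table of a compiled model; row params counted from weight arrays."""
    rows = []
    for leaf in model.leaves():
        n = int(sum(p.size for p in leaf.params()))
        rows.append((leaf.spec.name, leaf.input_name, leaf.spec.kernel_filter_label(), n))
    return LayerAudit(rows=rows, total=sum(r[3] for r in rows))


def audit_block(
    node, in_shape: TensorShape, input_name: str = "Input_Image"
) -> LayerAudit:
    """Analytic audit of a block spec (no weights allocated)."""
    rows: list[tuple[str, str, str, int]] = []

    def walk(n, shape, prev):
        if isinstance(n, ConvSpec):
            rows.append((n.name, prev, n.kernel_filter_label(), param_count(n, shape.channels)))
            return
        if n.topology == "parallel_concat":
            for child in n.nodes:
                walk(child, shape, prev)
            return
        cur, name = shape, prev
        for child in n.nodes:
            walk(child, cur, name)
            cur = propagate_shape(child, cur)
            name = child.name

    walk(node, in_shape, input_name)
    return LayerAudit(rows=rows, total=sum(r[3] for r in rows))


# ---------------------------------------------------------------------------
# reconciliation


DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "se_ratio": [2, 4, 8, 16],
    "head_hidden_units": [[], [256], [128], [512]],
    "bias": [True],
    "bn_variant": ["stem", "stem_postmim"],
}


@dataclass
class NearestMiss:
    config: ModelConfig
    count: int
    delta: int  # count - target


@dataclass
class ReconcileResult:
    target: int
    matches: list[ModelConfig]
    nearest: NearestMiss

    def report_dict(self) -> dict:
        return {
            "target": self.target,
            "n_matches": len(self.matches),
            "matches": [m.to_dict() for m in self.matches],
            "nearest_miss": {
                "config": self.nearest.config.to_dict(),
                "count": self.nearest.count,
                "delta": self.nearest.delta,
            },
        }


def _distance_from_default(cfg: ModelConfig, base: ModelConfig) -> int:
    return sum(
        getattr(cfg, f.name) != getattr(base, f.name) for f in fields(ModelConfig)
    )


def reconcile_config(
    search_space: dict[str, list] | None = None,
    target: int = 1_650_020,
    base: ModelConfig | None = None,
) -> ReconcileResult:
    """Search a finite space of unstated hyperparameters for a target count.

    Every combination in ``search_space`` (a mapping from ModelConfig field
    name to candidate values) is applied on top of ``base``; configurations
    whose analytic trainable-parameter count equals ``target`` are returned
    sorted by distance from the defaults.  The nearest miss (smallest absolute
    delta, ties toward fewer changed fields) is always reported.
    """
    space = search_space or DEFAULT_SEARCH_SPACE
    base = base or ModelConfig()
    names = list(space)
    matches: list[ModelConfig] = []
    best: NearestMiss | None = None
    for combo in itertools.product(*(space[k] for k in names)):
        cfg = replace(base, **dict(zip(names, combo)))
        count = block_param_total(build_pm_spec(cfg), cfg.input_shape)
        if count == target:
            matches.append(cfg)
        delta = count - target
        if best is None or (
            abs(delta), _distance_from_default(cfg, base)
        ) < (abs(best.delta), _distance_from_default(best.config, base)):
            best = NearestMiss(cfg, count, delta)
    matches.sort(key=lambda c: _distance_from_default(c, base))
    return ReconcileResult(target=target, matches=matches, nearest=best)
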