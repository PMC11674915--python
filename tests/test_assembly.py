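"""Full-model assembly, ablations, three-way parameter-count agreement,
and hyperparameter reconciliation."""

import numpy as np
import pytest

from amdnet.assembly import (
    AblationId,
    DEFAULT_SEARCH_SPACE,
    LayerAudit,
    ModelConfig,
    audit,
    audit_block,
    build_ablation,
    build_pm,
    build_pm_spec,
    count_trainable,
    reconcile_config,
)
from amdnet.blocks import build_inception_standard, build_mim
from amdnet.engine import compile_model
from amdnet.specs import InvalidSpecError, TensorShape, block_param_total


class TestFullModel:
    def test_three_way_parameter_count_agreement(self):
        """Framework count, audit total, and analytic summation coincide."""
        config = ModelConfig()
        model = build_pm(config, seed=0)
        analytic = block_param_total(build_pm_spec(config), config.input_shape)
        assert count_trainable(model) == audit(model).total == analytic

    def test_output_is_probability_simplex(self):
        # an untrained net can saturate float32 softmax to exact 0/1, so
        # nonnegativity rather than strict positivity is asserted
        model = build_pm(ModelConfig(), seed=1)
        x = np.random.default_rng(0).random((2, 3, 224, 224), dtype=np.float32)
        probs = model.forward(x)
        assert probs.shape == (2, 3)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_patch_size_names_offending_stage(self):
        config = ModelConfig(input_shape=TensorShape(225, 225, 3), cm_p=4)
        with pytest.raises(InvalidSpecError, match="ConvMixer"):
            build_pm_spec(config)

    def test_config_yaml_roundtrip(self, tmp_path):
        config = ModelConfig(se_ratio=8, head_hidden_units=[256], cm_d=4)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert ModelConfig.from_yaml(path) == config

    def test_unknown_config_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelConfig.from_dict({"se_ratios": 8})


SMALL = ModelConfig(
    input_shape=TensorShape(32, 32, 3), stem_filters=8, mim_branch_filters=8,
    post_mim_filters=16, dseb_filters=8, se_ratio=4, cm_h=8, cm_d=2, cm_k=3, cm_p=2,
)


class TestAblations:
    def test_flag_table(self):
        flags = {i: AblationId.from_id(i) for i in range(1, 8)}
        assert (flags[1].uses_mim, flags[1].uses_dseb, flags[1].uses_cm) == (True, False, False)
        assert (flags[3].uses_mim, flags[3].uses_dseb, flags[3].uses_cm) == (False, False, True)
        assert all(getattr(flags[7], f) for f in ("uses_mim", "uses_dseb", "uses_cm"))

    def test_invalid_ids_rejected(self):
        with pytest.raises(ValueError):
            AblationId.from_id(0)
        with pytest.raises(ValueError):
            AblationId(3, True, True, True)

    @pytest.mark.parametrize("abl_id", range(1, 8))
    def test_count_agreement_for_every_variant(self, abl_id):
        model = build_ablation(abl_id, ModelConfig())
        analytic = block_param_total(model.spec, ModelConfig().input_shape)
        assert count_trainable(model) == audit(model).total == analytic

    def test_full_flag_variant_matches_proposed_model(self):
        config = ModelConfig()
        assert count_trainable(build_ablation(7, config)) == count_trainable(
            build_pm(config)
        )

    def test_convmixer_only_variant_contents(self):
        model = build_ablation(3, SMALL)
        names = [leaf.spec.name for leaf in model.leaves()]
        assert not any("MIM" in n or "DSEB" in n or "Post_MIM" in n for n in names)
        assert sum("CM_block" in n and "PConv" in n for n in names) == SMALL.cm_d

    def test_component_flag_parameter_relations(self):
        """Adding the Inception module or the ConvMixer stage always adds
        parameters.  Adding the DSEB is different: it bottlenecks the channel
        count from 128 to 64 ahead of the ConvMixer patch embedding, so the
        full model is *smaller* than the variant without DSEB by exactly the
        embed saving minus the DSEB's own cost."""
        config = ModelConfig()
        counts = {i: count_trainable(build_ablation(i, config)) for i in range(1, 8)}
        # growing the flag set by MIM or CM only increases the count
        assert counts[1] < counts[5]
        assert counts[2] < counts[4]
        assert counts[2] < counts[6]
        assert counts[3] < counts[4] < counts[7]
        assert counts[1] < counts[7] and counts[6] < counts[7]
        # the DSEB bottleneck: embed on 128 ch vs 64 ch costs 64*4*256 more,
        # while the DSEB itself (on 128 input channels) costs 16,964
        embed_saving = (4 * 128 + 1) * 256 - (4 * 64 + 1) * 256
        dseb_cost = 16_964
        assert counts[5] - counts[7] == embed_saving - dseb_cost

    def test_ablation_outputs_are_probabilities(self):
        x = np.random.default_rng(0).random((2, 3, 32, 32), dtype=np.float32)
        for i in (1, 3, 6):
            probs = build_ablation(i, SMALL, seed=i).forward(x)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestAudit:
    def test_inception_audit_matches_reference_table(self):
        shape = TensorShape(224, 224, 3)
        model = compile_model(build_inception_standard(shape, 64), shape, seed=0)
        table = audit(model)
        assert table.param_column() == [256, 1792, 4160, 4864, 4160, 0, 256]
        assert [r[0] for r in table.rows] == [
            "Conv1", "Conv2", "Conv3", "Conv4", "Conv5", "Max_pooling", "Conv6",
        ]
        assert table.rows[1][1] == "Input_Image"  # Conv2 consumes the input
        assert table.rows[2][1] == "Conv2"  # Conv3 consumes Conv2

    def test_mim_audit_matches_reference_table(self):
        shape = TensorShape(224, 224, 3)
        model = compile_model(build_mim(shape, 64), shape, seed=0)
        table = audit(model)
        assert table.param_column() == [256, 30, 256, 78, 256, 0, 256]
        assert table.total == 1132

    def test_audit_total_invariant_under_input_resizing(self):
        a = ModelConfig()
        b = ModelConfig(input_shape=TensorShape(128, 128, 3))
        assert audit(build_pm(a)).total == audit(build_pm(b)).total

    def test_total_must_match_rows(self):
        with pytest.raises(ValueError):
            LayerAudit(rows=[("a", "in", "1 x 1/4", 10)], total=11)

    def test_csv_export(self, tmp_path):
        import pandas as pd

        shape = TensorShape(224, 224, 3)
        table = audit_block(build_mim(shape, 64), shape)
        path = tmp_path / "audit.csv"
        table.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["layer", "input", "kernel_filter", "params"]
        assert df.iloc[-1]["params"] == 1132


class TestReconciliation:
    def test_recovers_a_known_configuration(self):
        base = ModelConfig()
        target_cfg = ModelConfig(se_ratio=8, head_hidden_units=[128])
        target = block_param_total(build_pm_spec(target_cfg), target_cfg.input_shape)
        result = reconcile_config(DEFAULT_SEARCH_SPACE, target=target, base=base)
        assert target_cfg in result.matches

    def test_impossible_target_reports_nearest_miss(self):
        result = reconcile_config(DEFAULT_SEARCH_SPACE, target=1)
        assert result.matches == []
        assert result.nearest is not None
        assert result.nearest.count > 1
        assert result.nearest.delta == result.nearest.count - 1

    def test_matches_sorted_by_distance_from_defaults(self):
        base = ModelConfig()
        target = block_param_total(build_pm_spec(base), base.input_shape)
        space = dict(DEFAULT_SEARCH_SPACE)
        result = reconcile_config(space, target=target, base=base)
        assert result.matches and result.matches[0] == base

    def test_documented_space_nearest_miss_is_committed_report(self):
        """Regression: the shipped nearest-miss report matches a fresh search."""
        import json
        from pathlib import Path

        report_path = Path(__file__).parent.parent / "configs" / "reconciliation.json"
        committed = json.loads(report_path.read_text())
        result = reconcile_config(DEFAULT_SEARCH_SPACE, target=committed["target"])
        assert len(result.matches) == committed["n_matches"]
        assert result.nearest.count == committed["nearest_miss"]["count"]
        assert result.nearest.delta == committed["nearest_miss"]["delta"]
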