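import numpy as np
import pytest

from amdnet.assembly import ModelConfig, build_pm
from amdnet.data import SplitSpec, SyntheticSpec, generate_synthetic, split
from amdnet.specs import TensorShape
from amdnet.training import TrainConfig, evaluate, train

# printed reference confusion matrices (private clinic set and Noor set)
PRIVATE_CONFUSION = np.array([[98, 1, 5], [0, 133, 0], [1, 0, 109]])
NOOR_CONFUSION = np.diag([248, 243, 158])


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """Default synthetic B-scan dataset (32 images per class, seed 0)."""
    out = tmp_path_factory.mktemp("synth")
    return generate_synthetic(SyntheticSpec(), out)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small low-resolution dataset for fast training-loop contract tests."""
    out = tmp_path_factory.mktemp("synth_tiny")
    spec = SyntheticSpec(n_per_class=6, image_size=(32, 32), band_count=3,
                         fluid_radius=6, drusen_amplitude=5, seed=1)
    return generate_synthetic(spec, out)


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(
        input_shape=TensorShape(32, 32, 3),
        stem_filters=8,
        mim_branch_filters=8,
        post_mim_filters=16,
        dseb_filters=8,
        se_ratio=4,
        cm_h=8,
        cm_d=1,
        cm_k=3,
        cm_p=2,
    )


@pytest.fixture(scope="session")
def reduced_pm_run(synthetic_dataset):
    """Train a reduced-capacity full model (cm_d=2, cm_h=64) on the default
    synthetic dataset and evaluate it on the held-out test partition.

    Shared session-wide because the run is the expensive end-to-end check that
    the assembled architecture actually learns the class morphology.
    """
    parts = split(synthetic_dataset, SplitSpec(shuffle_seed=0))
    config = ModelConfig(cm_d=2, cm_h=64)
    model = build_pm(config, seed=0)
    train_config = TrainConfig(epochs=10, batch_size=16, seed=0)
    model, history = train(model, parts, train_config)
    cm, rep = evaluate(model, parts[2])
    return {"history": history, "confusion": cm, "report": rep, "parts": parts}
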