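import numpy as np
import pytest

from roboyield import seedcount as sc
from roboyield import synthetic_field as sf

#: working-crop scene used throughout the desk-scale tests: small enough to
#: train on, dense enough to be a counting problem
SCENE64 = sf.SceneSpec(
    image_size=(64, 64), n_background_seeds=6, seed_radius_px=(2.0, 3.5)
)


@pytest.fixture(scope="session")
def scene64() -> sf.SceneSpec:
    return SCENE64


@pytest.fixture(scope="session")
def tiny_counter() -> sc.CountModel:
    """A briefly trained counting model shared by feature-consumer tests."""
    corpus = sf.render_annotated_corpus(
        100, scene_template=SCENE64, count_range=(3, 30), rng_seed=7
    )
    cfg = sc.CountModelConfig(base_channels=6, merge_radius=4.0)
    model, _ = sc.train_count_model(
        {"base": corpus[:80]},
        "ISU_NO_AUG",
        val_data=corpus[80:],
        model=sc.CountModel(cfg, seed=7),
        epochs=10,
        lr=1e-3,
        seed=7,
    )
    return model
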