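import warnings

import numpy as np
import pytest

from encroach import maxent
from encroach.synth import VEG_CLASSES, SceneConfig, build_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture(scope="session")
def scene150():
    """Default-condition scene at 150x150, shared across read-only tests."""
    return build_scene(SceneConfig(shape=(150, 150), seed=1))


@pytest.fixture(scope="session")
def sdm_data(scene150):
    """Assembled habitat-model predictors, background and presence tables."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = maxent.assemble_sdm_predictors(scene150.stack, scene150.class_map, VEG_CLASSES)
        bg, _ = maxent.background_table(pred, n=10000, random_state=0)
        pres = maxent.presence_table(pred, scene150.presences)
    return {"pred_stack": pred, "background": bg, "presences": pres, "scene": scene150}
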