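import sys
from pathlib import Path

import numpy as np
import pytest

# make the oracle helpers importable as a plain module
sys.path.insert(0, str(Path(__file__).parent))

from fruitseg import SceneSpec, generate_dataset, generate_scene, scene_specs


@pytest.fixture(scope="session")
def set1_batch():
    """20 seeded neutral-background scenes with stems."""
    return generate_dataset(scene_specs("set1", 20, 7))


@pytest.fixture(scope="session")
def set1_scene():
    return generate_scene(SceneSpec(scene_kind="set1", n_fruits=3, seed=1))


@pytest.fixture(scope="session")
def field_scene():
    return generate_scene(
        SceneSpec(
            scene_kind="field",
            n_fruits=2,
            confuser_count=3,
            shadow_strength=0.5,
            seed=5,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(16, 16), p=0.4):
    return (rng.random(shape) < p).astype(np.uint8)
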