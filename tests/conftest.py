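import numpy as np
import pandas as pd
import pytest

from forestagb.synthetic_scene import SceneConfig, build_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 30-plot synthetic scene shared across test modules."""
    return build_scene(SceneConfig(n_plots=30, seed=1))


@pytest.fixture(scope="session")
def small_bundle(small_scene):
    from forestagb.pipeline import scene_feature_tables

    return scene_feature_tables(small_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n, zmax=25.0, ground_frac=0.2):
    """Random normalized plot cloud for metric oracles."""
    is_ground = rng.uniform(size=n) < ground_frac
    z = np.where(is_ground, rng.normal(0, 0.05, n),
                 rng.uniform(0, zmax, n))
    return pd.DataFrame({
        "x": rng.uniform(0, 20, n),
        "y": rng.uniform(0, 30, n),
        "z": z,
        "intensity": rng.uniform(0, 2.0, n),
        "return_number": rng.choice([1, 2, 3], size=n, p=[0.6, 0.25, 0.15]),
        "classification": np.where(is_ground, 2, 1),
    })
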