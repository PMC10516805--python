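import numpy as np
import pytest

import osteoseg as osg


@pytest.fixture(scope="session")
def trained_model():
    """One classifier trained on three synthetic scenes, shared across tests.

    Training happens once per session; every consumer treats the model as
    read-only.
    """
    scenes = osg.scene_batch(3, seed=100)
    images = [s.image for s in scenes]
    annotations = [
        osg.generate_annotations(s, seed=200 + i) for i, s in enumerate(scenes)
    ]
    return osg.PixelClassifier(random_state=17).fit(images, annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Feature bank small enough for tiny fixture images."""
    return osg.FeatureConfig(scales=(0.7, 1.6, 3.5))


def count_osteoclasts(model, image):
    return osg.quantify_endpoints(model.predict(image)).osteoclast_count
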